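"""Bioactivity curation: record filters, unit normalisation, dedup, class binning.

The curation stage turns a raw ChEMBL-style activity export into one record
per unique chemical structure, with a single activity value in nM and a
three-class activity label:

* ``active``    — activity < 1 µM (1000 nM)
* ``moderate``  — 1 µM ≤ activity ≤ 10 µM
* ``inactive``  — activity > 10 µM

Records are dropped when they cannot support that reduction: missing or
unparseable values, right-censored relations (``>``, ``≥``), units that do not
convert to a concentration in nM, fold-change/ratio readouts, or low assay
confidence. When several measurements map to the same structure the smallest
activity (most potent) is kept.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "BioactivityRecord",
    "CuratedCompound",
    "CurationLog",
    "UnitConversionError",
    "convert_to_nM",
    "filter_records",
    "canonical_key",
    "deduplicate_min",
    "assign_activity_class",
    "curate",
    "read_bioactivity_table",
    "write_curated_table",
]

ACTIVE_MAX_NM = 1000.0     # strictly below -> active
INACTIVE_MIN_NM = 10000.0  # strictly above -> inactive

#: nM per unit, after dialect normalisation (micro signs -> "u", lowercase).
_UNIT_FACTORS = {"m": 1e9, "mm": 1e6, "um": 1e3, "nm": 1.0, "pm": 1e-3}

_EXCLUDED_RELATIONS = {">", ">=", "≥"}
_EXCLUDED_TYPES = {"fc", "ratio"}

#: Rejection reasons, in the order rules are applied; a record is counted
#: once, under the first rule it violates.
REJECTION_RULES = (
    "missing_value",
    "unparseable",
    "censored_relation",
    "excluded_type",
    "missing_units",
    "nonconvertible_units",
    "low_confidence",
)


class UnitConversionError(ValueError):
    """Raised when a unit string cannot be converted to nM."""


@dataclass
class BioactivityRecord:
    """One raw activity measurement, ChEMBL-export shaped."""

    compound_id: str
    smiles: str
    standard_type: str = "IC50"
    standard_relation: str = "="
    standard_value: float | str | None = None
    standard_units: str | None = None
    confidence_score: int = 9
    target_id: str = ""


@dataclass
class CuratedCompound:
    """One deduplicated compound with its best (lowest) activity in nM."""

    compound_id: str
    canonical_structure: str
    activity_nM: float
    activity_class: str
    readout: str
    n_measurements: int = 1


@dataclass
class CurationLog:
    """Per-rule rejection counts and dedup statistics."""

    n_input: int = 0
    n_kept: int = 0
    rejections: dict = field(default_factory=lambda: {r: 0 for r in REJECTION_RULES})
    n_duplicate_groups: int = 0
    n_compounds: int = 0
    n_unparseable_structures: int = 0
    class_counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _normalise_units(units: str) -> str:
    return units.strip().replace("µ", "u").replace("μ", "u").lower()


def convert_to_nM(value: float, units: str) -> float:
    """Convert a concentration to nanomolar.

    Accepted units: M, mM, uM/µM/μM, nM, pM (case-insensitive).
    """
    key = _normalise_units(units)
    if key not in _UNIT_FACTORS:
        raise UnitConversionError(f"unit not convertible to nM: {units!r}")
    return value * _UNIT_FACTORS[key]


def _parse_value(value) -> float | None:
    """Return a finite nonnegative float, or None if absent/unparseable.

    Missing values return None with no distinction here; callers separate the
    missing case (empty/None) before calling.
    """
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if not math.isfinite(v) or v < 0:
        return None
    return v


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _rejection_reason(rec: BioactivityRecord, min_confidence: int) -> str | None:
    if _is_missing(rec.standard_value):
        return "missing_value"
    if _parse_value(rec.standard_value) is None:
        return "unparseable"
    relation = (rec.standard_relation or "").strip()
    if relation in _EXCLUDED_RELATIONS:
        return "censored_relation"
    if (rec.standard_type or "").strip().lower() in _EXCLUDED_TYPES:
        return "excluded_type"
    if _is_missing(rec.standard_units):
        return "missing_units"
    if _normalise_units(str(rec.standard_units)) not in _UNIT_FACTORS:
        return "nonconvertible_units"
    if rec.confidence_score is None or int(rec.confidence_score) < min_confidence:
        return "low_confidence"
    return None


def filter_records(
    records: Iterable[BioactivityRecord], min_confidence: int = 8
) -> tuple[list[BioactivityRecord], CurationLog]:
    """Apply the record-level exclusion rules.

    Retains records with a parseable nonnegative value, a relation other than
    ``>``/``≥``, a readout type other than FC/Ratio, nonempty nM-convertible
    units, and ``confidence_score >= min_confidence``. Each rejected record is
    counted under the first rule it violates; malformed numerics are rejected
    with reason ``unparseable``, never raised.
    """
    kept: list[BioactivityRecord] = []
    log = CurationLog()
    for rec in records:
        log.n_input += 1
        reason = _rejection_reason(rec, min_confidence)
        if reason is None:
            kept.append(rec)
        else:
            log.rejections[reason] += 1
    log.n_kept = len(kept)
    return kept, log


_largest_fragment = rdMolStandardize.LargestFragmentChooser()
_uncharger = rdMolStandardize.Uncharger()


def canonical_key(smiles: str) -> str | None:
    """Canonical SMILES after salt stripping and charge neutralisation.

    This is the deduplication key: counter-ions are removed (largest organic
    fragment kept) and formal charges neutralised where possible, so salt
    forms of one parent collapse to a single entry. Returns None for
    unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    mol = _uncharger.uncharge(_largest_fragment.choose(mol))
    return Chem.MolToSmiles(mol)


def assign_activity_class(activity_nM: float) -> str:
    """Three-class binning: <1 µM active, >10 µM inactive, else moderate.

    Both inequalities are strict, so the boundary values 1000 nM and
    10000 nM fall in the moderate class.
    """
    if not (activity_nM > 0) or not math.isfinite(activity_nM):
        raise ValueError(f"activity must be a positive finite nM value, got {activity_nM}")
    if activity_nM < ACTIVE_MAX_NM:
        return "active"
    if activity_nM > INACTIVE_MIN_NM:
        return "inactive"
    return "moderate"


def deduplicate_min(
    records: Sequence[BioactivityRecord], log: CurationLog | None = None
) -> list[CuratedCompound]:
    """Collapse filtered records to one compound per canonical structure.

    The smallest activity value (in nM) within each structure group is kept,
    across readouts; the readout of the kept measurement is recorded. Groups
    whose structures fail to parse are dropped and counted in the log.
    """
    if log is None:
        log = CurationLog()
    groups: dict[str, list[tuple[float, BioactivityRecord]]] = defaultdict(list)
    for rec in records:
        key = canonical_key(rec.smiles)
        if key is None:
            log.n_unparseable_structures += 1
            continue
        value = _parse_value(rec.standard_value)
        if value is None or value <= 0:
            continue
        groups[key].append((convert_to_nM(value, str(rec.standard_units)), rec))

    compounds = []
    for key, members in groups.items():
        if len(members) > 1:
            log.n_duplicate_groups += 1
        best_nM, best_rec = min(members, key=lambda t: t[0])
        compounds.append(
            CuratedCompound(
                compound_id=best_rec.compound_id,
                canonical_structure=key,
                activity_nM=best_nM,
                activity_class=assign_activity_class(best_nM),
                readout=best_rec.standard_type,
                n_measurements=len(members),
            )
        )
    log.n_compounds = len(compounds)
    return compounds


def curate(
    records: Iterable[BioactivityRecord], min_confidence: int = 8
) -> tuple[pd.DataFrame, CurationLog]:
    """Full curation: filter -> convert to nM -> dedup-min -> class binning.

    Returns the curated table (one row per compound) and the curation log
    with per-rule rejection counts, duplicate statistics, and class counts.
    """
    kept, log = filter_records(records, min_confidence=min_confidence)
    compounds = deduplicate_min(kept, log=log)
    df = pd.DataFrame([asdict(c) for c in compounds])
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "compound_id", "canonical_structure", "activity_nM",
                "activity_class", "readout", "n_measurements",
            ]
        )
    log.class_counts = df["activity_class"].value_counts().to_dict() if len(df) else {}
    return df, log


# ---------------------------------------------------------------------------
# I/O

_COLUMN_ALIASES = {
    "compound_id": {"compound_id", "molecule chembl id", "molecule_chembl_id", "chembl id"},
    "smiles": {"smiles", "canonical_smiles", "canonical smiles"},
    "standard_type": {"standard_type", "standard type"},
    "standard_relation": {"standard_relation", "standard relation"},
    "standard_value": {"standard_value", "standard value"},
    "standard_units": {"standard_units", "standard units"},
    "confidence_score": {"confidence_score", "confidence score"},
    "target_id": {"target_id", "target chembl id", "target_chembl_id"},
}


def read_bioactivity_table(path, sep: str | None = None) -> list[BioactivityRecord]:
    """Read a delimited ChEMBL-style export into BioactivityRecord objects.

    The delimiter is sniffed (comma or tab) unless given; header names are
    matched case-insensitively against the ChEMBL export field names.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    rename = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for col in df.columns:
            if col.strip().lower() in aliases:
                rename[col] = canon
    df = df.rename(columns=rename)
    records = []
    for row in df.to_dict("records"):
        records.append(
            BioactivityRecord(
                compound_id=str(row.get("compound_id", "")),
                smiles=str(row.get("smiles", "")),
                standard_type=str(row.get("standard_type", "")),
                standard_relation=str(row.get("standard_relation", "")),
                standard_value=row.get("standard_value"),
                standard_units=row.get("standard_units"),
                confidence_score=int(row["confidence_score"])
                if not _is_missing(row.get("confidence_score"))
                else 0,
                target_id=str(row.get("target_id", "")),
            )
        )
    return records


def write_curated_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
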