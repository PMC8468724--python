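"""PLIF-similarity screening model and enrichment-curve evaluation.

A protein–ligand interaction fingerprint (PLIF) here is a binary vector
over binding-site residues: 1 where a docked pose contacts the residue.
The screening function ranks compounds by the Tanimoto similarity of
their PLIF to the X-ray reference ligand's PLIF, computed over the N most
frequently contacted residues (N is swept over 5..25 in steps of 5 and
the curve chosen by inspection of its enrichment diagnostics).  Screening
quality is judged by enrichment curves — % of true actives among the
compounds passing each similarity threshold — and dual-target hits are
compounds satisfying an interval criterion on both targets' similarities
(default: 0.8 < sim_A ≤ 0.9 and sim_B ≥ 0.9).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "ScreeningFunction",
    "EnrichmentCurve",
    "DualCriterion",
    "contact_frequency",
    "select_top_residues",
    "plif_similarity",
    "ligand_efficiency",
    "enrichment_curve",
    "curve_diagnostics",
    "select_dual_hits",
    "screen_similarities",
]

DEFAULT_THRESHOLDS = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
DEFAULT_TOP_N = (5, 10, 15, 20, 25)


@dataclass
class ContactMatrix:
    """Compounds × residues binary contact profiles, with docking metadata.

    Residue labels follow ``chain:RESNAME:number`` (e.g. ``K:THR:1``).
    """

    compound_ids: list[str]
    residues: list[str]
    contacts: np.ndarray  # (n_compounds, n_residues) in {0,1}
    docking_score: np.ndarray | None = None  # lower = better
    n_heavy_atoms: np.ndarray | None = None
    labels: list[str] | None = None  # activity class per compound

    def __post_init__(self):
        self.contacts = np.asarray(self.contacts, dtype=np.uint8)
        if self.contacts.shape != (len(self.compound_ids), len(self.residues)):
            raise ValueError("contact matrix shape does not match id/residue lists")
        if not np.isin(self.contacts, (0, 1)).all():
            raise ValueError("contact matrix entries must be binary")

    def residue_index(self, subset: list[str]) -> np.ndarray:
        missing = [r for r in subset if r not in self.residues]
        if missing:
            raise KeyError(f"residues absent from matrix: {missing}")
        pos = {r: i for i, r in enumerate(self.residues)}
        return np.array([pos[r] for r in subset], dtype=int)


@dataclass
class ScreeningFunction:
    """A reference PLIF restricted to an optimised residue subset."""

    reference_profile: np.ndarray
    residue_subset: list[str]

    @property
    def N(self) -> int:
        return len(self.residue_subset)


@dataclass
class EnrichmentCurve:
    """% actives among selected vs selection threshold, with coverage.

    ``enrichment_pct`` is NaN wherever coverage is zero (undefined).
    """

    thresholds: np.ndarray
    enrichment_pct: np.ndarray
    coverage: np.ndarray
    direction: str = "higher_better"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "enrichment_pct": self.enrichment_pct,
                "coverage": self.coverage,
            }
        )


@dataclass
class DualCriterion:
    """Interval condition on two targets' PLIF similarities.

    Defaults encode ``0.8 < sim_A ≤ 0.9  and  sim_B ≥ 0.9``.
    """

    lower_a: float = 0.8
    upper_a: float = 0.9
    lower_b: float = 0.9
    lower_a_inclusive: bool = False
    upper_a_inclusive: bool = True
    lower_b_inclusive: bool = True

    def __post_init__(self):
        if not self.lower_a < self.upper_a:
            raise ValueError("lower_a must be < upper_a")

    def matches(self, sim_a: float, sim_b: float) -> bool:
        ok_lo = sim_a >= self.lower_a if self.lower_a_inclusive else sim_a > self.lower_a
        ok_hi = sim_a <= self.upper_a if self.upper_a_inclusive else sim_a < self.upper_a
        ok_b = sim_b >= self.lower_b if self.lower_b_inclusive else sim_b > self.lower_b
        return bool(ok_lo and ok_hi and ok_b)


_RES_NUM = re.compile(r"(-?\d+)\s*$")


def _residue_seqnum(label: str) -> int:
    m = _RES_NUM.search(label)
    return int(m.group(1)) if m else 0


def contact_frequency(matrix: ContactMatrix) -> pd.Series:
    """Fraction of compounds contacting each residue."""
    if len(matrix.compound_ids) == 0:
        raise ValueError("contact matrix is empty")
    freq = matrix.contacts.mean(axis=0)
    return pd.Series(freq, index=matrix.residues, name="contact_frequency")


def select_top_residues(frequencies: pd.Series, n: int) -> list[str]:
    """The N most frequently contacted residues.

    Ties are broken deterministically by ascending residue sequence number,
    then label.
    """
    if n > len(frequencies):
        raise ValueError(f"N={n} exceeds residue count {len(frequencies)}")
    order = sorted(
        frequencies.index,
        key=lambda r: (-frequencies[r], _residue_seqnum(r), r),
    )
    return order[:n]


def plif_similarity(
    profile_a: np.ndarray, profile_b: np.ndarray, subset: np.ndarray | None = None
) -> float:
    """Tanimoto similarity of two binary contact profiles over a residue subset.

    ``subset`` is an index array into the residue axis (None = all residues).
    Two profiles that are both empty on the subset are defined as similarity 0.
    """
    a = np.asarray(profile_a, dtype=bool)
    b = np.asarray(profile_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("profiles cover different residue universes")
    if subset is not None:
        a = a[subset]
        b = b[subset]
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def ligand_efficiency(score: float, n_heavy: int) -> float:
    """Docking score normalised by heavy-atom count (LE = score / #heavy)."""
    if n_heavy < 1:
        raise ValueError("heavy-atom count must be >= 1")
    return score / n_heavy


def screen_similarities(
    matrix: ContactMatrix,
    reference_profile: np.ndarray,
    n_top: int | None = None,
) -> tuple[pd.Series, ScreeningFunction]:
    """PLIF similarity of every compound to the reference over the top-N
    most frequently contacted residues (all residues when ``n_top`` is None).
    """
    ref = np.asarray(reference_profile).ravel()
    if ref.shape[0] != len(matrix.residues):
        raise ValueError("reference profile length does not match residue list")
    if n_top is None:
        subset_labels = list(matrix.residues)
    else:
        subset_labels = select_top_residues(contact_frequency(matrix), n_top)
    idx = matrix.residue_index(subset_labels)
    sims = np.array(
        [plif_similarity(row, ref, idx) for row in matrix.contacts], dtype=float
    )
    fn = ScreeningFunction(reference_profile=ref.astype(np.uint8), residue_subset=subset_labels)
    return pd.Series(sims, index=matrix.compound_ids, name="plif_similarity"), fn


def enrichment_curve(
    values: np.ndarray,
    labels: list[str],
    thresholds: np.ndarray | None = None,
    direction: str = "higher_better",
) -> EnrichmentCurve:
    """Enrichment (% actives among selected) and coverage across thresholds.

    Selection keeps ``value >= t`` (``higher_better``) or ``value <= t``
    (``lower_better``). Only the strict ``active`` class counts as active;
    moderates count against enrichment. Thresholds with zero coverage yield
    NaN enrichment.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels are not aligned")
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown direction: {direction!r}")
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS if direction == "higher_better" else np.sort(values)
    thresholds = np.asarray(thresholds, dtype=float)
    is_active = labels == "active"
    if not is_active.any():
        warnings.warn("no actives in dataset; enrichment will be 0 everywhere")
    enrich = np.full(thresholds.shape, np.nan)
    coverage = np.zeros(thresholds.shape, dtype=int)
    for i, t in enumerate(thresholds):
        sel = values >= t if direction == "higher_better" else values <= t
        coverage[i] = int(sel.sum())
        if coverage[i] > 0:
            enrich[i] = 100.0 * is_active[sel].mean()
    return EnrichmentCurve(thresholds, enrich, coverage, direction)


def curve_diagnostics(curve: EnrichmentCurve) -> dict:
    """Summary supporting manual curve selection: maximum enrichment (first
    occurrence on ties), its threshold and coverage, and the count/depth of
    non-monotone drops along the defined part of the curve.
    """
    defined = ~np.isnan(curve.enrichment_pct)
    if not defined.any():
        raise ValueError("curve has no defined points")
    vals = curve.enrichment_pct[defined]
    thr = curve.thresholds[defined]
    cov = curve.coverage[defined]
    imax = int(np.argmax(vals))  # argmax returns the first maximum
    drops = []
    i = 1
    while i < len(vals):
        if vals[i] < vals[i - 1]:
            start = vals[i - 1]
            while i < len(vals) and vals[i] < vals[i - 1]:
                i += 1
            drops.append(float(start - vals[i - 1]))
        else:
            i += 1
    return {
        "max_enrichment_pct": float(vals[imax]),
        "threshold_at_max": float(thr[imax]),
        "coverage_at_max": int(cov[imax]),
        "n_drops": len(drops),
        "drop_depths": drops,
    }


def select_dual_hits(
    sims_a: pd.Series, sims_b: pd.Series, criterion: DualCriterion | None = None
) -> pd.DataFrame:
    """Compounds satisfying the dual-target similarity criterion.

    Returns a table echoing both similarities per hit. Compounds present in
    only one similarity map are excluded with a warning.
    """
    criterion = criterion if criterion is not None else DualCriterion()
    common = sims_a.index.intersection(sims_b.index)
    missing = len(sims_a.index.symmetric_difference(sims_b.index))
    if missing:
        warnings.warn(f"{missing} compounds missing from one similarity map; excluded")
    rows = [
        {"compound_id": cid, "sim_a": float(sims_a[cid]), "sim_b": float(sims_b[cid])}
        for cid in common
        if criterion.matches(float(sims_a[cid]), float(sims_b[cid]))
    ]
    return pd.DataFrame(rows, columns=["compound_id", "sim_a", "sim_b"])
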