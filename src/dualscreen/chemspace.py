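"""Chemical-space comparison of two inhibitor datasets.

Quantifies how much two compound collections overlap: per-compound
physicochemical profiles, Bemis–Murcko scaffold content and overlap,
cross-set nearest-neighbour Tanimoto similarity over Morgan fingerprints
(1024 bits, radius 2), maximum-common-substructure pairs, and a seeded 2-D
t-SNE embedding of the joint fingerprint space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFMCS, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.manifold import TSNE

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintSet",
    "ScaffoldSummary",
    "SubstructureMatch",
    "physchem_profile",
    "murcko_scaffold",
    "scaffold_overlap",
    "morgan_fingerprints",
    "cross_max_similarity",
    "tanimoto",
    "shared_substructure_pairs",
    "embed_chemical_space",
]

FP_RADIUS = 2
FP_NBITS = 1024


@dataclass
class FingerprintSet:
    """Morgan fingerprints for a compound set as a dense binary matrix."""

    compound_ids: list[str]
    bits: np.ndarray  # (n_compounds, n_bits) uint8
    radius: int = FP_RADIUS
    n_bits: int = FP_NBITS

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.compound_ids):
            raise ValueError("fingerprint matrix shape does not match id list")

    def __len__(self) -> int:
        return len(self.compound_ids)


@dataclass
class ScaffoldSummary:
    scaffolds: set
    n_compounds: int

    @property
    def ratio(self) -> float:
        """Scaffold diversity: unique scaffolds per compound."""
        return len(self.scaffolds) / self.n_compounds if self.n_compounds else 0.0


@dataclass
class SubstructureMatch:
    id_a: str
    id_b: str
    n_matched_atoms: int
    mode: str
    smarts: str = ""


def _mol(smiles: str):
    return Chem.MolFromSmiles(smiles)


def physchem_profile(structures: list[str], ids: list[str] | None = None) -> pd.DataFrame:
    """Six key physicochemical properties per compound.

    TPSA, rotatable bonds, logP (Crippen), total H-bond donor+acceptor
    count, molecular weight, and ring count. Unparseable structures keep
    their row with NaN values and ``parse_error=True`` rather than being
    silently dropped.
    """
    ids = ids if ids is not None else [f"cpd{i}" for i in range(len(structures))]
    rows = []
    for cid, smi in zip(ids, structures):
        mol = _mol(smi)
        if mol is None:
            rows.append({"compound_id": cid, "smiles": smi, "parse_error": True})
            continue
        rows.append(
            {
                "compound_id": cid,
                "smiles": smi,
                "parse_error": False,
                "tpsa": Descriptors.TPSA(mol),
                "rotatable_bonds": Descriptors.NumRotatableBonds(mol),
                "logp": Descriptors.MolLogP(mol),
                "hbond_atoms": Descriptors.NumHDonors(mol) + Descriptors.NumHAcceptors(mol),
                "mol_weight": Descriptors.MolWt(mol),
                "ring_count": Descriptors.RingCount(mol),
            }
        )
    cols = ["compound_id", "smiles", "parse_error", "tpsa", "rotatable_bonds",
            "logp", "hbond_atoms", "mol_weight", "ring_count"]
    return pd.DataFrame(rows).reindex(columns=cols)


def murcko_scaffold(structure: str) -> str:
    """Canonical Bemis–Murcko scaffold SMILES; empty string for acyclic input."""
    mol = _mol(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold) if scaffold.GetNumAtoms() else ""


def scaffold_overlap(
    set_a: list[str], set_b: list[str]
) -> tuple[ScaffoldSummary, ScaffoldSummary, set]:
    """Scaffold summaries for each set plus the shared scaffold set.

    Acyclic molecules contribute no scaffold (the empty scaffold is not
    counted as shared content).
    """
    if not set_a or not set_b:
        raise ValueError("both compound sets must be nonempty")
    scaf_a = {s for s in (murcko_scaffold(x) for x in set_a) if s}
    scaf_b = {s for s in (murcko_scaffold(x) for x in set_b) if s}
    return (
        ScaffoldSummary(scaf_a, len(set_a)),
        ScaffoldSummary(scaf_b, len(set_b)),
        scaf_a & scaf_b,
    )


def morgan_fingerprints(
    structures: list[str],
    ids: list[str] | None = None,
    radius: int = FP_RADIUS,
    n_bits: int = FP_NBITS,
) -> FingerprintSet:
    """Morgan (ECFP-like) fingerprints as a dense uint8 bit matrix."""
    ids = ids if ids is not None else [f"cpd{i}" for i in range(len(structures))]
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = np.zeros((len(structures), n_bits), dtype=np.uint8)
    for i, smi in enumerate(structures):
        mol = _mol(smi)
        if mol is None:
            raise ValueError(f"unparseable structure: {smi!r}")
        bits[i] = np.frombuffer(
            gen.GetFingerprint(mol).ToBitString().encode(), dtype=np.uint8
        ) - ord("0")
    return FingerprintSet(list(ids), bits, radius=radius, n_bits=n_bits)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient of two binary vectors; 0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def cross_max_similarity(set_a: FingerprintSet, set_b: FingerprintSet) -> np.ndarray:
    """Per-compound maximum Tanimoto of each member of ``set_a`` against all
    of ``set_b`` (the 1-versus-all nearest-neighbour similarity distribution).
    """
    if len(set_b) == 0:
        raise ValueError("comparison set is empty")
    if set_a.n_bits != set_b.n_bits:
        raise ValueError("fingerprint lengths differ")
    a = set_a.bits.astype(np.float64)
    b = set_b.bits.astype(np.float64)
    inter = a @ b.T
    pop_a = a.sum(axis=1)[:, None]
    pop_b = b.sum(axis=1)[None, :]
    union = pop_a + pop_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim.max(axis=1)


def shared_substructure_pairs(
    set_a: list[str],
    set_b: list[str],
    ids_a: list[str] | None = None,
    ids_b: list[str] | None = None,
    min_atoms: int = 15,
    mode: str = "strict_aromatic",
    timeout: int = 5,
) -> list[SubstructureMatch]:
    """Cross-set pairs sharing a maximum common substructure of > ``min_atoms``
    atoms.

    ``strict_aromatic`` requires exact bond-order matching, so aromatic atoms
    map only onto aromatic atoms; ``relaxed`` ignores bond order. MCS search
    is NP-hard, so each pair gets a ``timeout`` (seconds); timed-out pairs are
    skipped with a logged warning.
    """
    if mode not in ("strict_aromatic", "relaxed"):
        raise ValueError(f"unknown mode: {mode!r}")
    bond_cmp = (
        rdFMCS.BondCompare.CompareOrderExact
        if mode == "strict_aromatic"
        else rdFMCS.BondCompare.CompareAny
    )
    ids_a = ids_a if ids_a is not None else [f"a{i}" for i in range(len(set_a))]
    ids_b = ids_b if ids_b is not None else [f"b{i}" for i in range(len(set_b))]
    mols_a = [(cid, _mol(s)) for cid, s in zip(ids_a, set_a)]
    mols_b = [(cid, _mol(s)) for cid, s in zip(ids_b, set_b)]
    for cid, m in mols_a + mols_b:
        if m is None:
            raise ValueError(f"unparseable structure for {cid}")
    matches = []
    for ida, ma in mols_a:
        for idb, mb in mols_b:
            result = rdFMCS.FindMCS([ma, mb], bondCompare=bond_cmp, timeout=timeout)
            if result.canceled:
                logger.warning("MCS timed out for pair (%s, %s); skipped", ida, idb)
                continue
            if result.numAtoms > min_atoms:
                matches.append(
                    SubstructureMatch(ida, idb, result.numAtoms, mode, result.smartsString)
                )
    return matches


def embed_chemical_space(fps: FingerprintSet, seed: int, perplexity: float = 30.0) -> np.ndarray:
    """Deterministic 2-D t-SNE embedding of a fingerprint set.

    Perplexity is capped at (n-1)/3 so small sets remain embeddable.
    """
    n = len(fps)
    if n < 3:
        raise ValueError("embedding needs at least 3 compounds")
    perplexity = min(perplexity, (n - 1) / 3)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return tsne.fit_transform(fps.bits.astype(np.float64))
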