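"""Seeded synthetic inputs for every pipeline stage, with ground truth.

Each generator is a pure function of a :class:`SyntheticSpec` (bit-identical
output per seed) and returns, alongside the data, a ground-truth ledger
computed from the construction itself — planted rejection counts, exact
duplicate minima, expected PLIF similarities, class means, planted H-bond
occupancies, residue fluctuation σ — so that recovery tests can compare the
pipeline's output against the planted truth without re-deriving anything
through the code under test.

The emulated regimes: ChEMBL-style activity tables spanning nM–mM with
duplicates and non-convertible units; binary contact matrices in which
actives reproduce the reference ligand's contacts more often than
inactives; Gaussian descriptor tables with class-separated informative
dimensions; Bernoulli/Markov or exactly-planted H-bond event streams;
and Cα trajectories with isotropic Gaussian jitter and a planted ligand
distance series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import BioactivityRecord
from .md import HBond, HBondMatrix, Trajectory, ATOM_COLUMNS
from .plif import ContactMatrix

__all__ = [
    "SyntheticSpec",
    "toy_smiles",
    "gen_bioactivity_table",
    "gen_plif_matrix",
    "gen_descriptor_table",
    "gen_hbond_matrix",
    "gen_trajectory",
    "gen_energy_series",
]


@dataclass
class SyntheticSpec:
    """Parameters of the planted data regimes.

    ``p_active``/``p_inactive`` are the probabilities that an active/inactive
    compound reproduces a reference contact; ``q`` is the background contact
    rate on off-reference residues. ``descriptor_separation`` is the distance
    between class means in pooled-SD units. ``sigma_fluct`` (Å) is the
    per-axis residue jitter; ``frac_within`` the planted fraction of frames
    with the ligand below the 5 Å distance cutoff.
    """

    seed: int = 0
    n_active: int = 170
    n_moderate: int = 160
    n_inactive: int = 170
    n_residues: int = 200
    p_active: float = 0.9
    p_inactive: float = 0.3
    q: float = 0.05
    descriptor_separation: float = 2.0
    occupancy_vector: tuple = (0.8, 0.6, 0.4, 0.2)
    sigma_fluct: float = 0.5
    drift_rate: float = 0.0
    frac_within: float = 0.164

    def __post_init__(self):
        for name in ("p_active", "p_inactive", "q", "frac_within"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.p_active < self.p_inactive:
            raise ValueError("planted-signal mode requires p_active >= p_inactive")


# ---------------------------------------------------------------------------
# Toy structures

_FAMILY_CORES = {
    "benzene": "c1ccccc1",
    "pyridine": "c1ccncc1",
    "indole": "c1ccc2[nH]ccc2c1",
    "furan": "c1ccoc1",
}


def toy_smiles(n: int, family: str = "benzene") -> list[str]:
    """``n`` chemically valid, structurally distinct SMILES from one scaffold
    family (a homologous alkyl series on a fixed aromatic core).

    Curated templates rather than random molecular graphs guarantee validity
    by construction.
    """
    core = _FAMILY_CORES[family]
    return [f"{'C' * (i + 1)}{core}" for i in range(n)]


# ---------------------------------------------------------------------------
# Bioactivity tables

_CLASS_THRESHOLD_LOW_NM = 1000.0
_CLASS_THRESHOLD_HIGH_NM = 10000.0

DEFAULT_VIOLATIONS = {
    "missing_value": 2,
    "unparseable": 1,
    "censored_relation": 3,
    "excluded_type": 2,
    "missing_units": 2,
    "nonconvertible_units": 2,
    "low_confidence": 4,
}


@dataclass
class BioactivityTruth:
    planted_rejections: dict
    n_surviving: int
    class_counts: dict
    duplicate_minima: dict      # compound smiles -> planted minimum (nM)
    n_duplicate_groups: int


def _express_in_units(rng, nM: float) -> tuple[float, str]:
    unit = rng.choice(["nM", "uM", "mM"])
    factor = {"nM": 1.0, "uM": 1e3, "mM": 1e6}[unit]
    return nM / factor, unit


def gen_bioactivity_table(
    spec: SyntheticSpec,
    n_clean: int = 30,
    violations: dict | None = None,
    n_duplicate_groups: int = 5,
    duplicates_per_group: int = 3,
) -> tuple[list[BioactivityRecord], BioactivityTruth]:
    """ChEMBL-style activity records with planted violations and duplicates.

    Clean activities are drawn log-uniform over [1, 10^6] nM and expressed in
    a random convertible unit. Each violation type gets exactly the planted
    number of otherwise-clean records; duplicate groups share one structure
    with a known minimum activity.
    """
    rng = np.random.default_rng(spec.seed)
    violations = dict(DEFAULT_VIOLATIONS if violations is None else violations)
    n_structures = n_clean + sum(violations.values()) + n_duplicate_groups
    smiles = toy_smiles(n_structures, "benzene")
    records: list[BioactivityRecord] = []
    truth_minima: dict[str, float] = {}
    class_counts = {"active": 0, "moderate": 0, "inactive": 0}
    cursor = 0

    def clean_record(smi: str, nM: float, cid: str) -> BioactivityRecord:
        value, unit = _express_in_units(rng, nM)
        return BioactivityRecord(
            compound_id=cid,
            smiles=smi,
            standard_type=rng.choice(["IC50", "Ki"]),
            standard_relation="=",
            standard_value=value,
            standard_units=unit,
            confidence_score=int(rng.integers(8, 10)),
        )

    def classify(nM: float) -> str:
        # ground-truth binning arithmetic, independent of the curation module
        if nM < _CLASS_THRESHOLD_LOW_NM:
            return "active"
        if nM > _CLASS_THRESHOLD_HIGH_NM:
            return "inactive"
        return "moderate"

    # singleton clean records
    for i in range(n_clean):
        smi = smiles[cursor]; cursor += 1
        nM = float(10 ** rng.uniform(0, 6))
        records.append(clean_record(smi, nM, f"CLEAN{i}"))
        truth_minima[smi] = nM
        class_counts[classify(nM)] += 1

    # duplicate groups with a known minimum
    for g in range(n_duplicate_groups):
        smi = smiles[cursor]; cursor += 1
        values = sorted(float(10 ** rng.uniform(0, 6)) for _ in range(duplicates_per_group))
        for j, nM in enumerate(rng.permutation(values)):
            records.append(clean_record(smi, float(nM), f"DUP{g}_{j}"))
        truth_minima[smi] = values[0]
        class_counts[classify(values[0])] += 1

    # planted violations: one rule violated per record
    for rule, count in violations.items():
        for i in range(count):
            smi = smiles[cursor]; cursor += 1
            rec = clean_record(smi, float(10 ** rng.uniform(0, 6)), f"BAD_{rule}_{i}")
            if rule == "missing_value":
                rec.standard_value = None
            elif rule == "unparseable":
                rec.standard_value = "not-a-number"
            elif rule == "censored_relation":
                rec.standard_relation = rng.choice([">", "≥"])
            elif rule == "excluded_type":
                rec.standard_type = rng.choice(["FC", "Ratio"])
            elif rule == "missing_units":
                rec.standard_units = ""
            elif rule == "nonconvertible_units":
                rec.standard_units = rng.choice(["%", "/s", "hr"])
            elif rule == "low_confidence":
                rec.confidence_score = int(rng.integers(0, 8))
            else:
                raise ValueError(f"unknown violation rule: {rule!r}")
            records.append(rec)

    rng.shuffle(records)
    truth = BioactivityTruth(
        planted_rejections=violations,
        n_surviving=n_clean + n_duplicate_groups,
        class_counts=class_counts,
        duplicate_minima=truth_minima,
        n_duplicate_groups=n_duplicate_groups,
    )
    return records, truth


# ---------------------------------------------------------------------------
# PLIF contact matrices

@dataclass
class PlifTruth:
    expected_similarity: dict   # class -> Monte-Carlo mean subset similarity
    reference_residues: list
    base_active_rate: float


def gen_plif_matrix(
    spec: SyntheticSpec, k: int = 10, n_mc: int = 4000
) -> tuple[ContactMatrix, np.ndarray, PlifTruth]:
    """Contact matrix with a planted class signal plus the X-ray reference.

    The reference ligand contacts the first ``k`` residues. Each active
    reproduces a reference contact with probability ``p_active``, each
    inactive with ``p_inactive`` (moderates at the midpoint); off-reference
    residues are contacted with background rate ``q``. Expected
    subset-restricted Tanimoto similarities per class are estimated by
    Monte Carlo with an independent RNG stream and stored in the truth.
    """
    if k > spec.n_residues:
        raise ValueError("reference size k exceeds residue count")
    rng = np.random.default_rng(spec.seed)
    n_res = spec.n_residues
    residues = [f"A:RES:{i + 1}" for i in range(n_res)]
    p_moderate = (spec.p_active + spec.p_inactive) / 2.0
    class_plan = (
        [("active", spec.p_active)] * spec.n_active
        + [("moderate", p_moderate)] * spec.n_moderate
        + [("inactive", spec.p_inactive)] * spec.n_inactive
    )
    n = len(class_plan)
    contacts = np.zeros((n, n_res), dtype=np.uint8)
    labels, scores, heavy = [], [], []
    for i, (cls, p) in enumerate(class_plan):
        contacts[i, :k] = rng.random(k) < p
        contacts[i, k:] = rng.random(n_res - k) < spec.q
        labels.append(cls)
        scores.append(rng.normal(-8.5 if cls == "active" else -6.5, 1.0))
        heavy.append(int(rng.integers(15, 46)))
    reference = np.zeros(n_res, dtype=np.uint8)
    reference[:k] = 1

    # Monte-Carlo expected subset similarity per class (independent stream)
    mc = np.random.default_rng(spec.seed + 10_007)
    expected = {}
    for cls, p in (("active", spec.p_active), ("moderate", p_moderate),
                   ("inactive", spec.p_inactive)):
        draws = mc.random((n_mc, k)) < p
        # subset = the k reference residues; union with reference is always k
        expected[cls] = float(draws.sum(axis=1).mean() / k)
    matrix = ContactMatrix(
        compound_ids=[f"cpd{i}" for i in range(n)],
        residues=residues,
        contacts=contacts,
        docking_score=np.array(scores),
        n_heavy_atoms=np.array(heavy),
        labels=labels,
    )
    truth = PlifTruth(
        expected_similarity=expected,
        reference_residues=residues[:k],
        base_active_rate=spec.n_active / n,
    )
    return matrix, reference, truth


# ---------------------------------------------------------------------------
# Descriptor tables

@dataclass
class DescriptorTruth:
    class_means: dict           # class -> mean vector on informative dims
    informative_columns: list


def gen_descriptor_table(
    spec: SyntheticSpec, n_features: int = 200, n_informative: int = 5
) -> tuple[pd.DataFrame, np.ndarray, DescriptorTruth]:
    """Gaussian descriptor table with class-separated informative dimensions.

    Five informative columns have class means placed ``descriptor_separation``
    pooled SDs apart along each dimension (unit SD, means at 0, s, 2s for
    inactive/moderate/active); the remaining columns are pure noise.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.descriptor_separation
    counts = {"active": spec.n_active, "moderate": spec.n_moderate,
              "inactive": spec.n_inactive}
    mean_of = {"inactive": 0.0, "moderate": s, "active": 2.0 * s}
    labels, blocks = [], []
    for cls in ("active", "moderate", "inactive"):
        n = counts[cls]
        block = rng.normal(0.0, 1.0, size=(n, n_features))
        block[:, :n_informative] += mean_of[cls]
        blocks.append(block)
        labels += [cls] * n
    X = np.vstack(blocks)
    y = np.array(labels)
    perm = rng.permutation(len(y))
    cols = [f"desc_{j}" for j in range(n_features)]
    df = pd.DataFrame(X[perm], columns=cols,
                      index=[f"cpd{i}" for i in range(len(y))])
    truth = DescriptorTruth(
        class_means={c: [mean_of[c]] * n_informative for c in counts},
        informative_columns=cols[:n_informative],
    )
    return df, y[perm], truth


# ---------------------------------------------------------------------------
# H-bond matrices

@dataclass
class HBondTruth:
    occupancies: dict           # residue label -> planted occupancy
    frac_at_least_one: float
    frac_at_least_two: float
    mode: str


def gen_hbond_matrix(
    spec: SyntheticSpec,
    n_frames: int = 1000,
    mode: str = "deterministic",
    persistence: float = 0.9,
) -> tuple[HBondMatrix, HBondTruth]:
    """Hydrogen-bond existence matrix with planted occupancies.

    ``deterministic`` plants each residue's bond in the first
    ``round(occ * n_frames)`` frames, so occupancy recovery is exact and the
    ≥1/≥2 simultaneity fractions equal the largest and second-largest planted
    occupancies (nested prefixes). ``bernoulli`` draws frames independently;
    ``markov`` uses a 2-state chain with the given persistence and the
    planted occupancy as stationary probability.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    occ = np.asarray(spec.occupancy_vector, dtype=float)
    n_res = len(occ)
    rng = np.random.default_rng(spec.seed)
    existence = np.zeros((n_res, n_frames), dtype=np.uint8)
    residues = [f"A:SER:{i + 1}" for i in range(n_res)]
    planted = {}
    if mode == "deterministic":
        counts = np.round(occ * n_frames).astype(int)
        for i, c in enumerate(counts):
            existence[i, :c] = 1
            planted[residues[i]] = c / n_frames
        sorted_counts = np.sort(counts)[::-1]
        ge1 = sorted_counts[0] / n_frames if n_res else 0.0
        ge2 = sorted_counts[1] / n_frames if n_res > 1 else 0.0
    elif mode == "bernoulli":
        for i, p in enumerate(occ):
            existence[i] = rng.random(n_frames) < p
            planted[residues[i]] = float(p)
        ge1 = float(1 - np.prod(1 - occ))
        # P(>=2) = 1 - P(0) - P(exactly 1), independent rows
        p0 = np.prod(1 - occ)
        p1 = sum(p * np.prod([1 - q for j, q in enumerate(occ) if j != i])
                 for i, p in enumerate(occ))
        ge2 = float(1 - p0 - p1)
    elif mode == "markov":
        for i, p in enumerate(occ):
            stay_on = persistence
            stay_off = 1 - p * (1 - stay_on) / max(1e-12, (1 - p))
            stay_off = min(max(stay_off, 0.0), 1.0)
            state = rng.random() < p
            for f in range(n_frames):
                existence[i, f] = state
                stay = stay_on if state else stay_off
                if rng.random() >= stay:
                    state = not state
            planted[residues[i]] = float(p)
        ge1 = float(1 - np.prod(1 - occ))
        p0 = np.prod(1 - occ)
        p1 = sum(p * np.prod([1 - q for j, q in enumerate(occ) if j != i])
                 for i, p in enumerate(occ))
        ge2 = float(1 - p0 - p1)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    bonds = [
        HBond(
            donor_atom=1000 + i,
            hydrogen_atom=2000 + i,
            acceptor_atom=i,
            donor_residue="X:LIG:1",
            acceptor_residue=res,
            partner_residue=res,
        )
        for i, res in enumerate(residues)
    ]
    times = np.arange(n_frames) * 10.0  # 10 ps spacing
    truth = HBondTruth(planted, float(ge1), float(ge2), mode)
    return HBondMatrix(bonds, existence, times), truth


# ---------------------------------------------------------------------------
# Trajectories

@dataclass
class TrajectoryTruth:
    sigma: np.ndarray           # per-residue planted jitter SD (Å per axis)
    frac_within: float          # planted fraction of frames below 5 Å
    near_distance: float
    far_distance: float


def gen_trajectory(
    spec: SyntheticSpec,
    n_frames: int = 1000,
    n_residues: int = 10,
    near: float = 3.0,
    far: float = 8.0,
    with_ligand: bool = True,
) -> tuple[Trajectory, TrajectoryTruth]:
    """Cα trajectory with isotropic Gaussian jitter and a planted ligand path.

    Residue i sits at a fixed mean position with N(0, σ_fluct²) jitter per
    axis. The single-atom ligand is placed at an exact distance from residue
    1's instantaneous position: ``near`` (Å) in the first
    ``round(frac_within · n_frames)`` frames and ``far`` after, so the
    fraction of frames below the 5 Å cutoff is planted exactly. Frames are
    10 ps apart.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(spec.seed)
    means = np.zeros((n_residues, 3))
    means[:, 0] = np.arange(n_residues) * 20.0  # well separated along x
    coords = means[None, :, :] + rng.normal(
        0.0, spec.sigma_fluct, size=(n_frames, n_residues, 3)
    )
    n_near = int(round(spec.frac_within * n_frames))
    rows = []
    for i in range(n_residues):
        rows.append(
            dict(atom_id=i, residue_id=i + 1, residue_name="ALA", chain="A",
                 element="C", is_donor=False, is_acceptor=False,
                 is_ligand=False, parent_donor=-1)
        )
    if with_ligand:
        # exact planted min distance to residue 1 along -y (no other atom nearer)
        offsets = np.where(np.arange(n_frames) < n_near, near, far)
        lig = coords[:, 0, :].copy()
        lig[:, 1] -= offsets
        coords = np.concatenate([coords, lig[:, None, :]], axis=1)
        rows.append(
            dict(atom_id=n_residues, residue_id=9999, residue_name="LIG",
                 chain="X", element="C", is_donor=False, is_acceptor=False,
                 is_ligand=True, parent_donor=-1)
        )
    times = np.arange(n_frames) * 10.0
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    truth = TrajectoryTruth(
        sigma=np.full(n_residues, spec.sigma_fluct),
        frac_within=n_near / n_frames,
        near_distance=near,
        far_distance=far,
    )
    return Trajectory(times, coords, atoms), truth


# ---------------------------------------------------------------------------
# Energy series

def gen_energy_series(
    spec: SyntheticSpec,
    n_points: int = 1000,
    mean_energy: float = -5.0e5,
    noise_sd: float = 50.0,
    duration_ps: float = 10_000.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-energy time series with a planted linear relative drift.

    Returns (times_ps, energy, planted relative drift over the run).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, duration_ps, n_points)
    drift = mean_energy * spec.drift_rate * (t / duration_ps)
    e = mean_energy + drift + rng.normal(0.0, noise_sd, n_points)
    return t, e, spec.drift_rate
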