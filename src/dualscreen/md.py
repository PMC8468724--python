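"""Molecular-dynamics post-analysis statistics.

Operates on plain coordinate arrays (frames × atoms × 3, Å) with an atom
table carrying residue labels and hydrogen-bond role flags, or on
GROMACS-style XVG/XPM text outputs (see :mod:`dualscreen.gmxio`).

Provided statistics: total-energy drift check, per-residue RMSF (with
optional least-squares frame superposition), ligand–residue minimum
distance series and within-cutoff fractions, kernel-density distance
distributions, geometric hydrogen-bond detection (donor–acceptor distance
≤ 3.5 Å and H–donor–acceptor angle ≤ 30°, the defaults of gmx hbond),
per-residue occupancy and simultaneity fractions, and time-binned H-bond
counts for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "Trajectory",
    "HBond",
    "HBondMatrix",
    "DistanceSeries",
    "DriftResult",
    "energy_drift",
    "superpose_frames",
    "rmsf",
    "min_distance_series",
    "fraction_within",
    "distance_distribution",
    "detect_hbonds",
    "occupancy_stats",
    "binned_hbond_counts",
]

HBOND_R_CUT = 3.5       # Å, donor–acceptor distance
HBOND_ANGLE_CUT = 30.0  # degrees, hydrogen–donor–acceptor angle

ATOM_COLUMNS = [
    "atom_id", "residue_id", "residue_name", "chain", "element",
    "is_donor", "is_acceptor", "is_ligand", "parent_donor",
]


@dataclass
class Trajectory:
    """Coordinates over time plus an atom table with roles.

    ``atoms`` columns: atom_id, residue_id, residue_name, chain, element,
    is_donor, is_acceptor, is_ligand, parent_donor (atom_id of the donor a
    hydrogen is bonded to; <0 for non-hydrogens). Times in ps, coordinates
    in Å.
    """

    times: np.ndarray           # (F,)
    coords: np.ndarray          # (F, A, 3)
    atoms: pd.DataFrame

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] != len(self.times):
            raise ValueError("coords must be (frames, atoms, 3) matching times")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table does not match coordinate atom count")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def residue_label(self, i: int) -> str:
        row = self.atoms.iloc[i]
        return f"{row['chain']}:{row['residue_name']}:{row['residue_id']}"


@dataclass
class HBond:
    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    donor_residue: str
    acceptor_residue: str
    partner_residue: str  # the non-ligand side; grouping key for occupancy


@dataclass
class HBondMatrix:
    """Bond identities × frames binary existence map."""

    bonds: list
    existence: np.ndarray  # (n_bonds, n_frames) in {0,1}
    times: np.ndarray | None = None

    def __post_init__(self):
        self.existence = np.asarray(self.existence, dtype=np.uint8)
        if self.existence.ndim != 2 or self.existence.shape[0] != len(self.bonds):
            raise ValueError("existence matrix shape does not match bond list")

    @property
    def n_frames(self) -> int:
        return self.existence.shape[1]


@dataclass
class DistanceSeries:
    times: np.ndarray
    d_min: np.ndarray
    reference_residue: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.d_min = np.asarray(self.d_min, dtype=float)
        if self.times.shape != self.d_min.shape:
            raise ValueError("times and distances differ in length")


@dataclass
class DriftResult:
    slope_per_ns: float
    relative_drift: float
    passed: bool
    tolerance: float


def energy_drift(
    times_ps: np.ndarray, energy: np.ndarray, rel_tolerance: float = 0.01
) -> DriftResult:
    """Least-squares total-energy drift over a run.

    A well-equilibrated NVE-like total energy should be constant; the check
    compares |slope × duration / mean energy| against ``rel_tolerance``
    (default 1%). Returns the slope per ns and the relative drift.
    """
    t = np.asarray(times_ps, dtype=float)
    e = np.asarray(energy, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 points for a drift estimate")
    if np.ptp(t) == 0:
        raise ValueError("time series is constant; cannot fit a drift")
    fit = stats.linregress(t, e)
    duration = t[-1] - t[0]
    mean_e = e.mean()
    rel = fit.slope * duration / mean_e if mean_e != 0 else np.inf
    return DriftResult(
        slope_per_ns=fit.slope * 1000.0,
        relative_drift=float(rel),
        passed=bool(abs(rel) <= rel_tolerance),
        tolerance=rel_tolerance,
    )


def _kabsch_superpose(coords: np.ndarray, fit_idx: np.ndarray) -> np.ndarray:
    """Least-squares superpose every frame onto frame 0 using ``fit_idx`` atoms."""
    out = coords.copy()
    ref = coords[0, fit_idx]
    ref_centered = ref - ref.mean(axis=0)
    for f in range(1, coords.shape[0]):
        mob = coords[f, fit_idx]
        mob_center = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, mob - mob_center)
        out[f] = rot.apply(coords[f] - mob_center) + ref.mean(axis=0)
    return out


def superpose_frames(traj: Trajectory, fit_mask: np.ndarray | None = None) -> Trajectory:
    """Remove rigid-body motion by fitting each frame onto the first.

    By default the fit uses all non-ligand atoms (for a Cα-only trajectory,
    the α-carbons of the analysed chain).
    """
    if fit_mask is None:
        fit_mask = ~traj.atoms["is_ligand"].to_numpy(dtype=bool)
    fit_idx = np.flatnonzero(fit_mask)
    if len(fit_idx) == 0:
        raise ValueError("empty superposition selection")
    return Trajectory(traj.times, _kabsch_superpose(traj.coords, fit_idx), traj.atoms)


def rmsf(
    traj: Trajectory,
    residue_ids: list | None = None,
    superpose: bool = True,
) -> pd.DataFrame:
    """Per-residue root-mean-square fluctuation (Å).

    RMSF_i = sqrt(mean over frames of |r_i(t) − <r_i>|²), averaged over the
    residue's atoms; frames are least-squares superposed onto the first
    frame by default to remove rigid-body drift.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    work = superpose_frames(traj) if superpose else traj
    atoms = work.atoms
    protein = ~atoms["is_ligand"].to_numpy(dtype=bool)
    if residue_ids is None:
        residue_ids = sorted(atoms.loc[protein, "residue_id"].unique())
    rows = []
    for rid in residue_ids:
        mask = (atoms["residue_id"] == rid) & protein
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"residue {rid!r} absent from topology")
        xyz = work.coords[:, idx, :]               # (F, a, 3)
        disp = xyz - xyz.mean(axis=0, keepdims=True)
        msf = (disp**2).sum(axis=2).mean()          # mean over frames and atoms
        rows.append({"residue_id": rid, "rmsf": float(np.sqrt(msf))})
    return pd.DataFrame(rows)


def min_distance_series(
    traj: Trajectory,
    ligand_mask: np.ndarray | None = None,
    reference_residue: str | int = 0,
) -> DistanceSeries:
    """Per-frame minimum ligand–residue distance (Å).

    ``reference_residue`` may be a residue_id or a ``chain:RES:num`` label.
    """
    atoms = traj.atoms
    if ligand_mask is None:
        ligand_mask = atoms["is_ligand"].to_numpy(dtype=bool)
    lig_idx = np.flatnonzero(ligand_mask)
    if isinstance(reference_residue, str) and ":" in reference_residue:
        chain, rname, rid = reference_residue.split(":")
        res_mask = (
            (atoms["chain"] == chain)
            & (atoms["residue_name"] == rname)
            & (atoms["residue_id"].astype(str) == rid)
        )
        label = reference_residue
    else:
        res_mask = atoms["residue_id"] == reference_residue
        label = str(reference_residue)
    res_idx = np.flatnonzero(res_mask.to_numpy())
    if len(lig_idx) == 0 or len(res_idx) == 0:
        raise ValueError("empty ligand or residue selection")
    d = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d[f] = cdist(traj.coords[f, lig_idx], traj.coords[f, res_idx]).min()
    return DistanceSeries(traj.times, d, reference_residue=label)


def fraction_within(series: DistanceSeries, cutoff: float = 5.0) -> float:
    """Fraction of frames with minimum distance strictly below ``cutoff`` Å."""
    if len(series.d_min) == 0:
        raise ValueError("empty distance series")
    return float((series.d_min < cutoff).mean())


def distance_distribution(
    series: DistanceSeries, bw_method=None, grid_size: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel-density estimate of the distance distribution.

    Returns (grid, density); the density integrates to ~1 over the padded
    support. A degenerate (zero-variance) series yields a narrow Gaussian
    centred on the repeated value.
    """
    d = np.asarray(series.d_min, dtype=float)
    if len(d) < 10:
        raise ValueError("need at least 10 points for a density estimate")
    if np.ptp(d) == 0:
        sigma = max(1e-3, 1e-3 * abs(d[0]))
        grid = np.linspace(d[0] - 6 * sigma, d[0] + 6 * sigma, grid_size)
        dens = stats.norm.pdf(grid, loc=d[0], scale=sigma)
        return grid, dens
    kde = stats.gaussian_kde(d, bw_method=bw_method)
    pad = 3 * d.std()
    grid = np.linspace(d.min() - pad, d.max() + pad, grid_size)
    return grid, kde(grid)


def _candidate_triples(atoms: pd.DataFrame, ligand_protein_only: bool):
    """(donor, hydrogen, acceptor) index triples from role annotations."""
    donors = atoms.index[atoms["is_donor"].astype(bool)].to_numpy()
    acceptors = atoms.index[atoms["is_acceptor"].astype(bool)].to_numpy()
    hydrogens_by_donor: dict[int, list[int]] = {}
    parent = atoms["parent_donor"].to_numpy()
    atom_ids = atoms["atom_id"].to_numpy()
    id_to_idx = {int(a): i for i, a in enumerate(atom_ids)}
    for i, p in enumerate(parent):
        if p is not None and int(p) >= 0:
            hydrogens_by_donor.setdefault(id_to_idx[int(p)], []).append(i)
    is_lig = atoms["is_ligand"].to_numpy(dtype=bool)
    triples = []
    for d in donors:
        hs = hydrogens_by_donor.get(int(d))
        if not hs:
            raise ValueError(
                f"donor atom {atoms.loc[d, 'atom_id']} has no attached hydrogen"
            )
        for a in acceptors:
            if a == d:
                continue
            if ligand_protein_only and is_lig[d] == is_lig[a]:
                continue
            for h in hs:
                triples.append((int(d), int(h), int(a)))
    return triples


def detect_hbonds(
    traj: Trajectory,
    r_cut: float = HBOND_R_CUT,
    angle_cut: float = HBOND_ANGLE_CUT,
    ligand_protein_only: bool = True,
) -> HBondMatrix:
    """Geometric hydrogen-bond detection over all frames.

    A bond (D, H, A) exists in a frame iff the donor–acceptor distance is
    ≤ ``r_cut`` and the H–D–A angle is ≤ ``angle_cut`` degrees (gmx hbond's
    default criterion). Only triples bonded in at least one frame are kept.
    With ``ligand_protein_only`` (default) one side must be the ligand.
    """
    triples = _candidate_triples(traj.atoms.reset_index(drop=True), ligand_protein_only)
    if not triples:
        return HBondMatrix([], np.zeros((0, traj.n_frames), dtype=np.uint8), traj.times)
    t = np.array(triples)  # (n, 3): donor, hydrogen, acceptor
    D = traj.coords[:, t[:, 0], :]
    H = traj.coords[:, t[:, 1], :]
    A = traj.coords[:, t[:, 2], :]
    da = A - D
    dh = H - D
    dist = np.linalg.norm(da, axis=2)
    cosang = (da * dh).sum(axis=2) / (
        np.linalg.norm(da, axis=2) * np.linalg.norm(dh, axis=2)
    )
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    exists = ((dist <= r_cut) & (angle <= angle_cut)).T  # (n_triples, F)
    keep = exists.any(axis=1)
    is_lig = traj.atoms["is_ligand"].to_numpy(dtype=bool)
    bonds = []
    for (d, h, a) in t[keep]:
        d_res = traj.residue_label(d)
        a_res = traj.residue_label(a)
        partner = a_res if is_lig[d] else d_res if is_lig[a] else a_res
        bonds.append(
            HBond(
                donor_atom=int(traj.atoms.iloc[d]["atom_id"]),
                hydrogen_atom=int(traj.atoms.iloc[h]["atom_id"]),
                acceptor_atom=int(traj.atoms.iloc[a]["atom_id"]),
                donor_residue=d_res,
                acceptor_residue=a_res,
                partner_residue=partner,
            )
        )
    return HBondMatrix(bonds, exists[keep].astype(np.uint8), traj.times)


@dataclass
class OccupancyStats:
    per_residue: dict           # residue label -> occupancy fraction
    frac_at_least_one: float    # frames with >=1 bond
    frac_at_least_two: float    # frames with bonds to >=2 distinct residues


def occupancy_stats(matrix: HBondMatrix) -> OccupancyStats:
    """Per-residue occupancy and bond-simultaneity fractions.

    Occupancy of a residue = fraction of frames with any bond involving that
    residue (grouping by each bond's partner residue). Simultaneity counts
    distinct partner residues per frame.
    """
    if matrix.n_frames == 0:
        raise ValueError("empty H-bond matrix")
    residues = sorted({b.partner_residue for b in matrix.bonds})
    F = matrix.n_frames
    per_res_any = {}
    res_rows = np.zeros((len(residues), F), dtype=bool)
    for i, res in enumerate(residues):
        idx = [j for j, b in enumerate(matrix.bonds) if b.partner_residue == res]
        res_rows[i] = matrix.existence[idx].any(axis=0)
        per_res_any[res] = float(res_rows[i].mean())
    n_res_per_frame = res_rows.sum(axis=0)
    return OccupancyStats(
        per_residue=per_res_any,
        frac_at_least_one=float((n_res_per_frame >= 1).mean()),
        frac_at_least_two=float((n_res_per_frame >= 2).mean()),
    )


def binned_hbond_counts(
    matrix: HBondMatrix, bin_width_ns: float, times_ps: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-residue, per-time-bin bonded-frame counts with heatmap categories.

    Categories: ``<10`` strictly below 10 bonded frames, ``10-20`` inclusive,
    ``>20`` strictly above. The bin width must be a multiple of the frame
    spacing and divide the run length to within one frame.
    """
    times = np.asarray(times_ps if times_ps is not None else matrix.times, dtype=float)
    if times is None or len(times) != matrix.n_frames:
        raise ValueError("frame times are required and must match the matrix")
    spacing = np.diff(times)
    dt = spacing[0]
    bin_ps = bin_width_ns * 1000.0
    if bin_ps < dt:
        raise ValueError("bin width is smaller than the frame spacing")
    duration = times[-1] - times[0] + dt
    n_bins = int(round(duration / bin_ps))
    if abs(n_bins * bin_ps - duration) > dt:
        raise ValueError("bin width does not divide the run length within one frame")
    bin_index = np.minimum(((times - times[0]) / bin_ps).astype(int), n_bins - 1)
    residues = sorted({b.partner_residue for b in matrix.bonds})
    rows = []
    for res in residues:
        idx = [j for j, b in enumerate(matrix.bonds) if b.partner_residue == res]
        bonded = matrix.existence[idx].any(axis=0)
        for b in range(n_bins):
            count = int(bonded[bin_index == b].sum())
            category = "<10" if count < 10 else ("10-20" if count <= 20 else ">20")
            rows.append({"residue": res, "bin": b, "count": count, "category": category})
    return pd.DataFrame(rows, columns=["residue", "bin", "count", "category"])
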