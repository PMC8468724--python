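"""Text I/O: GROMACS-style XVG/XPM dialects and delimited matrix formats.

XVG files are whitespace-column tables with ``#`` comment lines and ``@``
plot-directive lines (title, axis labels, legends).  XPM files are C-like
pixmap text: a header string ``"ncols nrows ncolors chars_per_pixel"``,
one colour line per level mapping a character to a colour with the value
in a trailing ``/* "value" */`` comment, then one quoted string per row.
Both writers round-trip losslessly through the corresponding reader for
binary matrices.

Delimited (CSV) round-trips are provided for ContactMatrix and
HBondMatrix, plus a simple ``frame,atom,x,y,z`` trajectory format with a
separate atom table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .md import HBond, HBondMatrix, Trajectory, ATOM_COLUMNS
from .plif import ContactMatrix

__all__ = [
    "XVGData",
    "load_xvg",
    "write_xvg",
    "load_xpm",
    "write_xpm",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_hbond_matrix",
    "write_hbond_matrix",
    "read_trajectory",
    "write_trajectory",
]


class ParseError(ValueError):
    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# XVG

@dataclass
class XVGData:
    """Columns of an XVG file plus its comment/legend metadata."""

    data: np.ndarray                 # (n_rows, n_cols)
    comments: list = field(default_factory=list)   # '#' lines
    directives: list = field(default_factory=list)  # '@' lines

    @property
    def times(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def values(self) -> np.ndarray:
        return self.data[:, 1] if self.data.shape[1] > 1 else self.data[:, 0]


def load_xvg(path) -> XVGData:
    """Read an XVG time series, preserving comment and directive lines."""
    comments, directives, rows = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                comments.append(line)
            elif line.lstrip().startswith("@"):
                directives.append(line)
            else:
                try:
                    rows.append([float(x) for x in line.split()])
                except ValueError as exc:
                    raise ParseError(path, lineno, f"bad data line: {exc}")
    if not rows:
        raise ParseError(path, 0, "no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(path, 0, f"inconsistent column counts: {sorted(widths)}")
    return XVGData(np.array(rows), comments, directives)


def write_xvg(path, data: np.ndarray, title: str = "", labels: tuple = ("Time (ps)", "Value")) -> None:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    with open(path, "w") as fh:
        fh.write(f"# generated by dualscreen\n")
        if title:
            fh.write(f'@    title "{title}"\n')
        fh.write(f'@    xaxis  label "{labels[0]}"\n')
        fh.write(f'@    yaxis  label "{labels[1]}"\n')
        for row in data:
            fh.write("  ".join(f"{v:.8g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# XPM

#: palette characters for XPM levels, GROMACS-style
_XPM_CHARS = "o+ABCDEFGHIJKLMNPQRSTUVWXYZabcdefghijklmnpqrstuvwxyz0123456789"

_QUOTED = re.compile(r'"([^"]*)"')
_VALUE_COMMENT = re.compile(r'/\*\s*"([^"]*)"\s*\*/')


def write_xpm(path, matrix: np.ndarray, title: str = "", row_labels=None, col_labels=None) -> None:
    """Write an integer matrix as GROMACS-flavoured XPM text.

    Each distinct value gets one palette character; the value is recorded in
    the colour line's trailing ``/* "value" */`` legend comment, which is what
    the reader uses to decode. Supports up to 62 distinct levels.
    """
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ValueError("XPM matrices must be 2-D")
    levels = sorted(set(np.unique(m).tolist()))
    if len(levels) > len(_XPM_CHARS):
        raise ValueError(f"too many distinct values for XPM palette: {len(levels)}")
    if len(levels) == 1:
        levels = levels  # single-level matrices are fine
    char_of = {v: _XPM_CHARS[i] for i, v in enumerate(levels)}
    nrows, ncols = m.shape
    with open(path, "w") as fh:
        fh.write(f'/* XPM */\n/* title: "{title}" */\n')
        if row_labels is not None:
            fh.write(f'/* rows: {",".join(str(r) for r in row_labels)} */\n')
        if col_labels is not None:
            fh.write(f'/* cols: {",".join(str(c) for c in col_labels)} */\n')
        fh.write("static char *matrix[] = {\n")
        fh.write(f'"{ncols} {nrows} {len(levels)} 1",\n')
        for v in levels:
            fh.write(f'"{char_of[v]}  c #FFFFFF " /* "{v}" */,\n')
        for i in range(nrows):
            line = "".join(char_of[v] for v in m[i])
            sep = "," if i < nrows - 1 else ""
            fh.write(f'"{line}"{sep}\n')
        fh.write("};\n")


def load_xpm(path) -> dict:
    """Read an XPM pixmap into an integer matrix.

    Returns ``{"matrix", "title", "row_labels", "col_labels"}``. Characters
    are decoded through the per-colour ``/* "value" */`` legend comments;
    legend strings that are not numeric are mapped to consecutive integers.
    """
    title, row_labels, col_labels = "", None, None
    header = None
    colors: dict[str, str] = {}
    rows: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("/*"):
                if "title:" in line:
                    m = _QUOTED.search(line)
                    title = m.group(1) if m else ""
                elif line.startswith("/* rows:"):
                    row_labels = line[len("/* rows:"):].rstrip("*/ ").strip().split(",")
                elif line.startswith("/* cols:"):
                    col_labels = line[len("/* cols:"):].rstrip("*/ ").strip().split(",")
                continue
            m = _QUOTED.search(line)
            if not m:
                continue
            content = m.group(1)
            if header is None:
                parts = content.split()
                if len(parts) != 4:
                    raise ParseError(path, lineno, f"malformed XPM header: {content!r}")
                ncols, nrows, nlevels, cpp = (int(p) for p in parts)
                if cpp != 1:
                    raise ParseError(path, lineno, "only 1 char per pixel supported")
                header = (ncols, nrows, nlevels)
            elif len(colors) < header[2]:
                vm = _VALUE_COMMENT.search(line)
                value = vm.group(1) if vm else content.split()[-1]
                colors[content[0]] = value
            else:
                rows.append(content)
    if header is None:
        raise ParseError(path, 0, "no XPM header found")
    ncols, nrows, _ = header
    if len(rows) != nrows:
        raise ParseError(path, 0, f"expected {nrows} pixel rows, found {len(rows)}")
    try:
        decode = {c: int(float(v)) for c, v in colors.items()}
    except ValueError:
        decode = {c: i for i, c in enumerate(colors)}
    matrix = np.empty((nrows, ncols), dtype=int)
    for i, r in enumerate(rows):
        if len(r) != ncols:
            raise ParseError(path, 0, f"pixel row {i} has length {len(r)}, expected {ncols}")
        matrix[i] = [decode[c] for c in r]
    return {"matrix": matrix, "title": title, "row_labels": row_labels, "col_labels": col_labels}


# ---------------------------------------------------------------------------
# Contact matrices (delimited)

_META_COLS = ("docking_score", "n_heavy_atoms", "label")


def write_contact_matrix(matrix: ContactMatrix, path) -> None:
    """Contact matrix as CSV: compound_id, one column per residue label,
    then optional docking_score / n_heavy_atoms / label columns."""
    df = pd.DataFrame(matrix.contacts, columns=matrix.residues)
    df.insert(0, "compound_id", matrix.compound_ids)
    if matrix.docking_score is not None:
        df["docking_score"] = matrix.docking_score
    if matrix.n_heavy_atoms is not None:
        df["n_heavy_atoms"] = matrix.n_heavy_atoms
    if matrix.labels is not None:
        df["label"] = matrix.labels
    df.to_csv(path, index=False)


def read_contact_matrix(path, sep: str | None = None) -> ContactMatrix:
    df = pd.read_csv(path, sep=sep, engine="python")
    residues = [c for c in df.columns if c not in ("compound_id",) + _META_COLS]
    return ContactMatrix(
        compound_ids=df["compound_id"].astype(str).tolist(),
        residues=residues,
        contacts=df[residues].to_numpy(dtype=np.uint8),
        docking_score=df["docking_score"].to_numpy() if "docking_score" in df else None,
        n_heavy_atoms=df["n_heavy_atoms"].to_numpy() if "n_heavy_atoms" in df else None,
        labels=df["label"].tolist() if "label" in df else None,
    )


# ---------------------------------------------------------------------------
# H-bond matrices (delimited)

def write_hbond_matrix(matrix: HBondMatrix, path) -> None:
    """H-bond existence matrix as CSV: bond identity columns then one column
    per frame (f0, f1, ...)."""
    meta = pd.DataFrame(
        [
            {
                "donor_atom": b.donor_atom,
                "hydrogen_atom": b.hydrogen_atom,
                "acceptor_atom": b.acceptor_atom,
                "donor_residue": b.donor_residue,
                "acceptor_residue": b.acceptor_residue,
                "partner_residue": b.partner_residue,
            }
            for b in matrix.bonds
        ]
    )
    frames = pd.DataFrame(
        matrix.existence, columns=[f"f{i}" for i in range(matrix.n_frames)]
    )
    pd.concat([meta, frames], axis=1).to_csv(path, index=False)


def read_hbond_matrix(path, sep: str | None = None) -> HBondMatrix:
    df = pd.read_csv(path, sep=sep, engine="python")
    frame_cols = [c for c in df.columns if re.fullmatch(r"f\d+", c)]
    frame_cols.sort(key=lambda c: int(c[1:]))
    bonds = [
        HBond(
            donor_atom=int(r["donor_atom"]),
            hydrogen_atom=int(r["hydrogen_atom"]),
            acceptor_atom=int(r["acceptor_atom"]),
            donor_residue=str(r["donor_residue"]),
            acceptor_residue=str(r["acceptor_residue"]),
            partner_residue=str(r["partner_residue"]),
        )
        for _, r in df.iterrows()
    ]
    return HBondMatrix(bonds, df[frame_cols].to_numpy(dtype=np.uint8))


# ---------------------------------------------------------------------------
# Trajectories (delimited)

def write_trajectory(traj: Trajectory, coords_path, atoms_path) -> None:
    """Coordinates as ``frame,time_ps,atom_id,x,y,z`` plus a separate atom table."""
    F, A, _ = traj.coords.shape
    atom_ids = traj.atoms["atom_id"].to_numpy()
    rec = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(F), A),
            "time_ps": np.repeat(traj.times, A),
            "atom_id": np.tile(atom_ids, F),
            "x": traj.coords[:, :, 0].ravel(),
            "y": traj.coords[:, :, 1].ravel(),
            "z": traj.coords[:, :, 2].ravel(),
        }
    )
    rec.to_csv(coords_path, index=False)
    traj.atoms[ATOM_COLUMNS].to_csv(atoms_path, index=False)


def read_trajectory(coords_path, atoms_path) -> Trajectory:
    atoms = pd.read_csv(atoms_path)
    rec = pd.read_csv(coords_path)
    frames = np.sort(rec["frame"].unique())
    order = {a: i for i, a in enumerate(atoms["atom_id"])}
    F, A = len(frames), len(atoms)
    coords = np.empty((F, A, 3))
    times = np.empty(F)
    for fi, f in enumerate(frames):
        sub = rec[rec["frame"] == f]
        times[fi] = sub["time_ps"].iloc[0]
        idx = sub["atom_id"].map(order).to_numpy()
        coords[fi, idx] = sub[["x", "y", "z"]].to_numpy()
    return Trajectory(times, coords, atoms)
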