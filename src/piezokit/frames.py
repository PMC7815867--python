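"""Trajectory containers, readers/writers and atom selections.

``FrameSeries`` is the common in-memory currency: a pandas atom table
plus per-frame coordinates (Å), times (ns) and orthorhombic box
dimensions.  Structure formats (PDB, GRO, XYZ; multi-model PDB as
frames) are read through MDAnalysis; the package's own columnar TSV
format (one row per frame x atom, human-readable) is round-trippable
and is what the synthetic generators write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FrameSeries",
    "Selection",
    "SelectionError",
    "sel_and",
    "sel_or",
    "sel_not",
    "read_frames",
    "write_frames",
    "resolve_selection",
]

COLUMNAR_COLUMNS = [
    "frame", "time_ns", "atom_id", "name", "resid", "resname", "segment",
    "charge_e", "x", "y", "z", "box_x", "box_y", "box_z",
]


class SelectionError(ValueError):
    pass


@dataclass
class FrameSeries:
    """Atom table + per-frame coordinates/boxes.

    atoms: DataFrame with columns atom_id, name, resid, resname,
    segment, charge_e.  coords: (F, N, 3) Å.  boxes: (F, 3) Å.
    """

    atoms: pd.DataFrame
    times: np.ndarray
    coords: np.ndarray
    boxes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.coords = np.asarray(self.coords, float)
        self.boxes = np.asarray(self.boxes, float)
        F, N = len(self.times), len(self.atoms)
        if self.coords.shape != (F, N, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{F} frames x {N} atoms"
            )
        if self.boxes.shape != (F, 3):
            raise ValueError("boxes must be (F, 3)")
        if F > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.boxes <= 0):
            raise ValueError("box dimensions must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def frame_coords(self, indices, frame: int | None = None):
        """Coordinates of the given atom indices, one frame or all."""
        if frame is not None:
            return self.coords[frame][indices]
        return [self.coords[f][indices] for f in range(self.n_frames)]


@dataclass(frozen=True)
class Selection:
    """Atom selection: AND over the given fields; combinable.

    ``resids`` accepts ints and (lo, hi) inclusive ranges.  ``op`` /
    ``parts`` implement and/or/not combinators (use sel_and, sel_or,
    sel_not rather than building these directly).
    """

    resids: tuple = ()
    resnames: tuple = ()
    names: tuple = ()
    segments: tuple = ()
    op: str = "leaf"
    parts: tuple = field(default_factory=tuple)

    def mask(self, atoms: pd.DataFrame) -> np.ndarray:
        if self.op == "and":
            m = np.ones(len(atoms), bool)
            for p in self.parts:
                m &= p.mask(atoms)
            return m
        if self.op == "or":
            m = np.zeros(len(atoms), bool)
            for p in self.parts:
                m |= p.mask(atoms)
            return m
        if self.op == "not":
            return ~self.parts[0].mask(atoms)
        m = np.ones(len(atoms), bool)
        if self.resids:
            rm = np.zeros(len(atoms), bool)
            resid = atoms["resid"].to_numpy()
            for r in self.resids:
                if isinstance(r, tuple):
                    rm |= (resid >= r[0]) & (resid <= r[1])
                else:
                    rm |= resid == r
            m &= rm
        if self.resnames:
            m &= atoms["resname"].isin(self.resnames).to_numpy()
        if self.names:
            m &= atoms["name"].isin(self.names).to_numpy()
        if self.segments:
            m &= atoms["segment"].isin(self.segments).to_numpy()
        return m


def sel_and(*parts: Selection) -> Selection:
    return Selection(op="and", parts=tuple(parts))


def sel_or(*parts: Selection) -> Selection:
    return Selection(op="or", parts=tuple(parts))


def sel_not(part: Selection) -> Selection:
    return Selection(op="not", parts=(part,))


def resolve_selection(series: FrameSeries, spec: Selection) -> np.ndarray:
    """Deterministic, order-stable atom index array for a selection."""
    idx = np.flatnonzero(spec.mask(series.atoms))
    if len(idx) == 0:
        raise SelectionError(f"selection matched no atoms: {spec}")
    return idx


def _read_columnar(path) -> FrameSeries:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COLUMNAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    frames = np.sort(df["frame"].unique())
    counts = df.groupby("frame").size()
    if counts.nunique() != 1:
        raise ValueError(f"{path}: inconsistent atom counts across frames")
    first = df[df["frame"] == frames[0]].sort_values("atom_id")
    atoms = first[["atom_id", "name", "resid", "resname", "segment", "charge_e"]]
    atoms = atoms.reset_index(drop=True)
    atoms["segment"] = atoms["segment"].fillna("")
    F, N = len(frames), len(atoms)
    coords = np.empty((F, N, 3))
    times = np.empty(F)
    boxes = np.empty((F, 3))
    for i, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values("atom_id")
        if not np.array_equal(sub["atom_id"].to_numpy(), atoms["atom_id"].to_numpy()):
            raise ValueError(f"{path}: atom ids differ in frame {f}")
        coords[i] = sub[["x", "y", "z"]].to_numpy()
        times[i] = sub["time_ns"].iloc[0]
        boxes[i] = sub[["box_x", "box_y", "box_z"]].iloc[0].to_numpy()
    return FrameSeries(atoms=atoms, times=times, coords=coords, boxes=boxes)


def _read_mda(paths, fmt: str) -> FrameSeries:
    import MDAnalysis as mda

    with np.errstate(all="ignore"):
        u = mda.Universe(*[str(p) for p in paths])
    ag = u.atoms
    n = len(ag)

    def attr(name, default):
        try:
            return getattr(ag, name)
        except Exception:
            return np.full(n, default)

    atoms = pd.DataFrame(
        {
            "atom_id": np.arange(1, n + 1),
            "name": attr("names", "X"),
            "resid": np.asarray(attr("resids", 0), int),
            "resname": attr("resnames", "UNK"),
            "segment": attr("segids", ""),
            "charge_e": np.asarray(attr("charges", 0.0), float),
        }
    )
    coords, times, boxes = [], [], []
    for k, ts in enumerate(u.trajectory):
        coords.append(ag.positions.copy())
        t = getattr(ts, "time", None)
        times.append(float(t) / 1000.0 if t else float(k))  # MDAnalysis ps -> ns
        dims = ts.dimensions
        if dims is not None and np.all(dims[:3] > 0):
            if not np.allclose(dims[3:6], 90.0, atol=1e-3):
                raise ValueError("triclinic boxes are unsupported")
            boxes.append(dims[:3].copy())
        else:
            span = ag.positions.max(axis=0) - ag.positions.min(axis=0) + 1.0
            boxes.append(span)
    times = np.asarray(times, float)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(len(times), dtype=float)
    return FrameSeries(
        atoms=atoms, times=times, coords=np.asarray(coords), boxes=np.asarray(boxes)
    )


def read_frames(paths, fmt: str | None = None) -> FrameSeries:
    """Read trajectory frames into a FrameSeries.

    ``fmt`` is one of pdb | gro | xyz | columnar, inferred from the
    first path's extension when omitted.  Coordinates are in Å on
    return (MDAnalysis converts GRO's nm itself).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(str(p))
    if fmt is None:
        ext = paths[0].suffix.lower().lstrip(".")
        fmt = {"tsv": "columnar", "csv": "columnar"}.get(ext, ext)
    fmt = fmt.lower()
    if fmt == "columnar":
        if len(paths) != 1:
            raise ValueError("columnar format expects a single file")
        return _read_columnar(paths[0])
    if fmt in ("pdb", "gro", "xyz"):
        return _read_mda(paths, fmt)
    raise ValueError(f"unknown format {fmt!r}")


def write_frames(series: FrameSeries, path) -> None:
    """Write a FrameSeries in the columnar TSV format."""
    rows = []
    a = series.atoms
    for f in range(series.n_frames):
        df = a.copy()
        df.insert(0, "frame", f)
        df.insert(1, "time_ns", series.times[f])
        df[["x", "y", "z"]] = series.coords[f]
        df[["box_x", "box_y", "box_z"]] = np.tile(series.boxes[f], (len(a), 1))
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)[COLUMNAR_COLUMNS]
    out.to_csv(path, sep="\t", index=False)
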