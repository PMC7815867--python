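"""Geometric order parameters of the channel from coordinate frames.

Covers the gate-triad centroid distances (the V2476 choke point of the
trimeric pore), dome radius and dome-dome distance under periodic
boundaries, arm flattening angle beta against the channel's internal
axis, rigid in-plane rotation of a domain about that axis (cap
rotation), minimum residue-pair distance series, and the leaflet area
fraction occupied by the protein.  Lengths in Å, angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "TriadDistances",
    "DomeGeometry",
    "centroid_distances",
    "dome_geometry",
    "arm_flattening_angle",
    "rotation_about_axis",
    "pair_distance_series",
    "leaflet_area_fraction",
]


@dataclass(frozen=True)
class TriadDistances:
    """Sorted distances of three marker atoms to their centroid, Å."""

    d_min: float
    d_median: float
    d_max: float


@dataclass(frozen=True)
class DomeGeometry:
    """Dome radius and dome-dome (image) distances in a periodic box, Å.

    ``r`` is the mean centroid distance of the outer-helix COM triangle;
    R_x = box_x - 2r and R_y = box_y - 2r are the edge-to-edge distances
    to the nearest periodic image.  Negative R (overlapping domes) is
    permitted but flagged.
    """

    r: float
    box_x: float
    box_y: float
    R_x: float
    R_y: float
    overlapping: bool


def centroid_distances(p1, p2, p3) -> TriadDistances:
    """Distances from three points to their centroid, sorted ascending."""
    pts = np.asarray([p1, p2, p3], float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    c = pts.mean(axis=0)
    d = np.sort(np.linalg.norm(pts - c, axis=1))
    return TriadDistances(float(d[0]), float(d[1]), float(d[2]))


def dome_geometry(outer_helix_coms, box) -> DomeGeometry:
    """Dome radius and dome-dome distances from the outer-helix COM triad."""
    box_x, box_y = float(box[0]), float(box[1])
    if box_x <= 0 or box_y <= 0:
        raise ValueError("box dimensions must be positive")
    td = centroid_distances(*np.asarray(outer_helix_coms, float))
    r = (td.d_min + td.d_median + td.d_max) / 3.0
    R_x, R_y = box_x - 2 * r, box_y - 2 * r
    return DomeGeometry(
        r=r, box_x=box_x, box_y=box_y, R_x=R_x, R_y=R_y,
        overlapping=bool(R_x <= 0 or R_y <= 0),
    )


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    q = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    return vt[0]


def arm_flattening_angle(beam_coords, cap_com, ctd_com) -> float:
    """Angle beta (degrees) between a beam and the channel internal axis.

    The internal axis points from the C-terminal-domain COM to the cap
    COM.  The beam direction is the dominant principal axis of the beam
    atom cloud, oriented from its pore-proximal end (first coordinate
    row) towards its distal end (last row).
    """
    beam = np.asarray(beam_coords, float)
    if len(beam) < 2:
        raise ValueError("need at least 2 beam points")
    axis = np.asarray(cap_com, float) - np.asarray(ctd_com, float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("cap and CTD centres of mass coincide")
    axis = axis / n
    v = _principal_axis(beam)
    if np.dot(v, beam[-1] - beam[0]) < 0:  # orient proximal -> distal
        v = -v
    cosb = float(np.clip(np.dot(v, axis), -1.0, 1.0))
    return math.degrees(math.acos(cosb))


def rotation_about_axis(
    coords_ref, coords_t, axis, pivot, sign: str = "ccw_from_plus"
) -> float:
    """Best-fit in-plane rotation angle (degrees, signed) about an axis.

    Projects pivot-centred coordinates of both frames onto the plane
    normal to ``axis`` and solves the least-squares 2D rotation that
    superposes the reference onto the target.  With the default sign
    convention a target generated by the right-handed rotation matrix
    R(+phi) about +axis yields +phi (counterclockwise viewed from the
    +axis side); ``sign='cw_from_plus'`` flips it.
    """
    a = np.asarray(coords_ref, float)
    b = np.asarray(coords_t, float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("frames must have the same (N>=2, 3) shape")
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    pivot = np.asarray(pivot, float)
    # orthonormal in-plane basis (e1, e2, axis) right-handed
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, axis)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = trial - np.dot(trial, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    P = np.vstack([e1, e2])
    ua = (a - pivot) @ P.T
    ub = (b - pivot) @ P.T
    if np.max(np.linalg.norm(ua, axis=1)) < 1e-9:
        raise ValueError("all atoms lie on the rotation axis")
    num = float(np.sum(ua[:, 0] * ub[:, 1] - ua[:, 1] * ub[:, 0]))
    den = float(np.sum(ua[:, 0] * ub[:, 0] + ua[:, 1] * ub[:, 1]))
    phi = math.degrees(math.atan2(num, den))
    if sign == "cw_from_plus":
        phi = -phi
    elif sign != "ccw_from_plus":
        raise ValueError(f"unknown sign convention {sign!r}")
    return phi


def pair_distance_series(frames_a, frames_b) -> np.ndarray:
    """Per-frame minimum distance between two atom selections, Å.

    ``frames_a`` and ``frames_b`` are sequences (one entry per frame) of
    (N,3)/(M,3) coordinate arrays, e.g. the Cβ atoms of two cross-linking
    residues across subunits.
    """
    frames_a, frames_b = list(frames_a), list(frames_b)
    if len(frames_a) != len(frames_b):
        raise ValueError("selections must cover the same frames")
    out = np.empty(len(frames_a))
    for i, (ca, cb) in enumerate(zip(frames_a, frames_b)):
        ca = np.atleast_2d(np.asarray(ca, float))
        cb = np.atleast_2d(np.asarray(cb, float))
        if ca.size == 0 or cb.size == 0:
            raise ValueError(f"empty selection at frame {i}")
        out[i] = cdist(ca, cb).min()
    return out


def leaflet_area_fraction(
    n_lipids: int, area_per_lipid: float, box_xy_area: float
) -> float:
    """Fraction of the leaflet area occupied by protein.

    1 - n*APL/box_area: the lipid-covered area is subtracted from the
    periodic box cross-section; the remainder is attributed to protein.
    """
    if n_lipids < 0 or area_per_lipid <= 0 or box_xy_area <= 0:
        raise ValueError("inputs must be positive")
    lipid_area = n_lipids * area_per_lipid
    if lipid_area > box_xy_area:
        raise ValueError("lipid area exceeds box area")
    return 1.0 - lipid_area / box_xy_area
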