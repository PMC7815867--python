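"""Synthetic-data generators with the statistical structure each
analysis stage assumes.

These stand in for microsecond-scale MD trajectories: a Gaussian-dome
bilayer point cloud with additive height noise, drift-diffusion ion
passages through a bounded cylindrical pore (emulating permeation under
an applied field), autocorrelated binary lipid-contact series, and
tabulated overlapping tanh footprint surfaces used as the geometric
oracle for the footprint model.  Every generator is deterministic given
its spec and seed and returns a ground-truth record alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dome import DomeModel2D
from .footprint import intersection_angle  # noqa: F401  (re-export convenience)
from .permeation import IonTrace, PoreRegion

__all__ = [
    "MembraneCloudSpec",
    "IonSimSpec",
    "ContactSeriesSpec",
    "gen_membrane_cloud",
    "gen_ion_traces",
    "gen_contact_series",
    "gen_footprint_surfaces",
]


@dataclass(frozen=True)
class MembraneCloudSpec:
    """Leaflet headgroup cloud sampled from a known dome surface.

    Defaults emulate the lower leaflet of a ~250x250 Å patch bent by a
    ~60 Å-deep dome with ~1 Å headgroup height noise.
    """

    dome: DomeModel2D
    n_points: int = 5000
    box_xy: tuple[float, float] = (250.0, 250.0)
    noise_sigma: float = 1.0
    exclusion_radius: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class IonSimSpec:
    """Drift-diffusion ion passages through a cylindrical pore region.

    Ions are injected as a Poisson process at the upstream reservoir
    plane (``reservoir`` Å beyond the entry boundary; both planes at
    half rate when drift is zero), undergo overdamped Euler-Maruyama
    drift-diffusion in z with an Ornstein-Uhlenbeck lateral confinement
    reflected at the radial cutoff, and are removed at the far walls.
    Defaults echo the in-silico patch-clamp geometry: a 10 Å slab
    (56 < z < 66 Å) with a 35 Å cylindrical restraint, sampled every
    0.1 ns for 100 ns per voltage.
    """

    region: PoreRegion = field(
        default_factory=lambda: PoreRegion(z_lo=56.0, z_hi=66.0, radial_cutoff=35.0)
    )
    D_coeff: float = 1.0  # Å^2/ns
    drift_velocity: float = 1.0  # Å/ns, sign encodes voltage polarity
    n_ions: int | None = None  # cap on injected ions (None = unlimited)
    dt: float = 0.1  # ns
    duration: float = 100.0  # ns
    injection_rate: float = 1.0  # ions/ns at the upstream reservoir
    reservoir: float = 10.0  # Å beyond each axial boundary
    species: str = "K+"
    charge: float = 1.0  # elementary charges
    ou_sigma: float | None = None  # lateral stationary SD, default cutoff/4
    ou_tau: float = 1.0  # ns
    drain: bool = False  # keep simulating past `duration` until ions exit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.D_coeff < 0:
            raise ValueError("D_coeff must be non-negative")
        if abs(self.drift_velocity) * self.dt > self.region.length / 4:
            raise ValueError(
                "dt too large: drift per step exceeds a quarter of the slab "
                "(event-skipping risk)"
            )


@dataclass(frozen=True)
class ContactSeriesSpec:
    """Two-state Markov lipid-contact series.

    ``persistence`` is the frame-to-frame stay probability of the
    contact (on) state; ``p_on`` the stationary contact probability.
    """

    p_on: float
    persistence: float
    n_frames: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_on <= 1.0:
            raise ValueError("p_on must lie in [0, 1]")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")


def gen_membrane_cloud(spec: MembraneCloudSpec):
    """Sample an (N,3) headgroup cloud from the spec's dome surface.

    xy is uniform over the box minus an optional exclusion disk at the
    dome peak (the protein's own area); z is the dome model plus iid
    Gaussian noise.  Returns ``(points, truth_dome)``.
    """
    bx, by = spec.box_xy
    r_ex = spec.exclusion_radius
    if r_ex > 0 and r_ex**2 >= (bx / 2) ** 2 + (by / 2) ** 2:
        raise ValueError("exclusion disk covers the whole box")
    rng = np.random.default_rng(spec.seed)
    pts = np.empty((spec.n_points, 2))
    filled = 0
    mu = spec.dome.mu
    while filled < spec.n_points:
        n_draw = int((spec.n_points - filled) * 1.5) + 16
        xy = rng.uniform([-bx / 2, -by / 2], [bx / 2, by / 2], size=(n_draw, 2))
        if r_ex > 0:
            xy = xy[np.hypot(xy[:, 0] - mu[0], xy[:, 1] - mu[1]) >= r_ex]
        take = min(len(xy), spec.n_points - filled)
        pts[filled : filled + take] = xy[:take]
        filled += take
    z = spec.dome(pts)
    if spec.noise_sigma > 0:
        z = z + rng.normal(0.0, spec.noise_sigma, size=len(z))
    return np.column_stack([pts, z]), spec.dome


def _splitting_probability(x0, A, B, v, D):
    """P(reach B before A | start x0) for dz = v dt + sqrt(2D) dW."""
    if D == 0:
        return 1.0 if v > 0 else (0.0 if v < 0 else 0.5)
    if v == 0:
        return (x0 - A) / (B - A)
    k = v / D
    # p = (1 - exp(-k(x0-A))) / (1 - exp(-k(B-A))), computed stably
    return float(np.expm1(-k * (x0 - A)) / np.expm1(-k * (B - A)))


def _simple_tally(z: np.ndarray, z_lo: float, z_hi: float) -> int:
    """Signed traversal count from the sequence of outside-slab sides.

    Deliberately minimal bookkeeping, independent of the analysis state
    machine: consecutive visits to opposite sides of the slab imply one
    net traversal.
    """
    net = 0
    side = None
    for zv in z:
        if zv < z_lo:
            cur = -1
        elif zv > z_hi:
            cur = 1
        else:
            continue
        if side is not None and cur != side:
            net += cur
        side = cur
    return net


def gen_ion_traces(spec: IonSimSpec):
    """Simulate drift-diffusion ion traces through the pore region.

    Returns ``(traces, truth)`` where ``truth`` holds the closed-form
    expected net crossing rate (injection rate times the drift-diffusion
    splitting probability from the injection plane to the far removal
    wall), the generator's own simple traversal tally, and bookkeeping
    counts.
    """
    rng = np.random.default_rng(spec.seed)
    reg = spec.region
    res = spec.reservoir
    lo_wall, hi_wall = reg.z_lo - 2 * res, reg.z_hi + 2 * res
    inj_lo, inj_hi = reg.z_lo - res, reg.z_hi + res
    v, D, dt = spec.drift_velocity, spec.D_coeff, spec.dt
    n_steps = int(round(spec.duration / dt))
    sigma_ou = spec.ou_sigma if spec.ou_sigma is not None else reg.radial_cutoff / 4
    ax, ay = reg.axis_xy

    # Poisson injection times at the upstream plane(s)
    planes: list[tuple[float, float]] = []  # (z_plane, rate)
    if v > 0:
        planes.append((inj_lo, spec.injection_rate))
    elif v < 0:
        planes.append((inj_hi, spec.injection_rate))
    else:
        planes.append((inj_lo, spec.injection_rate / 2))
        planes.append((inj_hi, spec.injection_rate / 2))
    injections = []
    for z_plane, rate in planes:
        n_inj = rng.poisson(rate * spec.duration)
        t_inj = np.sort(rng.uniform(0.0, spec.duration, size=n_inj))
        injections.extend((t, z_plane) for t in t_inj)
    injections.sort()
    if spec.n_ions is not None:
        injections = injections[: spec.n_ions]

    traces: list[IonTrace] = []
    tally = 0
    sq = math.sqrt(2 * D * dt)
    ou_decay = math.exp(-dt / spec.ou_tau)
    ou_sd = sigma_ou * math.sqrt(1 - ou_decay**2)
    step_cap = 10_000_000  # safety bound when draining
    for ion_id, (t_start, z_plane) in enumerate(injections):
        k0 = min(int(math.ceil(t_start / dt)), n_steps)
        n_avail = (n_steps - k0 + 1) if not spec.drain else step_cap
        if n_avail <= 1:
            continue
        zs: list[float] = []
        xs: list[float] = []
        ys: list[float] = []
        z = z_plane
        x = ax + rng.normal(0.0, sigma_ou)
        y = ay + rng.normal(0.0, sigma_ou)
        for k in range(n_avail):
            # reflect laterally at the cylinder wall
            r = math.hypot(x - ax, y - ay)
            if r > reg.radial_cutoff and r > 0:
                scale = (2 * reg.radial_cutoff - r) / r
                x = ax + (x - ax) * scale
                y = ay + (y - ay) * scale
            zs.append(z)
            xs.append(x)
            ys.append(y)
            if z <= lo_wall or z >= hi_wall:
                break
            z = z + v * dt + sq * rng.standard_normal()
            x = ax + (x - ax) * ou_decay + ou_sd * rng.standard_normal()
            y = ay + (y - ay) * ou_decay + ou_sd * rng.standard_normal()
        if len(zs) < 2:
            continue
        times = (k0 + np.arange(len(zs))) * dt
        pos = np.column_stack([xs, ys, zs])
        traces.append(
            IonTrace(ion_id=ion_id, species=spec.species, charge=spec.charge,
                     times=times, positions=pos)
        )
        tally += _simple_tally(pos[:, 2], reg.z_lo, reg.z_hi)

    p_up = _splitting_probability(inj_lo, lo_wall, hi_wall, v, D)
    p_down = 1.0 - _splitting_probability(inj_hi, lo_wall, hi_wall, v, D)
    expected_rate = 0.0
    for z_plane, rate in planes:
        if z_plane == inj_lo:
            expected_rate += rate * p_up
        else:
            expected_rate -= rate * p_down
    truth = {
        "expected_net_rate": expected_rate,  # traversals/ns, signed (+z positive)
        "expected_net_count": expected_rate * spec.duration,
        "self_tally_net": tally,
        "n_injected": len(injections),
        "duration": spec.duration,
        "charge": spec.charge,
    }
    return traces, truth


def gen_contact_series(spec: ContactSeriesSpec):
    """Binary contact series from a two-state Markov chain.

    P(on->on) = persistence; P(off->on) is set so the chain is
    stationary at p_on.  Returns ``(series, truth_occupancy)``.
    """
    p, a = spec.p_on, spec.persistence
    if p == 1.0:
        return np.ones(spec.n_frames, dtype=int), 1.0
    if p == 0.0:
        return np.zeros(spec.n_frames, dtype=int), 0.0
    b = p * (1 - a) / (1 - p)  # P(off -> on)
    if not 0.0 <= b <= 1.0:
        raise ValueError(
            f"inconsistent (p_on={p}, persistence={a}): implied off->on "
            f"probability {b:.3f} outside [0, 1]"
        )
    rng = np.random.default_rng(spec.seed)
    series = np.empty(spec.n_frames, dtype=int)
    u = rng.uniform(size=spec.n_frames)
    state = 1 if u[0] < p else 0
    series[0] = state
    for k in range(1, spec.n_frames):
        stay = a if state == 1 else 1 - b
        state = state if u[k] < stay else 1 - state
        series[k] = state
    return series, p


def gen_footprint_surfaces(alpha: float, D: float, H: float = 1.0, n: int = 20001):
    """Tabulate two mirrored tanh footprint profiles and measure their
    intersection angle by finite differences.

    The left dome edge sits at x = 0, the right at x = D (reduced
    units); the footprints h(x) = tanh(tan(alpha) x) and its mirror meet
    at x = D/2.  The measured angle pi - (arctan|m_L| + arctan|m_R|)
    from tabulated central-difference slopes serves as the geometric
    oracle for ``intersection_angle``.  Returns ``(table, theta_meas)``
    with heights scaled by H.
    """
    if not 0.0 <= alpha < math.pi / 2:
        raise ValueError("alpha must lie in [0, pi/2)")
    if D < 0:
        raise ValueError("D must be non-negative")
    m0 = math.tan(alpha)
    span = max(D, 2.0)
    x = np.linspace(0.0, span, n)
    h_left = np.tanh(m0 * x) * H
    h_right = np.tanh(m0 * (D - x)) * H  # mirrored; negative beyond x = D
    table = pd.DataFrame({"x": x, "h_left": h_left, "h_right": h_right})

    step = x[1] - x[0]
    xm = D / 2.0
    if xm < step:  # touching domes: one-sided slope at the edge
        m_l = (math.tanh(m0 * (xm + step)) - math.tanh(m0 * xm)) / step
        m_r = m_l
    else:
        i = int(round(xm / step))
        m_l = (math.tanh(m0 * x[i + 1]) - math.tanh(m0 * x[i - 1])) / (2 * step)
        m_r = abs(
            (math.tanh(m0 * (D - x[i + 1])) - math.tanh(m0 * (D - x[i - 1])))
            / (2 * step)
        )
    theta_meas = math.pi - (math.atan(abs(m_l)) + math.atan(m_r))
    return table, float(theta_meas)
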