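"""Ionic-conductance estimation from per-ion trajectories.

Two estimators of the single-channel current, as used for in-silico
electrophysiology of a channel pore under an applied field:

* boundary-crossing: count complete ion traversals N of a bounded
  cylindrical pore region over a period tau; the current is the net
  transported charge over tau (I = N/tau for a single species and
  direction), with exact Poisson confidence intervals on the counts;
* z-displacement: the instantaneous current
  I(t) = sum_i q_i [z_i(t+dt) - z_i(t)] / (dt * L)
  over ions inside the region, whose integral is the cumulative
  transported charge; uncertainty by moving-block bootstrap.

Per-voltage currents are combined into a conductance by a least-squares
line through the origin (zero voltage, zero current).  Units: Å, ns,
mV, pA, pS, elementary charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .constants import E_PER_NS_TO_PA

__all__ = [
    "PoreRegion",
    "IonTrace",
    "PermeationEvent",
    "IVPoint",
    "ConductanceFit",
    "SelectivityResult",
    "count_permeations",
    "current_from_counts",
    "poisson_ci",
    "zdisp_current",
    "fit_conductance",
    "bootstrap_sd",
    "selectivity_ratio",
]


@dataclass(frozen=True)
class PoreRegion:
    """Axially bounded cylindrical counting region, Å."""

    z_lo: float
    z_hi: float
    axis_xy: tuple[float, float] = (0.0, 0.0)
    radial_cutoff: float = 35.0

    def __post_init__(self) -> None:
        if self.z_lo >= self.z_hi:
            raise ValueError("z_lo must be below z_hi")
        if self.radial_cutoff <= 0:
            raise ValueError("radial_cutoff must be positive")

    @property
    def length(self) -> float:
        return self.z_hi - self.z_lo


@dataclass
class IonTrace:
    """Uniformly sampled trajectory of a single ion."""

    ion_id: int
    species: str
    charge: float  # elementary charges, signed, nonzero
    times: np.ndarray  # ns
    positions: np.ndarray  # (T, 3) Å

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        if self.charge == 0:
            raise ValueError("ion charge must be nonzero")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions length mismatch")

    @property
    def dt(self) -> float:
        d = np.diff(self.times)
        if len(d) == 0:
            return 0.0
        if np.any(np.abs(d - d[0]) > 1e-9):
            raise ValueError(f"ion {self.ion_id}: non-uniform time step")
        return float(d[0])


@dataclass(frozen=True)
class PermeationEvent:
    ion_id: int
    species: str
    direction: str  # "+z" | "-z"
    t_entry: float  # ns
    t_exit: float  # ns

    def __post_init__(self) -> None:
        if self.t_entry >= self.t_exit:
            raise ValueError("t_entry must precede t_exit")


@dataclass
class IVPoint:
    """One voltage condition of the simulated I-V experiment."""

    voltage: float  # mV
    duration: float  # ns
    counts: dict = field(default_factory=dict)  # species -> unsigned event count
    current: float = 0.0  # pA

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ConductanceFit:
    G: float  # pS
    r_squared: float
    method: str  # "counts" | "z_displacement"
    ci: tuple[float, float] | None = None  # (lo, hi) pS
    ci_level: float | None = None
    sd: float | None = None  # pS


@dataclass(frozen=True)
class SelectivityResult:
    ratio: float
    numerator: str
    denominator: str
    one_sided: bool  # True when the denominator count was zero (lower bound)


def _unwrap_z(z: np.ndarray, box_z: float | None) -> np.ndarray:
    if box_z is None:
        return z
    dz = np.diff(z)
    jumps = np.where(np.abs(dz) > box_z / 2, -np.sign(dz) * box_z, 0.0)
    return z + np.concatenate([[0.0], np.cumsum(jumps)])


def _interp_cross(t0, t1, z0, z1, plane):
    if z1 == z0:
        return t0
    return t0 + (plane - z0) / (z1 - z0) * (t1 - t0)


def count_permeations(traces, region: PoreRegion, box_z: float | None = None):
    """Detect complete pore traversals.

    An event is an ion entering the axial slab through one boundary and
    exiting through the opposite one, staying within the radial cutoff
    at every in-slab sample (for a single-step jump across the whole
    slab, at both bracketing samples).  Re-entries that leave through
    the entry boundary count nothing.  z is unwrapped first when
    ``box_z`` is given.

    Returns ``(events, counts, net_charge_e)`` where ``counts`` maps
    (species, direction) -> number of events and ``net_charge_e`` is the
    signed transported charge in elementary charges (+z crossing of a
    positive ion counts positive).
    """
    events: list[PermeationEvent] = []
    counts: dict[tuple[str, str], int] = {}
    net_charge = 0.0
    ax, ay = region.axis_xy
    for tr in traces:
        tr.dt  # validates uniform step
        pos = tr.positions
        if np.any(~np.isfinite(pos)):
            bad = int(np.argwhere(~np.isfinite(pos))[0, 0])
            raise ValueError(f"ion {tr.ion_id}: NaN coordinates at frame {bad}")
        z = _unwrap_z(pos[:, 2], box_z)
        r = np.hypot(pos[:, 0] - ax, pos[:, 1] - ay)
        inside_r = r <= region.radial_cutoff
        t = tr.times

        state = None  # 'below' | 'above' | 'inside'
        entry_side = None
        entry_time = None
        contained = True

        def emit(direction, t_entry, t_exit):
            nonlocal net_charge
            ev = PermeationEvent(tr.ion_id, tr.species, direction, t_entry, t_exit)
            events.append(ev)
            key = (tr.species, direction)
            counts[key] = counts.get(key, 0) + 1
            sgn = 1.0 if direction == "+z" else -1.0
            net_charge += sgn * tr.charge

        for k in range(len(z)):
            reg = "below" if z[k] < region.z_lo else ("above" if z[k] > region.z_hi else "inside")
            if state is None:
                state = reg
                entry_side = None  # starting inside cannot count as entry
                contained = inside_r[k] if reg == "inside" else True
            elif reg == state:
                if reg == "inside":
                    contained = contained and inside_r[k]
            elif state == "inside":
                # exiting the slab
                if reg == "above" and entry_side == "below" and contained:
                    emit("+z", entry_time, _interp_cross(t[k - 1], t[k], z[k - 1], z[k], region.z_hi))
                elif reg == "below" and entry_side == "above" and contained:
                    emit("-z", entry_time, _interp_cross(t[k - 1], t[k], z[k - 1], z[k], region.z_lo))
                state = reg
            elif reg == "inside":
                # entering the slab
                plane = region.z_lo if state == "below" else region.z_hi
                entry_side = state
                entry_time = _interp_cross(t[k - 1], t[k], z[k - 1], z[k], plane)
                contained = inside_r[k]
                state = "inside"
            else:
                # single-step jump across the whole slab
                if inside_r[k - 1] and inside_r[k]:
                    if state == "below":
                        emit(
                            "+z",
                            _interp_cross(t[k - 1], t[k], z[k - 1], z[k], region.z_lo),
                            _interp_cross(t[k - 1], t[k], z[k - 1], z[k], region.z_hi),
                        )
                    else:
                        emit(
                            "-z",
                            _interp_cross(t[k - 1], t[k], z[k - 1], z[k], region.z_hi),
                            _interp_cross(t[k - 1], t[k], z[k - 1], z[k], region.z_lo),
                        )
                state = reg
                entry_side = None
    return events, counts, net_charge


def current_from_counts(net_charge_e: float, tau_ns: float) -> float:
    """Current in pA from net transported charge (e) over tau (ns)."""
    if tau_ns <= 0:
        raise ValueError("tau must be positive")
    return net_charge_e / tau_ns * E_PER_NS_TO_PA


def poisson_ci(N: int, level: float = 0.85) -> tuple[float, float]:
    """Exact (Garwood) two-sided Poisson interval for a count N.

    lo solves P(X >= N | lam) = (1-level)/2 (lo = 0 at N = 0) and hi
    solves P(X <= N | lam) = (1-level)/2; via chi-squared quantiles.
    The interval is on the Poisson mean and scales linearly to a rate
    or conductance.
    """
    if N < 0:
        raise ValueError("count must be non-negative")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    a = (1.0 - level) / 2.0
    lo = 0.0 if N == 0 else 0.5 * chi2.ppf(a, 2 * N)
    hi = 0.5 * chi2.ppf(1.0 - a, 2 * N + 2)
    return float(lo), float(hi)


def zdisp_current(
    traces,
    region: PoreRegion,
    L: float | None = None,
    box_z: float | None = None,
    radial_gate: bool = True,
):
    """Instantaneous z-displacement current series and cumulative charge.

    I(t) = sum_i q_i * dz_i(t) / (dt * L) with dz the per-step change of
    z clipped to the slab [z_lo, z_hi] (so only in-region motion
    contributes and a full traversal transports exactly one ion charge).
    L defaults to the slab length.  With ``radial_gate`` the step of an
    ion whose radial position exceeds the cutoff at both endpoints is
    discarded.

    Returns ``(times, current_pA, cumulative_charge_e)`` on the common
    time grid (bin start times).
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces")
    dts = {round(tr.dt, 12) for tr in traces if len(tr.times) > 1}
    if len(dts) != 1:
        raise ValueError("all traces must share one uniform time step")
    dt = dts.pop()
    L = region.length if L is None else float(L)
    if L <= 0:
        raise ValueError("pore length L must be positive")
    t0 = min(tr.times[0] for tr in traces)
    t1 = max(tr.times[-1] for tr in traces)
    nbins = int(round((t1 - t0) / dt))
    charge_per_bin = np.zeros(max(nbins, 1))
    ax, ay = region.axis_xy
    for tr in traces:
        if len(tr.times) < 2:
            continue
        pos = tr.positions
        if np.any(~np.isfinite(pos)):
            bad = int(np.argwhere(~np.isfinite(pos))[0, 0])
            raise ValueError(f"ion {tr.ion_id}: NaN coordinates at frame {bad}")
        z = _unwrap_z(pos[:, 2], box_z)
        zc = np.clip(z, region.z_lo, region.z_hi)
        dz = np.diff(zc)
        if radial_gate:
            r = np.hypot(pos[:, 0] - ax, pos[:, 1] - ay)
            out = (r[:-1] > region.radial_cutoff) & (r[1:] > region.radial_cutoff)
            dz = np.where(out, 0.0, dz)
        start = int(round((tr.times[0] - t0) / dt))
        charge_per_bin[start : start + len(dz)] += tr.charge * dz / L
    current_pa = charge_per_bin / dt * E_PER_NS_TO_PA
    times = t0 + dt * np.arange(len(charge_per_bin))
    return times, current_pa, float(charge_per_bin.sum())


def fit_conductance(
    iv,
    method: str = "counts",
    ci_level: float = 0.85,
    n_resamples: int = 2000,
    seed: int | None = None,
) -> ConductanceFit:
    """Through-origin least-squares conductance from I-V points.

    G = sum(I*V)/sum(V^2) in pA/mV, reported in pS (x1000); R^2 is
    computed against the through-origin model (1 - SS_res/sum I^2).
    For ``method='counts'`` a confidence interval is propagated by
    resampling each point's total event count from Poisson(N_obs),
    rescaling its current and refitting (percentile interval at
    ``ci_level``); points with zero counts stay zero.
    """
    iv = list(iv)
    V = np.array([p.voltage for p in iv], float)
    I = np.array([p.current for p in iv], float)
    if np.all(V == 0):
        raise ValueError("need at least one nonzero voltage")
    G_pa_per_mv = float(I @ V / (V @ V))
    ss_res = float(np.sum((I - G_pa_per_mv * V) ** 2))
    ss_tot = float(I @ I)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    G = G_pa_per_mv * 1000.0

    ci = None
    if method == "counts":
        rng = np.random.default_rng(seed)
        Ns = np.array([sum(p.counts.values()) for p in iv], float)
        Gs = np.empty(n_resamples)
        for b in range(n_resamples):
            scale = np.ones_like(Ns)
            nz = Ns > 0
            scale[nz] = rng.poisson(Ns[nz]) / Ns[nz]
            Ib = I * scale
            Gs[b] = float(Ib @ V / (V @ V)) * 1000.0
        a = (1.0 - ci_level) / 2.0
        ci = (float(np.quantile(Gs, a)), float(np.quantile(Gs, 1.0 - a)))
    elif method != "z_displacement":
        raise ValueError(f"unknown method {method!r}")
    return ConductanceFit(G=G, r_squared=r2, method=method, ci=ci,
                          ci_level=ci_level if ci else None)


def bootstrap_sd(
    series_by_voltage: dict,
    n_resamples: int = 1000,
    block: int = 10,
    seed: int | None = None,
) -> float:
    """Moving-block-bootstrap SD of the through-origin conductance (pS).

    ``series_by_voltage`` maps voltage (mV) to the instantaneous-current
    series (pA) recorded at that voltage.  Each resample rebuilds every
    series from random contiguous blocks (respecting autocorrelation up
    to the block length), averages it into a per-voltage current and
    refits G; the SD over resamples is returned.  Deterministic under a
    fixed seed.
    """
    if n_resamples < 100:
        raise ValueError("need at least 100 resamples")
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    items = [(float(v), np.asarray(s, float)) for v, s in series_by_voltage.items()]
    for v, s in items:
        if len(s) <= block:
            raise ValueError(f"series at {v} mV shorter than block length")
    rng = np.random.default_rng(seed)
    V = np.array([v for v, _ in items])
    if np.all(V == 0):
        raise ValueError("need at least one nonzero voltage")
    Gs = np.empty(n_resamples)
    for b in range(n_resamples):
        Ib = np.empty(len(items))
        for j, (_, s) in enumerate(items):
            n = len(s)
            nblocks = math.ceil(n / block)
            starts = rng.integers(0, n - block + 1, size=nblocks)
            idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
            Ib[j] = s[idx].mean()
        Gs[b] = float(Ib @ V / (V @ V)) * 1000.0
    return float(Gs.std(ddof=1))


def selectivity_ratio(counts: dict, numerator: str, denominator: str) -> SelectivityResult:
    """Permeability ratio pX/pY from summed event counts.

    With a zero denominator count the ratio is reported as the one-sided
    lower bound N_numerator/1 and flagged (the true selectivity can only
    be larger).  Both counts zero is undefined.
    """
    nx = counts.get(numerator, 0)
    ny = counts.get(denominator, 0)
    if nx < 0 or ny < 0:
        raise ValueError("counts must be non-negative")
    if nx == 0 and ny == 0:
        raise ValueError("selectivity undefined: both counts are zero")
    if ny == 0:
        return SelectivityResult(float(nx), numerator, denominator, one_sided=True)
    return SelectivityResult(nx / ny, numerator, denominator, one_sided=False)
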