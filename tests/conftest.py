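import numpy as np
import pytest

from piezokit import DomeModel2D, IonTrace


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture()
def isotropic_dome():
    return DomeModel2D(
        zo=0.0, h=-8.0, mu=np.array([0.0, 0.0]),
        sigma_p1=30.0, sigma_p2=30.0, theta_rot=0.0,
    )


def make_walk_traces(n_traces, n_steps, rng, z_lo=56.0, z_hi=66.0, radius=35.0,
                     dt=0.1, step_sd=3.0, radial_spread=1.3):
    """Random-walk ion traces spanning the pore region, for oracle tests."""
    traces = []
    z0 = rng.uniform(z_lo - 15, z_hi + 15, size=n_traces)
    steps = rng.normal(0.0, step_sd, size=(n_traces, n_steps - 1))
    zs = z0[:, None] + np.concatenate(
        [np.zeros((n_traces, 1)), np.cumsum(steps, axis=1)], axis=1
    )
    xy = rng.uniform(-radius * radial_spread, radius * radial_spread,
                     size=(n_traces, n_steps, 2))
    times = np.arange(n_steps) * dt
    charges = rng.choice([1.0, -1.0], size=n_traces)
    for i in range(n_traces):
        traces.append(
            IonTrace(
                ion_id=i,
                species="K+" if charges[i] > 0 else "Cl-",
                charge=charges[i],
                times=times,
                positions=np.column_stack([xy[i, :, 0], xy[i, :, 1], zs[i]]),
            )
        )
    return traces


def oracle_count(traces, z_lo, z_hi, radius, axis_xy=(0.0, 0.0)):
    """Independent two-pass permeation counter.

    Pass one collects the indices of all outside-slab samples and their
    side; pass two pairs consecutive outside samples on opposite sides
    and checks that every intervening (in-slab) sample is radially
    contained (for an adjacent pair, that both endpoints are).
    """
    net = 0.0
    per_dir = {}
    for tr in traces:
        z = tr.positions[:, 2]
        r = np.hypot(tr.positions[:, 0] - axis_xy[0], tr.positions[:, 1] - axis_xy[1])
        side = np.where(z < z_lo, -1, np.where(z > z_hi, 1, 0))
        out_idx = np.flatnonzero(side != 0)
        for i1, i2 in zip(out_idx[:-1], out_idx[1:]):
            if side[i1] == side[i2]:
                continue
            if i2 == i1 + 1:
                ok = r[i1] <= radius and r[i2] <= radius
            else:
                ok = bool(np.all(r[i1 + 1 : i2] <= radius))
            if ok:
                d = "+z" if side[i2] == 1 else "-z"
                per_dir[(tr.species, d)] = per_dir.get((tr.species, d), 0) + 1
                net += tr.charge if d == "+z" else -tr.charge
    return per_dir, net
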