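"""Config-driven pipeline orchestration.

A YAML/dict config names stages and their parameters; each stage runs a
library operation on synthetic or supplied inputs and writes TSV/JSON
artifacts into ``out_dir``.  Every JSON artifact carries the package
version and a hash of the canonical config, so bundles are byte-stable
and attributable for fixed seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dome import fit_dome_2d, peak_curvatures
from .footprint import critical_D, critical_R, intersection_angle
from .permeation import (
    IVPoint,
    PoreRegion,
    count_permeations,
    current_from_counts,
    fit_conductance,
)
from .synth import (
    ContactSeriesSpec,
    IonSimSpec,
    MembraneCloudSpec,
    gen_contact_series,
    gen_ion_traces,
    gen_membrane_cloud,
)
from .dome import DomeModel2D

log = logging.getLogger("piezokit")

KNOWN_STAGES = ("footprint_critical", "membrane_curvature", "permeation", "contacts")


class ConfigError(ValueError):
    pass


def _require(stage: dict, keys, name: str) -> None:
    for k in keys:
        if k not in stage:
            raise ConfigError(f"stage {name!r}: missing required field {k!r}")


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict, meta: dict) -> None:
    path.write_text(json.dumps({**meta, **payload}, indent=2, sort_keys=True) + "\n")


def run_pipeline(config, out_dir=None) -> dict:
    """Execute the configured stages; returns {stage_name: artifact path}.

    ``config`` is a dict or a path to a YAML file with keys ``seed``,
    ``out_dir`` and ``stages`` (list of {name, ...params}).  The schema
    is validated before any computation runs.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict) or "stages" not in config:
        raise ConfigError("config must be a mapping with a 'stages' list")
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "."))
    stages = config["stages"]
    # validate schema fully before running anything
    for st in stages:
        if "name" not in st:
            raise ConfigError("every stage needs a 'name'")
        name = st["name"]
        if name not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage {name!r}; known: {KNOWN_STAGES}")
        if name == "footprint_critical":
            _require(st, ["alpha_deg", "height_nm"], name)
        elif name == "membrane_curvature":
            _require(st, ["dome"], name)
        elif name == "permeation":
            _require(st, ["voltages"], name)
        elif name == "contacts":
            _require(st, ["p_on", "persistence"], name)

    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": _config_hash(config), "version": __version__, "seed": seed}
    artifacts: dict[str, str] = {}
    for st in stages:
        name = st["name"]
        t0 = time.perf_counter()
        path = out / f"{name}.json"
        if name == "footprint_critical":
            alpha = math.radians(float(st["alpha_deg"]))
            H = float(st["height_nm"])
            d = critical_D(alpha)
            payload = {
                "alpha_deg": st["alpha_deg"],
                "D_crit": d,
                "R_crit_nm": critical_R(alpha, H),
                "theta_at_crit_deg": math.degrees(intersection_angle(alpha, d).theta),
            }
        elif name == "membrane_curvature":
            dome = DomeModel2D(
                zo=float(st["dome"].get("zo", 0.0)),
                h=float(st["dome"].get("h", -60.0)),
                mu=np.array(st["dome"].get("mu", [0.0, 0.0]), float),
                sigma_p1=float(st["dome"].get("sigma_p1", 60.0)),
                sigma_p2=float(st["dome"].get("sigma_p2", 60.0)),
                theta_rot=float(st["dome"].get("theta_rot", 0.0)),
            )
            spec = MembraneCloudSpec(
                dome=dome,
                n_points=int(st.get("n_points", 5000)),
                noise_sigma=float(st.get("noise_sigma", 1.0)),
                seed=seed,
            )
            points, truth = gen_membrane_cloud(spec)
            model, diag = fit_dome_2d(points)
            cs = peak_curvatures(model)
            payload = {
                "fit": {
                    "zo": model.zo, "h": model.h,
                    "sigma_p1": model.sigma_p1, "sigma_p2": model.sigma_p2,
                    "theta_rot": model.theta_rot,
                    "kappa1": cs.kappa1, "kappa2": cs.kappa2,
                    "mean_curvature": cs.mean_curvature,
                    "converged": diag["converged"],
                },
                "truth": {"h": truth.h, "sigma_p1": truth.sigma_p1,
                          "sigma_p2": truth.sigma_p2},
            }
        elif name == "permeation":
            region = PoreRegion(
                z_lo=float(st.get("z_lo", 56.0)),
                z_hi=float(st.get("z_hi", 66.0)),
                radial_cutoff=float(st.get("radial_cutoff", 35.0)),
            )
            mobility = float(st.get("mobility", 0.002))  # Å/ns per mV
            iv = []
            for j, V in enumerate(st["voltages"]):
                spec = IonSimSpec(
                    region=region,
                    drift_velocity=mobility * float(V),
                    duration=float(st.get("duration", 50.0)),
                    injection_rate=float(st.get("injection_rate", 0.5)),
                    seed=seed * 1000 + j,
                )
                traces, _ = gen_ion_traces(spec)
                _, counts, net = count_permeations(traces, region)
                I = current_from_counts(net, spec.duration)
                by_species: dict[str, int] = {}
                for (sp, _d), c in counts.items():
                    by_species[sp] = by_species.get(sp, 0) + c
                iv.append(IVPoint(voltage=float(V), duration=spec.duration,
                                  counts=by_species, current=I))
            fit = fit_conductance(iv, method="counts", seed=seed)
            payload = {
                "iv": [
                    {"voltage_mV": p.voltage, "current_pA": p.current,
                     "counts": p.counts}
                    for p in iv
                ],
                "G_pS": fit.G, "R2": fit.r_squared,
                "CI85_pS": list(fit.ci) if fit.ci else None,
            }
        elif name == "contacts":
            spec = ContactSeriesSpec(
                p_on=float(st["p_on"]),
                persistence=float(st["persistence"]),
                n_frames=int(st.get("n_frames", 10000)),
                seed=seed,
            )
            series, truth = gen_contact_series(spec)
            payload = {
                "occupancy": float(series.mean()),
                "truth_occupancy": truth,
                "n_frames": int(spec.n_frames),
            }
        _write_json(path, payload, meta)
        artifacts[name] = str(path)
        log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
    return artifacts
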