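"""Bivariate-Gaussian dome fit to lipid-headgroup point clouds.

The bilayer region occupied by the channel forms a bowl-like dome.  Each
leaflet's headgroup cloud (x, y, z) is fitted with

    g(x, y) = zo + h * exp(-1/2 (p - mu)^T C^-1 (p - mu)),   h < 0,

where ``zo`` is the flat-plateau height, ``h`` the (negative) peak
offset, ``mu`` the peak location and C a 2x2 SPD covariance written as
Rot(theta) diag(sigma_p1^2, sigma_p2^2) Rot(theta)^T.  At the peak the
two principal curvatures of the fitted surface are |h| / sigma_pi^2 and
the reported mean curvature is their arithmetic mean.

Fitting minimises the sum of squared z-residuals with a BFGS
quasi-Newton iteration and an analytic gradient, parameterised as
(zo, u, mu_x, mu_y, log sigma_p1, log sigma_p2, theta) with h = -exp(u)
so that h stays negative and the sigmas positive.

The initial guess follows a percentile recipe: zo is the 95th percentile
of z; rows outside the [5th, 95th] z-percentile band are dropped; |h| is
the z-range of the clipped data; mu is the depth-weighted mean of (x, y)
(weight = zo - z, clipped at zero); the principal axes and sigmas come
from the eigendecomposition of the depth-weighted second-moment tensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "DomeModel2D",
    "CurvatureSummary",
    "Profile1D",
    "DomeFitError",
    "fit_dome_2d",
    "peak_curvatures",
    "fit_profile_1d",
    "curvature_series",
    "dome_surface",
]


class DomeFitError(RuntimeError):
    """Raised when a dome fit cannot be initialised or does not converge."""


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class DomeModel2D:
    """Fitted dome parameters. Lengths in Å, angles in radians."""

    zo: float
    h: float
    mu: np.ndarray  # (2,)
    sigma_p1: float
    sigma_p2: float
    theta_rot: float  # in [0, pi)

    def __post_init__(self) -> None:
        if self.h >= 0:
            raise ValueError("h must be negative (concave-up dome)")
        if self.sigma_p1 <= 0 or self.sigma_p2 <= 0:
            raise ValueError("sigmas must be positive")

    @property
    def C(self) -> np.ndarray:
        """Covariance matrix Rot diag(sigma^2) Rot^T."""
        R = _rot(self.theta_rot)
        return R @ np.diag([self.sigma_p1**2, self.sigma_p2**2]) @ R.T

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        """Evaluate the dome surface at points xy (N,2)."""
        return dome_surface(
            np.asarray(xy, float), self.zo, self.h, self.mu,
            self.sigma_p1, self.sigma_p2, self.theta_rot,
        )


@dataclass(frozen=True)
class CurvatureSummary:
    """Principal curvatures at the dome peak, Å^-1."""

    kappa1: float
    kappa2: float
    mean_curvature: float


@dataclass(frozen=True)
class Profile1D:
    """1D Gaussian profile fit in a planar slab (xz or yz)."""

    zo: float
    h: float
    mu: float
    sigma: float
    plane: str  # "xz" | "yz"

    @property
    def curvature(self) -> float:
        return abs(self.h) / self.sigma**2


def dome_surface(xy, zo, h, mu, s1, s2, theta):
    """g(x,y) for the dome model; xy is (N,2)."""
    q = np.asarray(xy, float) - np.asarray(mu, float)
    w = q @ _rot(theta)  # rows are Rot^T q
    e = np.exp(-0.5 * ((w[:, 0] / s1) ** 2 + (w[:, 1] / s2) ** 2))
    return zo + h * e


def _sse_and_grad(params, xy, z):
    """Sum of squared residuals and analytic gradient.

    params = (zo, u, mux, muy, l1, l2, theta) with h = -exp(u),
    sigma_i = exp(l_i).
    """
    zo, u, mux, muy, l1, l2, theta = params
    h = -math.exp(u)
    s1, s2 = math.exp(l1), math.exp(l2)
    q = xy - np.array([mux, muy])
    R = _rot(theta)
    w = q @ R  # (N,2): w[:,k] = (R^T q)_k
    a1, a2 = w[:, 0] / s1, w[:, 1] / s2
    E = np.exp(-0.5 * (a1**2 + a2**2))
    g = zo + h * E
    r = g - z
    sse = float(r @ r)

    hE = h * E
    two_r = 2.0 * r
    # d g / d zo = 1 ; d g / d u = h*E (since dh/du = h)
    d_zo = float(two_r.sum())
    d_u = float(two_r @ hE)
    # d(-1/2 sum a^2)/dmu = R diag(1/s) a  (per point)
    # dg/dmu = hE * (R @ [a1/s1, a2/s2])
    v1 = a1 / s1
    v2 = a2 / s2
    dmu = R @ np.vstack([v1, v2])  # (2,N)
    d_mux = float(two_r @ (hE * dmu[0]))
    d_muy = float(two_r @ (hE * dmu[1]))
    # d g / d l_k = hE * a_k^2
    d_l1 = float(two_r @ (hE * a1**2))
    d_l2 = float(two_r @ (hE * a2**2))
    # d w / d theta = q @ dR = (dR^T q); dR^T/dtheta rows
    c, s = math.cos(theta), math.sin(theta)
    dRT = np.array([[-s, c], [-c, -s]])
    dw = q @ dRT.T  # (N,2)
    d_theta = float(two_r @ (hE * (-(a1 / s1) * dw[:, 0] - (a2 / s2) * dw[:, 1])))
    grad = np.array([d_zo, d_u, d_mux, d_muy, d_l1, d_l2, d_theta])
    return sse, grad


def _initial_guess(points: np.ndarray):
    """Percentile-based initial guess; returns (params, clipped points)."""
    z = points[:, 2]
    zo = float(np.percentile(z, 95))
    z5 = float(np.percentile(z, 5))
    keep = (z >= z5) & (z <= zo)
    pts = points[keep]
    if len(pts) < 10:
        pts = points
    zc = pts[:, 2]
    h0 = max(float(zc.max() - zc.min()), 1e-8)
    depth = np.clip(zo - zc, 0.0, None)
    wsum = float(depth.sum())
    xy = pts[:, :2]
    if wsum > 0:
        mu = (depth[:, None] * xy).sum(axis=0) / wsum
        q = xy - mu
        M = (depth[:, None] * q).T @ q / wsum
    else:
        mu = xy.mean(axis=0)
        q = xy - mu
        M = q.T @ q / len(q)
    evals, evecs = np.linalg.eigh(M)
    if evals[0] <= 0 or not np.all(np.isfinite(evals)):
        raise DomeFitError("degenerate xy spread: singular initialization")
    s_init = np.sqrt(evals)  # ascending
    # order so sigma_p1 is the first principal axis (largest spread)
    s1, s2 = float(s_init[1]), float(s_init[0])
    v1 = evecs[:, 1]
    theta0 = math.atan2(v1[1], v1[0]) % math.pi
    params0 = np.array(
        [zo, math.log(h0), mu[0], mu[1], math.log(s1), math.log(s2), theta0]
    )
    return params0, pts


def fit_dome_2d(
    points: np.ndarray,
    x0: np.ndarray | None = None,
    max_iter: int = 2000,
    gtol: float = 1e-8,
    clip: bool = False,
) -> tuple[DomeModel2D, dict]:
    """Fit the bivariate-Gaussian dome to an (N,3) headgroup cloud.

    Returns the fitted model and a diagnostics dict with keys
    ``converged``, ``n_iter``, ``sse_init``, ``sse_final``, ``message``.
    ``x0`` warm-starts the optimizer (internal parameter vector); by
    default the percentile recipe (clip to the [5th, 95th] z-percentile
    band, depth-weighted moments) is used for the initial guess only.
    With ``clip=True`` the least squares itself also drops rows outside
    the band; this matches the outlier-robust recipe but censors the
    height noise near the dome peak, so parameter recovery on clean
    synthetic data is run with the default.  The returned model is
    canonicalized so sigma_p1 >= sigma_p2 (p1 = major axis).
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    if len(points) < 10:
        raise ValueError("need at least 10 points")
    if np.linalg.matrix_rank(points[:, :2] - points[:, :2].mean(axis=0)) < 2:
        raise DomeFitError("degenerate xy spread: singular initialization")

    params0, pts = _initial_guess(points)
    if not clip:
        pts = points
    if x0 is not None:
        params0 = np.asarray(x0, float)
    xy, z = pts[:, :2], pts[:, 2]

    sse0, _ = _sse_and_grad(params0, xy, z)
    res = minimize(
        _sse_and_grad,
        params0,
        args=(xy, z),
        jac=True,
        method="BFGS",
        options={"maxiter": max_iter, "gtol": gtol},
    )
    best = res.x if res.fun <= sse0 else params0
    sse_final = min(float(res.fun), sse0)
    zo, u, mux, muy, l1, l2, theta = best
    s1, s2 = math.exp(l1), math.exp(l2)
    if s1 < s2:  # canonical order: p1 is the major axis
        s1, s2 = s2, s1
        theta += math.pi / 2
    model = DomeModel2D(
        zo=float(zo),
        h=-math.exp(u),
        mu=np.array([mux, muy]),
        sigma_p1=s1,
        sigma_p2=s2,
        theta_rot=float(theta % math.pi),
    )
    diag = {
        "converged": bool(res.success or res.status == 2),
        "n_iter": int(res.nit),
        "sse_init": sse0,
        "sse_final": sse_final,
        "message": str(res.message),
        "params": best,
    }
    if not diag["converged"]:
        diag["message"] = f"dome fit did not converge: {res.message}"
    return model, diag


def peak_curvatures(model: DomeModel2D) -> CurvatureSummary:
    """Principal curvatures |h|/sigma_i^2 at the dome peak and their mean."""
    k1 = abs(model.h) / model.sigma_p1**2
    k2 = abs(model.h) / model.sigma_p2**2
    return CurvatureSummary(kappa1=k1, kappa2=k2, mean_curvature=0.5 * (k1 + k2))


def _gauss1d(x, zo, h, mu, sigma):
    return zo + h * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


def fit_profile_1d(
    points: np.ndarray,
    plane: str,
    axis_origin: float = 0.0,
    half_width: float = 5.0,
) -> Profile1D:
    """1D Gaussian fit of a planar membrane profile.

    ``plane='xz'`` fits z against x using points with |y - axis_origin|
    <= half_width (and symmetrically for 'yz').  Curvature at the trough
    is |h|/sigma^2, as in the 2D model restricted to a principal plane.
    """
    points = np.asarray(points, float)
    if plane == "xz":
        mask = np.abs(points[:, 1] - axis_origin) <= half_width
        x, z = points[mask, 0], points[mask, 2]
    elif plane == "yz":
        mask = np.abs(points[:, 0] - axis_origin) <= half_width
        x, z = points[mask, 1], points[mask, 2]
    else:
        raise ValueError("plane must be 'xz' or 'yz'")
    if len(x) < 10:
        raise DomeFitError(f"fewer than 10 points in the {plane} slab")

    zo0 = float(np.percentile(z, 95))
    z5 = float(np.percentile(z, 5))
    keep = (z >= z5) & (z <= zo0)
    xs, zs = (x[keep], z[keep]) if keep.sum() >= 10 else (x, z)
    h0 = max(float(zs.max() - zs.min()), 1e-8)
    depth = np.clip(zo0 - zs, 0.0, None)
    wsum = depth.sum()
    mu0 = float((depth * xs).sum() / wsum) if wsum > 0 else float(xs.mean())
    var0 = (
        float((depth * (xs - mu0) ** 2).sum() / wsum)
        if wsum > 0
        else float(np.var(xs))
    )
    s0 = math.sqrt(max(var0, 1e-12))

    def sse(p):
        zo, u, mu, ls = p
        r = _gauss1d(xs, zo, -math.exp(u), mu, math.exp(ls)) - zs
        return float(r @ r)

    p0 = np.array([zo0, math.log(h0), mu0, math.log(s0)])
    res = minimize(sse, p0, method="BFGS", options={"maxiter": 2000, "gtol": 1e-10})
    zo, u, mu, ls = res.x if res.fun <= sse(p0) else p0
    return Profile1D(
        zo=float(zo), h=-math.exp(u), mu=float(mu), sigma=math.exp(ls), plane=plane
    )


def curvature_series(frames, times=None) -> pd.DataFrame:
    """Per-frame dome fits over a sequence of leaflet point clouds.

    Each element of ``frames`` is an (N,3) array.  Fits are warm-started
    from the previous frame's solution; frames whose fit fails are
    flagged (``converged=False``, NaN parameters) without aborting the
    series.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    rows = []
    warm = None
    for i, pts in enumerate(frames):
        t = times[i] if times is not None else float(i)
        try:
            model, diag = fit_dome_2d(np.asarray(pts, float), x0=warm)
            if diag["converged"]:
                warm = diag["params"]
            cs = peak_curvatures(model)
            rows.append(
                dict(
                    frame=i, time=t, zo=model.zo, h=model.h,
                    sigma_p1=model.sigma_p1, sigma_p2=model.sigma_p2,
                    theta_rot=model.theta_rot, kappa1=cs.kappa1,
                    kappa2=cs.kappa2, mean_curvature=cs.mean_curvature,
                    converged=diag["converged"],
                )
            )
        except (DomeFitError, ValueError):
            rows.append(
                dict(
                    frame=i, time=t, zo=np.nan, h=np.nan, sigma_p1=np.nan,
                    sigma_p2=np.nan, theta_rot=np.nan, kappa1=np.nan,
                    kappa2=np.nan, mean_curvature=np.nan, converged=False,
                )
            )
    return pd.DataFrame(rows)
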