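"""Elastic-backscatter lidar inversions of the combined channel.

These are the single-channel baselines an HSRL is compared against; all of
them must assume something the HSRL measures:

* slope method — homogeneous water; attenuation from the log-slope of the
  range-corrected signal.
* Fernald method — two-component (seawater + particles) backward integration
  from a boundary value, with an assumed particulate extinction-to-backscatter
  ratio (the lidar ratio).
* perturbation method — zeroth-order constant attenuation from the slope,
  first-order backscatter perturbation around the column mean, converted to a
  particulate backscatter profile through a Case-1-style bio-optical closure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_sim import LidarGeometry, SignalProfile
from .iop_model import SeawaterConstants

__all__ = [
    "ElasticRetrievalConfig",
    "FernaldDivergenceError",
    "slope_method",
    "fernald",
    "perturbation",
]


class FernaldDivergenceError(RuntimeError):
    """Backward integration denominator crossed zero."""

    def __init__(self, depth: float):
        super().__init__(f"Fernald integration diverged at depth {depth:.2f} m")
        self.depth = depth


@dataclass(frozen=True)
class ElasticRetrievalConfig:
    """Configuration shared by the elastic inversions.

    assumed_R is the Fernald particulate lidar ratio (sr); the boundary is
    placed at ``boundary_depth`` (None: deepest valid bin) with a clear-water
    particulate backscatter ``boundary_bbp`` (converted to beta_p_pi with
    chi).  ``r_case1`` is the Case-1 attenuation-to-backscatter closure used
    by the perturbation method.
    """

    method: str = "fernald"
    assumed_R: float = 100.0
    boundary_depth: float | None = None
    boundary_bbp: float = 1e-4
    r_case1: float = 100.0

    def __post_init__(self) -> None:
        if self.method not in ("slope", "fernald", "perturbation"):
            raise ValueError(f"unknown elastic method {self.method!r}")
        if self.assumed_R <= 0 or self.r_case1 <= 0:
            raise ValueError("lidar ratios must be > 0")


def _range_corrected(signal: SignalProfile, geom: LidarGeometry, valid=None):
    z = signal.depth_grid
    v = signal.values
    ok = np.isfinite(v) & (v > 0)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    x = np.full_like(v, np.nan)
    x[ok] = v[ok] * geom.range_factor(z[ok]) ** 2
    return x, geom.path(z), ok


def slope_method(signal: SignalProfile, geom: LidarGeometry, valid=None) -> float:
    """Constant attenuation (1/m) from the range-corrected log slope.

    Least-squares fit of ln[S * G^2] against the in-water slant path over the
    valid bins; the attenuation is minus half the slope.  Requires at least
    10 valid bins.
    """
    x, s, ok = _range_corrected(signal, geom, valid)
    if ok.sum() < 10:
        raise ValueError("slope method needs at least 10 valid bins")
    slope = np.polyfit(s[ok], np.log(x[ok]), 1)[0]
    return -0.5 * float(slope)


def fernald(
    signal: SignalProfile,
    geom: LidarGeometry,
    cfg: ElasticRetrievalConfig = ElasticRetrievalConfig(),
    const: SeawaterConstants = SeawaterConstants(),
    valid=None,
):
    """Two-component backward Fernald inversion of the combined channel.

    The molecular component has known backscatter beta_B_pi and extinction
    K_dw; the particulate component uses the assumed extinction-to-backscatter
    ratio ``cfg.assumed_R``.  Integration runs backward (upward) from the
    boundary bin, which keeps the solution stable.  Returns
    ``(alpha, beta_p_pi, valid_out)`` where alpha = K_dw + R*beta_p is the
    total diffuse-attenuation-like extinction (the method's K_d estimate);
    bins below the boundary are NaN.
    """
    x, s, ok = _range_corrected(signal, geom, valid)
    z = signal.depth_grid
    idx_ok = np.flatnonzero(ok)
    if idx_ok.size < 2:
        raise ValueError("not enough valid bins for Fernald inversion")
    if cfg.boundary_depth is None:
        ib = int(idx_ok[-1])
    else:
        if not (z[idx_ok[0]] <= cfg.boundary_depth <= z[idx_ok[-1]]):
            raise ValueError("boundary depth outside the valid range")
        ib = int(idx_ok[np.argmin(np.abs(z[idx_ok] - cfg.boundary_depth))])

    beta_m = const.beta_B_pi
    s_m = const.K_dw / beta_m  # molecular extinction-to-backscatter ratio
    s_p = cfg.assumed_R
    beta_p_b = cfg.boundary_bbp / (2.0 * np.pi * const.chi)

    sl = idx_ok[idx_ok <= ib]
    xs, ss = x[sl], s[sl]
    att = np.exp(2.0 * (s_p - s_m) * beta_m * (ss[-1] - ss))
    y = xs * att
    # integral from s to the boundary, trapezoid, accumulated backward
    seg = 0.5 * np.diff(ss) * (y[1:] + y[:-1])
    integral = np.concatenate((np.cumsum(seg[::-1])[::-1], [0.0]))
    denom = xs[-1] / (beta_p_b + beta_m) + 2.0 * s_p * integral
    bad = denom <= 0
    if bad.any():
        raise FernaldDivergenceError(float(z[sl][bad][0]))
    beta_tot = y / denom
    beta_p = np.full_like(x, np.nan)
    beta_p[sl] = beta_tot - beta_m
    alpha = const.K_dw + s_p * beta_p
    valid_out = np.zeros_like(ok)
    valid_out[sl] = True
    return alpha, beta_p, valid_out


def perturbation(
    signal: SignalProfile,
    geom: LidarGeometry,
    cfg: ElasticRetrievalConfig = ElasticRetrievalConfig(method="perturbation"),
    const: SeawaterConstants = SeawaterConstants(),
    valid=None,
):
    """Perturbation inversion: constant K_d plus first-order backscatter.

    The zeroth order is the slope-method attenuation K (the method's only,
    depth-constant K_d output).  The first-order relative backscatter
    perturbation is beta'(z) = X(z) e^{2 K s} / <X e^{2 K s}> - 1, and the
    column-mean particulate backscatter follows from the Case-1 closure
    K - K_dw = r_case1 * beta_p_pi.  Returns ``(K_d, beta_p_pi, valid_out)``
    with K_d a scalar.
    """
    x, s, ok = _range_corrected(signal, geom, valid)
    k0 = slope_method(signal, geom, valid)
    y = x[ok] * np.exp(2.0 * k0 * s[ok])
    beta_rel = y / np.mean(y) - 1.0
    beta_p0 = max(k0 - const.K_dw, 0.0) / cfg.r_case1
    beta_p = np.full_like(x, np.nan)
    beta_p[ok] = beta_p0 + (beta_p0 + const.beta_B_pi) * beta_rel
    return k0, beta_p, ok
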