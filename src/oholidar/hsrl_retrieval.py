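"""Core HSRL inversion at 532 nm.

The molecular (Brillouin) channel isolates seawater backscatter whose
180-degree volume scattering function beta_B_pi is known, so the combined /
molecular channel ratio yields the particulate 180-degree return without any
lidar-ratio assumption:

    beta_p_pi(z) = beta_B_pi * (T_B * B_C(z) / B_M(z) - 1)
    b_bp(z)      = 2 * pi * chi * beta_p_pi(z)

and the slope of the range-corrected molecular signal yields the apparent
lidar attenuation

    k_lidar(z) = -1/2 * d/d(z/cos theta_r) ln[ B_M(z) * (nH/cos theta_i
                                                         + z/cos theta_r)^2 ]

which the multiple-scattering correction later maps onto K_d.  The lidar
ratio is R(z) = (K_d(z) - K_dw) / beta_p_pi(z), in sr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .iop_model import SeawaterConstants

__all__ = [
    "ChannelCalibration",
    "RetrievalProducts",
    "retrieve_beta_p_pi",
    "retrieve_bbp",
    "retrieve_klidar",
    "lidar_ratio",
]


@dataclass(frozen=True)
class ChannelCalibration:
    """Iodine-cell channel transmittances and relative gain.

    T_B is the molecular Brillouin transmittance of the iodine-cell channel;
    the particulate and Rayleigh transmittances T_p, T_R are accepted for
    completeness but the simplified inversion assumes they are negligible
    (a warning is raised if T_p is not small relative to T_B).  gain_ratio is
    the combined/molecular channel scale factor; it is divided out of B_C
    before the ratio is formed.
    """

    T_B: float = 0.85
    T_p: float = 0.0
    T_R: float = 0.0
    gain_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.T_B <= 1.0):
            raise ValueError("T_B must be in (0, 1]")
        if self.T_p < 0 or self.T_R < 0:
            raise ValueError("T_p and T_R must be >= 0")
        if self.gain_ratio <= 0:
            raise ValueError("gain_ratio must be > 0")
        if self.T_p / self.T_B > 0.05:
            warnings.warn(
                "T_p/T_B > 0.05: the simplified inversion neglects particulate "
                "cross-talk and may be biased",
                stacklevel=2,
            )


@dataclass
class RetrievalProducts:
    """Depth-resolved retrieval products with a shared validity mask."""

    depth_grid: np.ndarray
    beta_p_pi: np.ndarray
    b_bp: np.ndarray
    k_lidar: np.ndarray
    K_d: np.ndarray
    R: np.ndarray
    valid: np.ndarray
    clipped_negative: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def retrieve_beta_p_pi(
    B_C,
    B_M,
    cal: ChannelCalibration = ChannelCalibration(),
    const: SeawaterConstants = SeawaterConstants(),
):
    """Particulate 180-degree volume scattering function from the channel ratio.

    Returns ``(beta_p_pi, valid, clipped)``: negative values (clearest water
    plus noise) are clipped to zero and flagged in ``clipped``; bins where the
    molecular signal is non-positive are masked in ``valid`` rather than
    raising.
    """
    bc = np.asarray(getattr(B_C, "values", B_C), dtype=float)
    bm = np.asarray(getattr(B_M, "values", B_M), dtype=float)
    if bc.shape != bm.shape:
        raise ValueError("combined and molecular signals must be aligned")
    valid = bm > 0
    ratio = np.full_like(bm, np.nan)
    ratio[valid] = (bc[valid] / cal.gain_ratio) / bm[valid]
    beta = const.beta_B_pi * (cal.T_B * ratio - 1.0)
    clipped = valid & (beta < 0)
    beta = np.where(clipped, 0.0, beta)
    beta[~valid] = np.nan
    return beta, valid, clipped


def retrieve_bbp(beta_p_pi, chi: float = 1.0):
    """b_bp = 2*pi*chi*beta_p_pi, elementwise (NaN propagates)."""
    return 2.0 * np.pi * chi * np.asarray(beta_p_pi, dtype=float)


def _window_slopes(x: np.ndarray, y: np.ndarray, valid: np.ndarray, window: int):
    """Sliding-window least-squares slope of y vs x at every index.

    Windows shrink one-sidedly at the profile ends; bins with fewer than two
    valid neighbours in the window give NaN.
    """
    n = x.size
    half = window // 2
    slopes = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sel = valid[lo:hi]
        if sel.sum() < 2:
            continue
        xs, ys = x[lo:hi][sel], y[lo:hi][sel]
        xm = xs - xs.mean()
        denom = np.dot(xm, xm)
        if denom <= 0:
            continue
        slopes[i] = np.dot(xm, ys) / denom
    return slopes


def retrieve_klidar(B_M, geom, window: int = 11):
    """Apparent lidar attenuation from the range-corrected molecular signal.

    The derivative in the defining equation is estimated by sliding-window
    linear regression of ln[B_M * G(z)^2] against the in-water slant path
    z/cos(theta_r) (default window 11 bins, ~3 m at 0.28 m sampling); window
    ends are handled one-sidedly.  Non-positive signal bins are masked, not
    raised.  Returns ``(k_lidar, valid)``.
    """
    z = np.asarray(getattr(B_M, "depth_grid", None), dtype=float)
    if z is None:
        raise ValueError("retrieve_klidar needs a SignalProfile with a depth grid")
    bm = np.asarray(B_M.values, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    valid = np.isfinite(bm) & (bm > 0)
    s = z / np.cos(geom.theta_r)
    logrc = np.full_like(bm, np.nan)
    logrc[valid] = np.log(bm[valid] * geom.range_factor(z[valid]) ** 2)
    slopes = _window_slopes(s, logrc, valid, window)
    k = -0.5 * slopes
    return k, valid & np.isfinite(k)


def lidar_ratio(
    K_d,
    beta_p_pi,
    K_dw: float = SeawaterConstants().K_dw,
    beta_floor: float = 1e-7,
):
    """Lidar ratio R(z) = (K_d - K_dw)/beta_p_pi, sr.

    Bins where beta_p_pi is below ``beta_floor`` (clearest water, or clipped
    negatives) are returned as NaN rather than raising.
    """
    kd = np.asarray(K_d, dtype=float)
    beta = np.asarray(beta_p_pi, dtype=float)
    scalar = kd.ndim == 0 and beta.ndim == 0
    shape = np.broadcast(kd, beta).shape or (1,)
    kd = np.broadcast_to(kd, shape)
    beta = np.broadcast_to(beta, shape)
    out = np.full(shape, np.nan)
    ok = np.isfinite(beta) & (beta > beta_floor) & np.isfinite(kd)
    out[ok] = (kd[ok] - K_dw) / beta[ok]
    return float(out[0]) if scalar else out
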