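"""Water-column inherent optical properties (IOPs) and the empirical K_d relation.

The water column is described by depth profiles of the absorption coefficient
``a``, the total scattering coefficient ``b`` and the total backscattering
coefficient ``b_b`` (all in 1/m, at 532 nm), on a uniform depth grid that is
zero at the identified water surface and positive downward.  The diffuse
attenuation coefficient of downwelling irradiance K_d is tied to the IOPs
through the empirical relation of Lee et al.,

    K_d = a + 4.18 * b_b * (1 - 0.52 * exp(-10.8 * a)),

which is also the relation embedded in the multiple-scattering correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IOPProfile",
    "SeawaterConstants",
    "PhaseFunction",
    "lee_kd",
    "make_profile",
    "read_iop_csv",
    "write_iop_csv",
]


@dataclass(frozen=True)
class SeawaterConstants:
    """Pure-seawater optical constants at 532 nm.

    The defaults are conventional literature values; every retrieval and the
    simulator accept an instance of this class so each constant can be
    overridden from configuration.

    Attributes
    ----------
    n : refractive index of seawater (dimensionless).
    K_dw : diffuse attenuation coefficient of pure seawater, 1/m.
    beta_B_pi : Brillouin 180-degree volume scattering function of seawater,
        1/(m sr); the molecular-channel backscatter source term.
    chi : conversion factor between the particulate 180-degree volume
        scattering function and b_bp, ``b_bp = 2*pi*chi*beta_p_pi``.
    b_bw : pure-seawater backscattering coefficient, 1/m; used to convert the
        retrieved particulate b_bp to the total b_b needed by the correction.
    """

    n: float = 1.34
    K_dw: float = 0.0452
    beta_B_pi: float = 2.0e-4
    chi: float = 1.0
    b_bw: float = 9.0e-4

    def __post_init__(self) -> None:
        if not (1.30 <= self.n <= 1.40):
            raise ValueError(f"refractive index n={self.n} outside [1.30, 1.40]")
        for name in ("K_dw", "beta_B_pi", "chi", "b_bw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class PhaseFunction:
    """Particulate scattering phase-function descriptor.

    Only the simulator needs the phase function; retrievals never do.  The
    default family is Fournier-Forand parameterised by its particulate
    backscatter fraction b_bp/b_p (the hinge-point parameterisation used by
    standard radiative-transfer codes).
    """

    family: str = "fournier-forand"
    backscatter_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.family not in ("fournier-forand",):
            raise ValueError(f"unknown phase function family {self.family!r}")
        if not (1e-4 < self.backscatter_fraction < 0.5):
            raise ValueError("backscatter_fraction must be in (1e-4, 0.5)")


@dataclass
class IOPProfile:
    """Depth-gridded IOPs: absorption a, scattering b, backscattering b_b.

    ``depth_grid`` is in meters, monotone increasing from 0 at the surface,
    positive downward, uniformly spaced.  All coefficient arrays share the
    grid length; b_b <= b everywhere.
    """

    depth_grid: np.ndarray
    a: np.ndarray
    b: np.ndarray
    b_b: np.ndarray
    phase_fn: PhaseFunction = field(default_factory=PhaseFunction)

    def __post_init__(self) -> None:
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        self.a = np.broadcast_to(np.asarray(self.a, dtype=float), self.depth_grid.shape).copy()
        self.b = np.broadcast_to(np.asarray(self.b, dtype=float), self.depth_grid.shape).copy()
        self.b_b = np.broadcast_to(np.asarray(self.b_b, dtype=float), self.depth_grid.shape).copy()
        if self.depth_grid.ndim != 1 or self.depth_grid.size < 2:
            raise ValueError("depth_grid must be 1-D with at least 2 points")
        dz = np.diff(self.depth_grid)
        if not np.all(dz > 0):
            raise ValueError("depth_grid must be strictly increasing")
        for name in ("a", "b", "b_b"):
            arr = getattr(self, name)
            if arr.shape != self.depth_grid.shape:
                raise ValueError(f"{name} length does not match depth_grid")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and >= 0")
        if np.any(self.b_b > self.b * (1 + 1e-12)):
            raise ValueError("b_b must not exceed b at any depth")

    @property
    def dz(self) -> float:
        return float(self.depth_grid[1] - self.depth_grid[0])

    @property
    def c(self) -> np.ndarray:
        """Beam attenuation coefficient c = a + b, 1/m."""
        return self.a + self.b

    def kd_true(self) -> np.ndarray:
        """Reference K_d profile implied by the IOPs (Lee et al. relation)."""
        return lee_kd(self.a, self.b_b)


def lee_kd(a, b_b):
    """Diffuse attenuation K_d from absorption and backscattering.

    Empirical relation K_d = a + 4.18*b_b*(1 - 0.52*exp(-10.8*a)); elementwise
    over aligned profiles or scalars.  Raises on negative input.
    """
    a = np.asarray(a, dtype=float)
    b_b = np.asarray(b_b, dtype=float)
    if np.any(a < 0) or np.any(b_b < 0):
        raise ValueError("lee_kd requires a >= 0 and b_b >= 0")
    out = a + 4.18 * b_b * (1.0 - 0.52 * np.exp(-10.8 * a))
    return float(out) if out.ndim == 0 else out


def make_profile(
    layer_spec,
    z_max: float | None = None,
    dz: float = 0.28,
    gaussian_layers=None,
    phase_fn: PhaseFunction | None = None,
    smooth_bins: int = 0,
) -> IOPProfile:
    """Build a piecewise-constant IOPProfile from layer specs.

    Parameters
    ----------
    layer_spec : list of (z_top, z_bottom, a, b, b_b)
        Non-overlapping depth ranges covering [0, z_max].  Ranges are applied
        as half-open intervals [z_top, z_bottom).
    z_max : bottom of the grid; defaults to the deepest layer bottom.
    dz : uniform grid spacing, m (default 0.28, the sampling resolution).
    gaussian_layers : optional list of (center_m, sigma_m, delta_a, delta_b,
        delta_b_b) Gaussian perturbations added on top of the layers.
    smooth_bins : if > 0, boxcar-smooth the coefficients over this many bins
        (layer steps become ramps, useful for avoiding grid artefacts).
    """
    if not layer_spec:
        raise ValueError("layer_spec must contain at least one layer")
    layers = sorted((tuple(map(float, ls)) for ls in layer_spec), key=lambda t: t[0])
    for (t0, b0, *_), (t1, _b1, *_) in zip(layers, layers[1:]):
        if t1 < b0 - 1e-12:
            raise ValueError("layer ranges overlap")
    if z_max is None:
        z_max = layers[-1][1]
    z = np.arange(0.0, z_max + dz / 2, dz)
    a = np.full_like(z, np.nan)
    b = np.full_like(z, np.nan)
    bb = np.full_like(z, np.nan)
    for z_top, z_bot, la, lb, lbb in layers:
        if lbb > lb:
            raise ValueError(f"layer ({z_top}-{z_bot} m) has b_b={lbb} > b={lb}")
        sel = (z >= z_top - 1e-12) & (z < z_bot - 1e-12)
        a[sel], b[sel], bb[sel] = la, lb, lbb
    # the grid endpoint belongs to the last layer
    if np.isnan(a[-1]):
        a[-1], b[-1], bb[-1] = layers[-1][2:]
    if np.any(np.isnan(a)):
        raise ValueError("layer_spec does not cover the requested grid")
    if gaussian_layers:
        for center, sigma, da, db, dbb in gaussian_layers:
            g = np.exp(-0.5 * ((z - center) / sigma) ** 2)
            a = a + da * g
            b = b + db * g
            bb = bb + dbb * g
    if smooth_bins > 1:
        kern = np.ones(int(smooth_bins)) / int(smooth_bins)
        pad = int(smooth_bins)
        for arr_name, arr in (("a", a), ("b", b), ("bb", bb)):
            padded = np.pad(arr, pad, mode="edge")
            sm = np.convolve(padded, kern, mode="same")[pad:-pad]
            if arr_name == "a":
                a = sm
            elif arr_name == "b":
                b = sm
            else:
                bb = sm
    return IOPProfile(z, a, b, bb, phase_fn=phase_fn or PhaseFunction())


def write_iop_csv(profile: IOPProfile, path) -> None:
    """Write an IOP profile as CSV with columns depth_m, a, b, bb."""
    pd.DataFrame(
        {"depth_m": profile.depth_grid, "a": profile.a, "b": profile.b, "bb": profile.b_b}
    ).to_csv(path, index=False)


def read_iop_csv(path, phase_fn: PhaseFunction | None = None) -> IOPProfile:
    """Read an IOP profile from CSV (columns depth_m, a, b, bb)."""
    df = pd.read_csv(path)
    return IOPProfile(
        df["depth_m"].to_numpy(),
        df["a"].to_numpy(),
        df["b"].to_numpy(),
        df["bb"].to_numpy(),
        phase_fn=phase_fn or PhaseFunction(),
    )
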