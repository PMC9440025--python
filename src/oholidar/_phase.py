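"""Fournier-Forand particulate phase function, tabulated for the simulator.

The Fournier-Forand (FF) family is the standard analytic ocean particulate
phase function: an ensemble of Mie scatterers with a Junge (hyperbolic) size
distribution of slope mu and relative refractive index n_p.  Following common
radiative-transfer practice the two parameters are collapsed onto one via the
linear constraint n_p = 1.01 + 0.1542*(mu - 3), so the family is indexed by a
single number — its particulate backscatter fraction B = b_bp/b_p.

Both the analytic quasi-single-scattering model and the Monte-Carlo oracle
consume the same tabulated cumulative distribution built here, so their
comparison probes the transport approximation, not the phase function.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = ["FournierForand"]


def _ff_pf(psi: np.ndarray, n_p: float, mu: float) -> np.ndarray:
    """FF phase function value at scattering angle psi (rad), 1/sr."""
    nu = (3.0 - mu) / 2.0
    s2 = np.sin(psi / 2.0) ** 2
    u2 = 4.0 * s2
    delta = u2 / (3.0 * (n_p - 1.0) ** 2)
    d180 = 4.0 / (3.0 * (n_p - 1.0) ** 2)
    dnu = delta**nu
    term1 = (
        nu * (1.0 - delta)
        - (1.0 - dnu)
        + (delta * (1.0 - dnu) - nu * (1.0 - delta)) / s2
    ) / (4.0 * np.pi * (1.0 - delta) ** 2 * dnu)
    term2 = (
        (1.0 - d180**nu)
        / (16.0 * np.pi * (d180 - 1.0) * d180**nu)
        * (3.0 * np.cos(psi) ** 2 - 1.0)
    )
    return term1 + term2


def _ff_backscatter_fraction(n_p: float, mu: float) -> float:
    """Closed-form FF backscatter fraction (integral over 90-180 degrees)."""
    nu = (3.0 - mu) / 2.0
    d90 = 2.0 / (3.0 * (n_p - 1.0) ** 2)
    return 1.0 - (1.0 - d90 ** (nu + 1.0) - 0.5 * (1.0 - d90**nu)) / (
        (1.0 - d90) * d90**nu
    )


def _solve_mu(backscatter_fraction: float) -> tuple[float, float]:
    """Invert the backscatter fraction for (mu, n_p) on the hinge line."""

    def f(mu: float) -> float:
        n_p = 1.01 + 0.1542 * (mu - 3.0)
        return _ff_backscatter_fraction(n_p, mu) - backscatter_fraction

    mu = brentq(f, 3.001, 4.999, xtol=1e-10)
    return mu, 1.01 + 0.1542 * (mu - 3.0)


class FournierForand:
    """Tabulated FF phase function indexed by backscatter fraction.

    Provides the full-sphere CDF of the scattering angle, the forward-lobe
    (0-90 degree) conditional CDF used for FOV retention probabilities, and
    inverse-CDF sampling of forward-lobe angles for the Monte-Carlo oracle.
    """

    _N_LOG, _N_LIN = 900, 600

    def __init__(self, backscatter_fraction: float = 0.02):
        self.backscatter_fraction = float(backscatter_fraction)
        self.mu, self.n_p = _solve_mu(self.backscatter_fraction)
        lo = np.logspace(-6, np.log10(0.1), self._N_LOG, endpoint=False)
        hi = np.linspace(0.1, np.pi, self._N_LIN)
        self.theta = np.concatenate(([0.0], lo, hi))
        pf = _ff_pf(self.theta[1:], self.n_p, self.mu)
        # p(theta)*sin(theta) -> 0 as theta -> 0 (FF is integrably singular)
        f = np.concatenate(([0.0], 2.0 * np.pi * pf * np.sin(self.theta[1:])))
        cdf = np.concatenate(
            ([0.0], np.cumsum(0.5 * np.diff(self.theta) * (f[1:] + f[:-1])))
        )
        self.norm = cdf[-1]
        self._cdf = cdf / self.norm
        i90 = int(np.searchsorted(self.theta, np.pi / 2.0))
        c90 = np.interp(np.pi / 2.0, self.theta, self._cdf)
        self._c90 = c90
        # forward-lobe conditional CDF on [0, pi/2]
        self._fwd_theta = np.concatenate((self.theta[:i90], [np.pi / 2.0]))
        self._fwd_cdf = np.concatenate((self._cdf[:i90], [c90])) / c90

    def cdf(self, theta) -> np.ndarray:
        """P(scattering angle <= theta), full sphere."""
        return np.interp(theta, self.theta, self._cdf)

    def forward_cdf(self, theta) -> np.ndarray:
        """P(angle <= theta | forward lobe), 1 for theta >= pi/2."""
        theta = np.asarray(theta, dtype=float)
        return np.interp(theta, self._fwd_theta, self._fwd_cdf, right=1.0)

    def sample_forward(self, rng: np.random.Generator, size) -> np.ndarray:
        """Sample forward-lobe scattering angles (rad) by inverse CDF."""
        u = rng.uniform(size=size)
        return np.interp(u, self._fwd_cdf, self._fwd_theta)
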