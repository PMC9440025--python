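"""Multiple-scattering correction (MSC) of the lidar attenuation.

Under multiple scattering the apparent lidar attenuation k_lidar varies with
depth even in homogeneous water.  The correction models that pattern as

    k_lidar(z) = m1 * exp(-m2 * z) + m3 + a

fits (m1, m2, m3) on QSSA-simulated homogeneous columns spanning the expected
IOP range, regresses each m-parameter on the backscattering coefficient b_b,
and then inverts a measured k_lidar profile to the diffuse attenuation via

    A(z) = k_lidar(z) - m1(b_b)*exp(-m2(b_b)*z) - m3(b_b)      (~ absorption)
    K_d(z) = A(z) + 4.18*b_b*(1 - 0.52*exp(-10.8*A(z)))        (Lee et al.)

Because the m-regressions are trained per acquisition geometry (the incidence
angle changes the footprint growth), a trained model carries a geometry tag
and refuses application to a different geometry unless explicitly overridden.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .forward_sim import LidarGeometry, simulate_molecular_signal
from .hsrl_retrieval import lidar_ratio, retrieve_klidar
from .iop_model import IOPProfile, PhaseFunction, SeawaterConstants, make_profile

__all__ = [
    "MSCModel",
    "MSCFitError",
    "fit_msc_single",
    "fit_msc_model",
    "correct_kd",
    "update_lidar_ratio",
    "DEFAULT_TRAIN_A",
    "DEFAULT_TRAIN_BB",
]

DEFAULT_TRAIN_A = (0.05, 0.1, 0.2, 0.35, 0.5)
DEFAULT_TRAIN_BB = (0.001, 0.002, 0.004, 0.007, 0.01)


class MSCFitError(RuntimeError):
    """Raised when the attenuation-model fit fails or is too poor."""


def _eq5(z, m1, m2, m3, a):
    return m1 * np.exp(-m2 * z) + m3 + a


def fit_msc_single(k_lidar, a: float, z):
    """Fit m1, m2, m3 of the attenuation model to one homogeneous column.

    Returns ``(m1, m2, m3, fit_rmsrd_percent)``.  The absorption a of the
    simulated column is known and held fixed.  Initial guesses follow the
    model's structure (m1 = surface-minus-deep excess, which is negative for
    the depth-increasing profiles multiple scattering produces); several
    fallback starts are tried before giving up.
    """
    z = np.asarray(z, dtype=float)
    k = np.asarray(k_lidar, dtype=float)
    ok = np.isfinite(k) & np.isfinite(z)
    z, k = z[ok], k[ok]
    if z.size < 5:
        raise MSCFitError("too few valid bins to fit the attenuation model")
    z_span = z[-1] - z[0]
    m1_0 = k[0] - k[-1]
    m3_0 = max(k[-1] - a, 0.0)
    starts = [
        (m1_0, 1.0 / max(z_span, 1e-6), m3_0),
        (m1_0, 5.0 / max(z_span, 1e-6), m3_0),
        (-abs(m1_0) - 1e-4, 0.2, m3_0),
        (0.0, 0.5, m3_0),
    ]
    bounds = ([-np.inf, 1e-9, 0.0], [np.inf, np.inf, np.inf])
    last_err = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                lambda zz, m1, m2, m3: _eq5(zz, m1, m2, m3, a),
                z, k, p0=p0, bounds=bounds, maxfev=20000,
            )
        except RuntimeError as err:  # pragma: no cover - rare non-convergence
            last_err = err
            continue
        resid = _eq5(z, *popt, a) / k - 1.0
        rmsrd = 100.0 * float(np.sqrt(np.mean(resid**2)))
        return float(popt[0]), float(popt[1]), float(popt[2]), rmsrd
    raise MSCFitError(f"attenuation-model fit did not converge; tried starts {starts}") from last_err


_FAMILIES = {
    "linear": (lambda x, c0, c1: c0 + c1 * x, 2),
    "quadratic": (lambda x, c0, c1, c2: c0 + c1 * x + c2 * x**2, 3),
    "power": (lambda x, c0, c1: c0 * x**c1, 2),
}


def _fit_family(x: np.ndarray, y: np.ndarray):
    """Fit {power, linear, quadratic} and keep the best R^2 family."""
    best = None
    for name, (fn, npar) in _FAMILIES.items():
        if name == "power" and (np.any(y <= 0) or np.any(x <= 0)):
            continue
        try:
            if name == "power":
                c1, logc0 = np.polyfit(np.log(x), np.log(y), 1)
                p0 = [float(np.exp(logc0)), float(c1)]
            else:
                p0 = [float(np.mean(y))] + [0.0] * (npar - 1)
            with warnings.catch_warnings():
                # near-constant m-parameters make the covariance singular;
                # only the point estimate is used
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(fn, x, y, p0=p0, maxfev=20000)
        except RuntimeError:  # pragma: no cover
            continue
        pred = fn(x, *popt)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        if best is None or r2 > best["r2"]:
            best = {"family": name, "coeffs": [float(c) for c in popt], "r2": r2}
    if best is None:
        raise MSCFitError("no m-parameter regression family converged")
    return best


def _eval_family(fit: dict, x):
    fn, _ = _FAMILIES[fit["family"]]
    return fn(np.asarray(x, dtype=float), *fit["coeffs"])


@dataclass
class MSCModel:
    """Fitted m1/m2/m3 regressions on b_b, tagged with the training geometry."""

    m_fits: dict  # name -> {family, coeffs, r2}
    geometry: LidarGeometry
    training: dict = field(default_factory=dict)

    def m(self, name: str, b_b):
        return _eval_family(self.m_fits[name], b_b)

    def check_geometry(self, geom: LidarGeometry, force: bool = False) -> None:
        if geom != self.geometry:
            msg = (
                f"MSC model trained for {self.geometry} applied to {geom}; "
                "the m-parameter regressions are geometry-specific"
            )
            if force:
                warnings.warn(msg, stacklevel=3)
            else:
                raise ValueError(msg)

    def to_json(self, path=None) -> str:
        payload = {
            "m_fits": self.m_fits,
            "geometry": {
                "H": self.geometry.H,
                "theta_i_deg": self.geometry.theta_i_deg,
                "fov": self.geometry.fov,
                "n": self.geometry.n,
            },
            "training": self.training,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MSCModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(payload["m_fits"], LidarGeometry(**payload["geometry"]),
                   payload.get("training", {}))


def fit_msc_model(
    training_conditions=None,
    geom: LidarGeometry = LidarGeometry(),
    const: SeawaterConstants = SeawaterConstants(),
    z_max: float = 25.0,
    dz: float = 0.28,
    backscatter_fraction: float = 0.02,
    klidar_window: int = 11,
    max_condition_rmsrd: float = 10.0,
    fit_zmin: float = 0.0,
) -> MSCModel:
    """Train the MSC model on homogeneous IOP conditions.

    ``training_conditions`` is a list of IOPProfile (homogeneous columns) or
    of (a, b_b) pairs; the default is the 5x5 grid spanning the product ranges
    observed in coastal-to-open waters (a in 0.05-0.5, b_b in 0.001-0.01 per
    m).  Each condition is simulated with the QSSA model, k_lidar derived by
    the standard slope estimator, the attenuation model fitted per condition,
    and each m-parameter regressed on b_b over {power, linear, quadratic}
    picked by R^2.  Any per-condition fit with RMSRD above
    ``max_condition_rmsrd`` percent aborts with diagnostics.
    """
    if training_conditions is None:
        training_conditions = [(a, bb) for a in DEFAULT_TRAIN_A for bb in DEFAULT_TRAIN_BB]
    profiles = []
    for cond in training_conditions:
        if isinstance(cond, IOPProfile):
            profiles.append(cond)
        else:
            a, bb = cond
            profiles.append(
                make_profile(
                    [(0.0, z_max, a, bb / backscatter_fraction, bb)],
                    dz=dz,
                    phase_fn=PhaseFunction(backscatter_fraction=backscatter_fraction),
                )
            )
    if len(profiles) < 6:
        raise ValueError("need at least 6 training conditions")
    rows = []
    for prof in profiles:
        a = float(prof.a[0])
        bb = float(prof.b_b[0])
        if np.ptp(prof.a) > 1e-12 or np.ptp(prof.b_b) > 1e-12:
            raise ValueError("training conditions must be homogeneous columns")
        bm = simulate_molecular_signal(prof, geom, const)
        k, valid = retrieve_klidar(bm, geom, window=klidar_window)
        sel = valid & (prof.depth_grid >= fit_zmin)
        m1, m2, m3, rmsrd = fit_msc_single(k[sel], a, prof.depth_grid[sel])
        if rmsrd > max_condition_rmsrd:
            raise MSCFitError(
                f"condition (a={a}, b_b={bb}): fit RMSRD {rmsrd:.2f}% exceeds "
                f"{max_condition_rmsrd}%"
            )
        rows.append({"a": a, "b_b": bb, "m1": m1, "m2": m2, "m3": m3, "rmsrd": rmsrd})
    bbs = np.array([r["b_b"] for r in rows])
    m_fits = {}
    for name in ("m1", "m2", "m3"):
        y = np.array([r[name] for r in rows])
        if np.ptp(bbs) < 1e-15:
            m_fits[name] = {"family": "linear", "coeffs": [float(np.mean(y)), 0.0], "r2": 1.0}
        else:
            m_fits[name] = _fit_family(bbs, y)
    training = {
        "conditions": rows,
        "z_max": z_max,
        "dz": dz,
        "backscatter_fraction": backscatter_fraction,
        "klidar_window": klidar_window,
    }
    return MSCModel(m_fits, geom, training)


def modeled_klidar(model: MSCModel, a, b_b, z):
    """Attenuation-model prediction k = m1(b_b) e^{-m2(b_b) z} + m3(b_b) + a."""
    z = np.asarray(z, dtype=float)
    m1 = model.m("m1", b_b)
    m2 = np.clip(model.m("m2", b_b), 1e-9, None)
    m3 = model.m("m3", b_b)
    return m1 * np.exp(-m2 * z) + m3 + np.asarray(a, dtype=float)


def correct_kd(k_lidar, b_b, model: MSCModel, z, geom: LidarGeometry | None = None,
               force_geometry: bool = False):
    """MSC-corrected K_d from measured k_lidar and retrieved b_b.

    Evaluates the m-parameters at the local b_b(z) (homogeneous training is
    extrapolated to stratified columns bin by bin), removes the modelled
    multiple-scattering excess and maps the residual absorption-like term
    through the embedded Lee et al. relation.  Bins where the residual A(z)
    is negative are masked (NaN) and flagged.  Returns ``(K_d, flagged)``.
    """
    if geom is not None:
        model.check_geometry(geom, force=force_geometry)
    z = np.asarray(z, dtype=float)
    k = np.asarray(k_lidar, dtype=float)
    bb = np.broadcast_to(np.asarray(b_b, dtype=float), k.shape)
    m1 = np.broadcast_to(model.m("m1", bb), k.shape)
    m2 = np.clip(np.broadcast_to(model.m("m2", bb), k.shape), 1e-9, None)
    m3 = np.broadcast_to(model.m("m3", bb), k.shape)
    a_est = k - m1 * np.exp(-m2 * z) - m3
    flagged = np.isfinite(a_est) & (a_est < 0)
    with np.errstate(invalid="ignore"):
        kd = a_est + 4.18 * bb * (1.0 - 0.52 * np.exp(-10.8 * a_est))
    kd = np.where(flagged, np.nan, kd)
    return kd, flagged


def update_lidar_ratio(K_d_corrected, beta_p_pi,
                       const: SeawaterConstants = SeawaterConstants(),
                       beta_floor: float = 1e-7):
    """Recompute the lidar ratio with the MSC-corrected K_d."""
    return lidar_ratio(K_d_corrected, beta_p_pi, K_dw=const.K_dw, beta_floor=beta_floor)
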