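"""Accuracy metrics, the method-comparison harness and curtain file I/O.

The accuracy metric throughout is the root-mean-square relative difference

    RMSRD(%) = 100 * sqrt( sum_i (x_i / xref_i - 1)^2 / N )

computed over the intersection of validity masks, plus the coefficient of
determination of log10 products (the convention for optical properties that
span decades).  ``compare_methods`` runs the full pipeline — preprocessing,
HSRL retrieval, multiple-scattering correction and the elastic baselines —
over a synthetic scene and pools all valid bins of all columns into one
report per method and product.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from . import elastic_retrieval as el
from . import hsrl_retrieval as hr
from . import msc as msc_mod
from . import preprocess as pp
from .forward_sim import Scene
from .iop_model import SeawaterConstants

__all__ = [
    "AcquisitionSpec",
    "ComparisonReport",
    "rmsrd",
    "r_squared",
    "r_squared_log10",
    "depth_bin_size",
    "compare_methods",
    "scene_to_dataset",
    "save_curtain",
    "load_curtain",
]

C_LIGHT = 2.998e8  # m/s


@dataclass(frozen=True)
class AcquisitionSpec:
    """Digitiser sampling and the in-water range resolution it implies."""

    f_s: float = 400e6
    n: float = 1.33

    def __post_init__(self) -> None:
        if self.f_s <= 0:
            raise ValueError("sampling frequency must be > 0")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def bin_size(self) -> float:
        return depth_bin_size(self)


def depth_bin_size(spec: AcquisitionSpec) -> float:
    """Range bin in water, m: c / (2 * n * f_s)."""
    return C_LIGHT / (2.0 * spec.n * spec.f_s)


def _paired(x, x_ref, mask=None, exclude_zero_ref=False):
    x = np.asarray(x, dtype=float).ravel()
    r = np.asarray(x_ref, dtype=float).ravel()
    if x.shape != r.shape:
        raise ValueError("profiles must be aligned")
    ok = np.isfinite(x) & np.isfinite(r)
    if mask is not None:
        ok &= np.asarray(mask, dtype=bool).ravel()
    if exclude_zero_ref and np.any(ok & (r == 0)):
        warnings.warn("zero reference bins excluded from metric", stacklevel=3)
        ok &= r != 0
    if not ok.any():
        raise ValueError("no jointly valid bins to compare")
    return x[ok], r[ok]


def rmsrd(x, x_ref, mask=None) -> float:
    """Root-mean-square relative difference, percent."""
    xs, rs = _paired(x, x_ref, mask, exclude_zero_ref=True)
    return 100.0 * float(np.sqrt(np.mean((xs / rs - 1.0) ** 2)))


def r_squared(x, x_ref, mask=None) -> float:
    """Coefficient of determination of x against x_ref (1 - SSres/SStot)."""
    xs, rs = _paired(x, x_ref, mask)
    ss_tot = float(np.sum((rs - rs.mean()) ** 2))
    # a (numerically) constant reference has no variance to explain
    if ss_tot <= (1e-12 * max(np.max(np.abs(rs)), 1e-300)) ** 2 * rs.size:
        return 1.0 if np.allclose(xs, rs) else float("nan")
    return 1.0 - float(np.sum((xs - rs) ** 2)) / ss_tot


def r_squared_log10(x, x_ref, mask=None) -> float:
    """R^2 of log10(x) against log10(x_ref) over jointly positive bins."""
    xs, rs = _paired(x, x_ref, mask)
    pos = (xs > 0) & (rs > 0)
    if not pos.any():
        raise ValueError("no jointly positive bins for log metric")
    return r_squared(np.log10(xs[pos]), np.log10(rs[pos]))


@dataclass
class ComparisonReport:
    """Pooled per-method, per-product accuracy over a scene.

    ``metrics[method][product]`` holds rmsrd_percent, r2_log10 and the pooled
    valid-bin count.  Bins are pooled across profiles before the metric is
    taken (not averaged per profile); the pooling convention is recorded.
    """

    metrics: dict
    scene_meta: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    pooling: str = "bins pooled across profiles"

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "metrics": self.metrics,
                "scene_meta": _jsonable(self.scene_meta),
                "config": _jsonable(self.config),
                "pooling": self.pooling,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ComparisonReport":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(payload["metrics"], payload["scene_meta"], payload["config"],
                   payload["pooling"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items() if not _is_object(v)}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _is_object(v) -> bool:
    return hasattr(v, "__dataclass_fields__") and not isinstance(v, dict)


_DEFAULT_METHODS = {
    "fernald_ratios": [100.0, 200.0],
    "perturbation": True,
    "klidar_window": 11,
    "surface_cut_m": 3.0,
    "dynamic_range_decades": 3.0,
    "denoise": "auto",
    "boundary_bbp": 1e-4,
}


def compare_methods(scene: Scene, methods: dict | None = None,
                    model: msc_mod.MSCModel | None = None) -> ComparisonReport:
    """Run every retrieval on a scene and score it against the truth.

    Pipeline per column: (optional) denoising, dynamic-range truncation,
    HSRL inversion, multiple-scattering correction (a model is trained for the
    scene geometry if not supplied), and the elastic baselines on the combined
    channel.  Background subtraction is applied only when the scene was
    generated with noise ("denoise": "auto"); a noiseless signal has no
    background-dominated tail to estimate from.  Deterministic given the scene
    (whose seed is recorded in the report).
    """
    cfg = dict(_DEFAULT_METHODS)
    cfg.update(methods or {})
    const = scene.const
    geom = scene.geometry
    if model is None:
        bbf = scene.profiles[0].phase_fn.backscatter_fraction
        model = msc_mod.fit_msc_model(
            geom=geom, const=const,
            z_max=float(scene.depth_grid[-1]), dz=scene.profiles[0].dz,
            backscatter_fraction=bbf, klidar_window=cfg["klidar_window"],
        )
    noise_on = bool(scene.meta.get("noise", {}).get("enabled", False))
    do_denoise = noise_on if cfg["denoise"] == "auto" else bool(cfg["denoise"])

    pairs: dict[str, dict[str, list]] = {}

    def add(method: str, product: str, est: np.ndarray, tru: np.ndarray, ok: np.ndarray):
        store = pairs.setdefault(method, {}).setdefault(product, [[], []])
        sel = ok & np.isfinite(est) & np.isfinite(tru) & (tru > 0)
        store[0].append(est[sel])
        store[1].append(tru[sel])

    failures = []
    for icol, (bc, bm) in enumerate(scene.signals):
        try:
            if do_denoise:
                bc = pp.denoise(bc)
                bm = pp.denoise(bm)
            mask_c = pp.truncate_valid_range(bc, cfg["surface_cut_m"],
                                             cfg["dynamic_range_decades"])
            mask_m = pp.truncate_valid_range(bm, cfg["surface_cut_m"],
                                             cfg["dynamic_range_decades"])
            valid = mask_c.valid & mask_m.valid
            z = scene.depth_grid
            tru_kd = scene.truth["K_d"][icol]
            tru_bbp = scene.truth["b_bp"][icol]

            # HSRL + MSC
            beta_p, v_beta, _ = hr.retrieve_beta_p_pi(bc, bm, scene.cal, const)
            b_bp = hr.retrieve_bbp(beta_p, const.chi)
            k_lidar, v_k = hr.retrieve_klidar(bm, geom, window=cfg["klidar_window"])
            v_hsrl = valid & v_beta & v_k
            kd_msc, flagged = msc_mod.correct_kd(
                k_lidar, b_bp + const.b_bw, model, z, geom=geom)
            add("hsrl", "b_bp", b_bp, tru_bbp, v_hsrl)
            add("hsrl", "K_d", k_lidar, tru_kd, v_hsrl)
            add("hsrl_msc", "b_bp", b_bp, tru_bbp, v_hsrl)
            add("hsrl_msc", "K_d", kd_msc, tru_kd, v_hsrl & ~flagged)

            # elastic baselines on the combined channel
            for ratio in cfg["fernald_ratios"]:
                fc = el.ElasticRetrievalConfig(
                    method="fernald", assumed_R=float(ratio),
                    boundary_bbp=cfg["boundary_bbp"])
                alpha, beta_f, v_f = el.fernald(bc, geom, fc, const, valid=valid)
                name = f"fernald_{int(ratio)}"
                add(name, "K_d", alpha, tru_kd, valid & v_f)
                add(name, "b_bp", 2 * np.pi * const.chi * beta_f, tru_bbp, valid & v_f)
            if cfg["perturbation"]:
                k0, beta_pe, v_p = el.perturbation(
                    bc, geom, el.ElasticRetrievalConfig(method="perturbation"), const,
                    valid=valid)
                add("perturbation", "K_d", np.full_like(z, k0), tru_kd, valid & v_p)
                add("perturbation", "b_bp", 2 * np.pi * const.chi * beta_pe,
                    tru_bbp, valid & v_p)
        except Exception as err:  # noqa: BLE001 - per-column failures are recorded
            failures.append({"column": icol, "error": f"{type(err).__name__}: {err}"})

    metrics: dict = {}
    for method, products in pairs.items():
        metrics[method] = {}
        for product, (ests, trus) in products.items():
            est = np.concatenate(ests) if ests else np.array([])
            tru = np.concatenate(trus) if trus else np.array([])
            if est.size == 0:
                metrics[method][product] = {"rmsrd_percent": None, "r2_log10": None, "n": 0}
                continue
            entry = {"rmsrd_percent": rmsrd(est, tru), "n": int(est.size)}
            try:
                r2l = r_squared_log10(est, tru)
                entry["r2_log10"] = None if math.isnan(r2l) else r2l
            except ValueError:
                entry["r2_log10"] = None
            metrics[method][product] = entry
    scene_meta = {"seed": scene.meta.get("seed"), "n_columns": len(scene.signals),
                  "template": scene.meta.get("config", {}).get("template"),
                  "failures": failures}
    return ComparisonReport(metrics, scene_meta, cfg)


def scene_to_dataset(scene: Scene, products: dict | None = None) -> xr.Dataset:
    """Serialise a scene (and optional retrieval products) to the curtain schema.

    Dims (time, depth); variables B_C, B_M, the truth products and any
    supplied retrieval arrays; geometry, seed and a config hash as attributes.
    """
    z = scene.depth_grid
    bc = np.stack([s[0].values for s in scene.signals])
    bm = np.stack([s[1].values for s in scene.signals])
    data = {
        "B_C": (("time", "depth"), bc),
        "B_M": (("time", "depth"), bm),
        "a": (("time", "depth"), np.stack([p.a for p in scene.profiles])),
        "b": (("time", "depth"), np.stack([p.b for p in scene.profiles])),
        "b_b": (("time", "depth"), np.stack([p.b_b for p in scene.profiles])),
    }
    for name, arr in scene.truth.items():
        data[f"truth_{name}"] = (("time", "depth"), np.asarray(arr))
    for name, arr in (products or {}).items():
        data[name] = (("time", "depth"), np.asarray(arr))
    cfg_json = json.dumps(_jsonable(scene.meta.get("config", {})), sort_keys=True)
    attrs = {
        "H": scene.geometry.H,
        "theta_i_deg": scene.geometry.theta_i_deg,
        "fov": scene.geometry.fov,
        "n": scene.geometry.n,
        "seed": scene.meta.get("seed", -1),
        "config_hash": f"{abs(hash(cfg_json)):x}",
        "config_json": cfg_json,
        "K_dw": scene.const.K_dw,
        "beta_B_pi": scene.const.beta_B_pi,
        "chi": scene.const.chi,
        "b_bw": scene.const.b_bw,
    }
    return xr.Dataset(data, coords={"time": scene.times, "depth": z}, attrs=attrs)


def save_curtain(ds: xr.Dataset, path) -> None:
    """Write a curtain dataset as netCDF (classic format via the scipy engine)."""
    ds.to_netcdf(path, engine="scipy")


def load_curtain(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


def optical_depth_limit(kd_profile, z, n_od: float = 3.0):
    """Depth at which the accumulated optical depth reaches ``n_od``.

    The product K_d * z is the conventional penetration bound (about 3
    optical depths); returns the interpolated depth, or z[-1] if not reached.
    """
    kd = np.asarray(kd_profile, dtype=float)
    z = np.asarray(z, dtype=float)
    od = np.concatenate(([0.0], np.cumsum(0.5 * np.diff(z) * (kd[1:] + kd[:-1]))))
    if od[-1] < n_od:
        return float(z[-1])
    return float(np.interp(n_od, od, z))
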