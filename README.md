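# oholidar

Processing chain for a shipborne **oceanic high-spectral-resolution lidar
(HSRL)** at 532 nm: forward simulation of multiple-scattering lidar returns
from stratified seawater, HSRL inversion of depth-resolved particulate
backscattering and attenuation, a simulation-trained **multiple-scattering
correction (MSC)** that converts the apparent lidar attenuation into the
diffuse attenuation coefficient, and the classic elastic-backscatter
inversions (slope, Fernald, perturbation) as baselines.

It is written for ocean-optics and lidar researchers who want to prototype
HSRL retrieval algorithms, quantify multiple-scattering biases for a given
acquisition geometry, or benchmark elastic-lidar inversions against a
two-channel instrument on controlled synthetic scenes.

## The science in brief

An oceanic HSRL splits the return into a **combined** channel `B_C` (all
backscatter) and a **molecular** channel `B_M` (only the Brillouin-shifted
seawater return, isolated by an iodine absorption cell).  Because the
seawater 180° volume scattering function `β_B^π` is known, the channel ratio
gives the particulate 180° return without assuming a lidar ratio:

    β_p^π(z) = β_B^π · (T_B · B_C(z)/B_M(z) − 1),      b_bp(z) = 2π·χ·β_p^π(z)

and the slope of the range-corrected molecular signal gives the apparent
lidar attenuation

    k_lidar(z) = −½ · d/d(z/cosθ_r) ln[ B_M(z)·(nH/cosθ_i + z/cosθ_r)² ].

`k_lidar` is **not** the diffuse attenuation `K_d`: multiple forward
scattering inside the receiver field of view makes it depth- and
FOV-dependent even in homogeneous water.  The MSC models that pattern as

    k_lidar(z) = m₁·e^(−m₂·z) + m₃ + a,

fits (m₁, m₂, m₃) on simulated homogeneous columns spanning the expected IOP
range, regresses each parameter on the backscattering coefficient `b_b`, and
inverts a measured profile through the embedded empirical relation of
Lee et al.:

    A(z) = k_lidar − m₁e^(−m₂z) − m₃            (≈ absorption)
    K_d(z) = A + 4.18·b_b·(1 − 0.52·e^(−10.8·A))

The lidar ratio `R(z) = (K_d − K_dw)/β_p^π` (sr) is then updated with the
corrected `K_d`.  Accuracy is reported as the root-mean-square relative
difference, `RMSRD(%) = 100·√(Σ(x_i/x̃_i − 1)²/N)`.

The forward model is a quasi-single small-angle approximation (QSSA) using a
Fournier–Forand particulate phase function, cross-checked by a semianalytic
Monte-Carlo transport of the same microphysics (see `docs/methods.md`).

## Worked example

```python
from oholidar import generate_scene, compare_methods

scene = generate_scene(
    {"template": "homogeneous", "n_columns": 2, "a": 0.08, "b_b": 0.004,
     "geometry": {"theta_i_deg": 40.0}}, seed=7)
report = compare_methods(scene)
for method, entry in report.metrics.items():
    print(f"{method:13s} K_d RMSRD {entry['K_d']['rmsrd_percent']:6.2f} %   "
          f"b_bp RMSRD {entry['b_bp']['rmsrd_percent']:8.2f} %")
```

prints

```
hsrl          K_d RMSRD  33.09 %   b_bp RMSRD     0.00 %
hsrl_msc      K_d RMSRD   0.45 %   b_bp RMSRD     0.00 %
fernald_100   K_d RMSRD  24.34 %   b_bp RMSRD    46.66 %
fernald_200   K_d RMSRD  24.60 %   b_bp RMSRD    50.33 %
perturbation  K_d RMSRD  33.67 %   b_bp RMSRD    60.64 %
```

Reading: on a moderately turbid homogeneous column (a = 0.08 m⁻¹,
b_b = 0.004 m⁻¹) the raw HSRL attenuation (`hsrl`) overshoots the true `K_d`
by ~33 % because of multiple scattering; the correction (`hsrl_msc`) brings
it to 0.45 %.  The HSRL channel ratio recovers `b_bp` essentially exactly on
a noiseless scene, while every elastic inversion — which must assume a lidar
ratio or a bio-optical closure — is tens of percent off on both products.

The same stages are available from a shell:

```bash
oholidar simulate --config scene.yaml --seed 3 --out raw.nc
oholidar preprocess --in raw.nc --out pre.nc
oholidar retrieve --in pre.nc --out ret.nc
oholidar msc-train --incidence-deg 40 --out msc.json
oholidar msc-apply --in ret.nc --model msc.json --out products.nc
oholidar elastic --in pre.nc --method fernald --lidar-ratio 100 --out fernald.nc
oholidar compare --config compare.yaml --seed 5 --out report.json
```

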