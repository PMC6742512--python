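# ppixmap

Wide-field spectrally resolved **quantitative PpIX fluorescence imaging** in
Python: from dual-illumination hyperspectral cubes to per-pixel
protoporphyrin IX concentration maps, with TV-regularized reconstruction, a
physics-based phantom simulator, and histology correlation tools.

## Who this is for

5-ALA-induced PpIX gives fluorescent contrast between glioma and normal
brain tissue during resection surgery, but the raw emission intensity is
distorted by the tissue's optical absorption (hemoglobin) and scattering, by
the illumination geometry, and by acquisition noise — so raw fluorescence is
a poor proxy for fluorophore concentration. This package implements the full
computational side of a wide-field spectral quantification system for people
who want to study, extend, or benchmark such pipelines without hardware: the
simulator generates realistic phantom acquisitions, and the reconstruction
stack turns cubes into calibrated concentration maps in µg/ml.

## The model

A measurement consists of four hyperspectral cubes (x, y, λ) on a
400–720 nm grid in 10-nm steps: fluorescence under 405-nm (UV) excitation,
diffuse reflectance under white light, and two reference cubes acquired from
a diffuse reflector under the same illuminations. After normalizing each
measurement to its reference (which cancels the lighting/collection
geometry), the per-pixel fluorescence on the emission band is modeled as

    F(λ) = (1 − R̄'_ex) [R'_em(λ)]^q f_basic(λ) C + ε,   λ ∈ [600, 720] nm

where `R'_em(λ)` is the normalized diffuse reflectance at the emission band,
`R̄'_ex` its excitation-side average over the 430/440/450-nm bands,
`f_basic(λ)` the unit-concentration PpIX emission spectrum, `q` an
empirical attenuation exponent (default 2.6, recoverable from phantom data
with `calibrate_q`), and `C` the PpIX concentration. With the kernel
`h(λ) = (1 − R̄'_ex)[R'_em(λ)]^q f_basic(λ)` the per-pixel least-squares
estimate is `C_ls = ⟨F, h⟩ / ⟨h, h⟩`.

Under short exposures `C_ls` is noisy, so the map is restored by solving the
isotropic **TV-L1** denoising problem

    min_C  Σ |C − C_ls|  +  δ · Σ ‖∇C‖₂

with a Chambolle–Pock primal–dual solver. The L1 data term preserves the
concentration level of piecewise-constant structures; δ presets are 3.0
(tissue-range maps) and 40 (phantom-range maps), and `select_delta` scans δ
against a ground-truth map by RMSE.

The phantom simulator builds intralipid/hemoglobin/PpIX scenes whose optical
properties are anchored to measured values (1% intralipid → µs′ = 10.94 /
5.88 cm⁻¹ at 410/640 nm; 1 mg/ml hemoglobin → µa = 10.85 / 0.16 cm⁻¹),
computes diffuse reflectance with a semi-infinite diffusion-approximation
closed form, applies angled elliptical-Gaussian illumination, and adds
seeded Gaussian noise — then the exact inverse path above recovers the
ground-truth concentration to machine precision in the noiseless limit.

## Worked example

Simulate the structured phantom — a fluorescent glyph-shaped inclusion
(2.0% IL, 2.5 mg/ml Hb, 0.2 µg/ml PpIX) on a nonfluorescent bed — at a
short-exposure-like noise level, reconstruct, and denoise:

```python
import numpy as np
import ppixmap as pm
from ppixmap.containers import ROIPatch
from ppixmap.tv import TVParams

basis = pm.load_emission_basis()
scene = pm.make_logo_scene(pm.default_logo_mask((256, 256)))
cubes = pm.simulate_acquisition(
    scene,
    pm.IlluminationProfile.for_shape(scene.shape),
    pm.IlluminationProfile.for_shape(scene.shape, angle=-0.2),
    pm.NoiseModel(sigma_rel=0.03, seed=7),
    basis, q_true=2.6,
)

c_ls = pm.reconstruct_ls(cubes, basis, q=2.6)
scan = pm.select_delta(c_ls, scene.concentration_map(),
                       np.geomspace(0.1, 11.0, 20), TVParams(max_iters=300))
c_tv = pm.tv_denoise(c_ls, TVParams(delta=scan.best_delta, max_iters=300)).field

roi = ROIPatch.centered((256, 256), 50, 50)
bkg = ROIPatch(8, 8, 50, 50)
print(f"best delta        {scan.best_delta:.2f}")
print(f"CNR (C_ls)        {pm.cnr(c_ls, roi, bkg).cnr:.1f}")
print(f"CNR (C_TV)        {pm.cnr(c_tv, roi, bkg).cnr:.1f}")
```

Output:

```
best delta        1.52
CNR (C_ls)        3.5
CNR (C_TV)        42.3
RMSE vs truth     0.0746 -> 0.0598 ug/ml
inclusion mean    0.204 ug/ml (true 0.200)
```

The RMSE–δ curve has its knee near δ ≈ 1 and stays flat for a decade above
it; TV reconstruction raises the contrast-to-noise ratio by an order of
magnitude here while the inclusion's concentration level survives within 2%.

The same workflow is scriptable from the shell:

```bash
ppixmap simulate --out acq/ --size 256 --noise 0.03 --seed 7
ppixmap reconstruct --cubes acq/ --preset phantom --out recon/
ppixmap evaluate --map recon/c_tv.tif --gt acq/c_gt.tif \
                 --roi 103,103,50,50 --bkg 8,8,50,50
```

Other commands: `denoise`, `delta-scan`, `rgb`, `calibrate-q`, and the
`histology` group (`segment`, `profile`, `correlate`) for H&E
nuclear–cytoplasmic ratio profiles and their spatial correlation with
concentration maps.

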