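# Methods

This note documents the models, parameter choices and numerical decisions
behind `ppixmap`, and what the simulator-based tests do and do not
demonstrate about real acquisitions.

## Acquisition model and calibration

A measurement is four cubes on the 400–720 nm, 10-nm grid (33 bands):
fluorescence under UV (405-nm) excitation, diffuse reflectance under white
light, and one reference cube per illumination acquired from a diffuse
reflector. All quantification happens on normalized quantities:

* `R'_em(λ) = R_white(λ) / R_ref,white(λ)` on the 600–720 nm emission band;
* `R'_ex(λ) = R_uv(λ) / R_ref,uv(λ)`, summarized as the unweighted mean
  `R̄'_ex` over the 430/440/450-nm bands;
* the emission-band fluorescence is likewise divided by the UV reference
  cube. This third normalization is what makes the estimate independent of
  the (heterogeneous, angled-Gaussian) illumination field: in the noiseless
  limit the forward model cancels exactly and the inverse recovers the true
  concentration to machine precision at every unmasked pixel.

Exposure-time differences between a measurement and its reference are
compensated by the ratio of exposures before division. Pixels where the
reference falls below a floor (default 10⁻³ of the reference cube's global
maximum) at any band are masked rather than zero-filled — ratios explode at
the dark edge of the illumination spot. Masks only ever shrink along the
pipeline; no stage revalidates a masked pixel.

## Quantification

Per pixel, the emission-band model kernel is

    h(λ) = (1 − R̄'_ex) [R'_em(λ)]^q f_basic(λ)

and the least-squares concentration is the exact minimizer of
`‖h·C − F‖²`, namely `C_ls = ⟨F, h⟩ / ⟨h, h⟩`. A variant dividing by
`‖h‖₂` instead of `‖h‖₂²` is exposed (`variant="printed"`) for comparison
with formulations that normalize by the kernel norm; it is not the true
minimizer and is never the default.

Choices that matter:

* **q (attenuation exponent), default 2.6.** An empirical calibration
  factor; `calibrate_q` recovers it from a phantom series by maximizing the
  estimated-vs-true R² over a grid (ties go to the smaller q). On simulated
  data with q_true = 2.6 the recovery is exact to the grid step (±0.1).
* **R̄'_ex clamp.** Normalized reflectance can exceed 1 on specular pixels,
  which would flip the kernel sign; R̄'_ex is clamped into [0, 1−10⁻⁶) and
  clamped pixels are counted and logged.
* **µa at excitation.** The tissue absorption coefficient at the excitation
  band is not separately estimated (it is absorbed into the empirical
  calibration); `build_kernel` accepts no tissue-absorption input.
* **f_basic and absolute units.** The packaged emission basis is a synthetic
  two-Gaussian digitization of the PpIX emission shape (main band at 637 nm,
  vibronic shoulder near 704 nm), peak-normalized on load; any 2-column CSV
  can replace it. Absolute µg/ml units come solely from `calibrate_scale`
  against one phantom of known concentration.
* **Valdés-style correction.** The alternative band-integral correction
  `F / (Φ_ex · Φ_em^α)` is provided as a baseline; Φ integrals use the
  trapezoid rule over the 460/470/480 and 620/630/640-nm band centers
  (matching 465–485 and 625–645 nm at 10-nm resolution). In the limit of
  spatially constant reflectance, flat across the emission band, and α = q,
  it agrees with the model-based equalization up to a global scalar.

## TV-regularized reconstruction

`C_ls` is restored by the isotropic TV-L1 model

    min_C  Σ|C − C_ls| + δ·Σ√((∂x C)² + (∂y C)²)

with forward differences and replicate boundaries, solved by the
Chambolle–Pock primal–dual algorithm. Decisions:

* **L1 data term.** The data fidelity is L1 (prox = soft-shrinkage toward
  `C_ls`), which makes the model contrast-invariant: whether a structure
  survives depends on its geometry (roughly area/perimeter vs δ), not its
  amplitude, and surviving structures keep their concentration level. An L2
  data term is available behind `data_term="l2"` for sensitivity checks
  only.
* **Step sizes.** The operator bound is L² = 8. Symmetric steps
  τ = σ = 1/√8 stall for moderate-to-large δ: the L1 prox shrinks by τ per
  iteration while the dual variable charges by σ·|∇u| toward the δ-ball
  boundary, so the primal iterate can sit frozen for hundreds of
  iterations. The default therefore rebalances τ = 1/(√8·max(1, δ)),
  σ = max(1, δ)/√8 (τσL² = 1); explicit steps are validated against
  τσL² ≤ 1.
* **Stopping.** Convergence is declared when the relative change of the
  primal *and* dual iterates both drop below `tol` (default 10⁻⁶), capped at
  `max_iters` (default 500). The solver is deterministic.
* **Masks.** Masked pixels are held at their input values and excluded from
  gradient coupling across the mask boundary.
* **δ presets.** δ multiplies the TV term of a map in µg/ml, so it is
  scale-dependent; shipped presets are 3.0 for tissue-range maps and 40 for
  phantom-range maps. `select_delta` scans a grid and returns the
  RMSE-argmin against a ground-truth map (ties toward smaller δ). On the
  simulated structured phantom the RMSE–δ curve has its knee near δ ≈ 1 and
  varies by <10% over the following decade — but the upper end of the flat
  region is set by the erosion threshold of the inclusion, which scales
  with its radius in pixels, so the full-decade flatness holds at the
  256-pixel evaluation scale and shortens on smaller fixtures.

Solver correctness is tested against exhaustive oracles: a transfer-matrix
dynamic program over column bit-patterns gives the exact TV-L1 optimum over
all two-level images on small grids (equivalent to enumerating 2^36
candidates on 6×6), and a level-set DP gives the exact 1-D optimum; the
solver's objective must reach both.

## Phantom simulator

The simulator is the package's study-condition generator, not a fixture:

* **Optical properties.** µs′(λ) scales linearly with intralipid volume
  fraction via a Mie-type power law a·(λ/500)⁻ᵇ fitted so 1% IL gives
  10.94 cm⁻¹ at 410 nm and 5.88 cm⁻¹ at 640 nm; µa(λ) scales linearly with
  hemoglobin via a packaged absorption shape (synthetic hemoglobin-like
  curve: Soret band near 410 nm, weak Q-band structure, long red tail)
  rescaled to the 410-nm anchor (10.85 cm⁻¹ per mg/ml) with a mild
  exponential tilt pinning the 640-nm anchor (0.16 cm⁻¹ per mg/ml) exactly.
  PpIX contributes no absorption: at ≤5 µg/ml its contribution is
  negligible against hemoglobin. The composition-table cross-checks hold to
  ±0.01 cm⁻¹ on the anchored columns.
* **Diffuse reflectance.** Semi-infinite diffusion-approximation closed
  form `R_d = a′ / (1 + 2k(1−a′) + (1 + 2k/3)√(3(1−a′)))` with transport
  albedo a′ = µs′/(µa+µs′) and internal-reflection parameter
  k = (1+r_d)/(1−r_d) from the standard Groenhuis/Egan polynomial
  (k ≈ 2.79 at n_rel = 1.33). Correct limits (R_d → 1 for a pure scatterer,
  0 for a pure absorber) and monotonicity in the albedo are contract-tested;
  the specific closed form is isolated behind `diffuse_reflectance` and can
  be swapped without touching anything else.
* **Excitation band.** The 405-nm excitation is represented by the 410-nm
  band of the 10-nm grid. The specular contamination sometimes seen at the
  excitation band on shiny surfaces is not simulated.
* **Forward signal.** The UV cube carries reflected light R_d(λ)·I_uv below
  600 nm and `(1−R̄'_ex)·R_d(λ)^q·f_basic(λ)·C·I_uv` on the emission band;
  the white-light cube is R_d(λ)·I_white; reference cubes are the bare
  illumination fields (an idealized spectrally flat reflector).
* **Noise.** Additive Gaussian, std = `sigma_rel` × the cube's peak signal,
  drawn per cube from child streams of one seed (bitwise reproducible);
  negative counts are clipped at zero. A signal-proportional (shot-like)
  mode is optional. The 20-ms "short exposure" condition is emulated purely
  through `sigma_rel` (0.03 in the evaluation workflows), roughly 15× the
  ground-truth-like level, rather than through exposure metadata.
* **Structured phantom.** The shipped inclusion glyph is a license-free
  disk-plus-bar shape (2.0% IL, 2.5 mg/ml Hb, 0.2 µg/ml PpIX inclusion on a
  nonfluorescent bed of the same optical properties), sized so a 50×50 ROI
  fits inside the disk.

What the simulator does **not** emulate: Monte-Carlo light transport,
layered or curved media, wavelength-dependent filter transmission and
camera quantum efficiency (flat by default), photobleaching and
self-quenching, tissue autofluorescence, and specular highlights. Passing
simulation tests therefore demonstrates the correctness and noise
robustness of the inverse pipeline under the stated forward model — not the
fidelity of that model to any particular instrument.

## Evaluation workflows

`ppixmap.experiments` packages the three desk-scale evaluations, each run
at 128×128 (sweeps) or 256×256 (structured phantom) — sizes chosen to keep
a full run in seconds while leaving ≥2500-pixel averaging patches:

* **Concentration linearity** — all 16 phantoms of a composition set,
  1% noise, central 50×50 averaging, OLS fit of estimated vs true
  concentration. Both sets reach R² > 0.999 under these conditions.
* **Spectral equalization** — raw vs corrected 640-nm peaks across the
  4-phantom absorber (or scatterer) sweep at 0.3 µg/ml PpIX; NRMSD is the
  RMS deviation from the mean divided by the mean, ×100 (mean-normalized
  form; range- and max-normalized variants are options). The correction
  collapses the spread by two orders of magnitude; the absorber sweep
  always deviates more than the scatterer sweep, matching the qualitative
  absorption-dominance of the distortion.
* **TV benefit** — structured phantom at `sigma_rel` 0.03, 20-point δ-scan,
  CNR before/after at the RMSE-optimal δ. CNR is (µ_ROI − µ_bkg)/σ_bkg with
  the population (denominator-N) standard deviation for determinism on
  small patches (sample form switchable).

## Histology

Nuclei are classified in the L*a*b* chroma plane against two fixed stain
references (hematoxylin violet-blue, eosin pink-red), refined by at most 20
two-cluster Lloyd iterations; chroma-based classification is insensitive to
±20% global brightness changes. The NC (nuclear–cytoplasmic) ratio is
operationalized as the nuclear **area fraction** per non-overlapping
0.05-mm window along the region's long axis (a nuclear/non-nuclear variant
is exposed as an option); with equal windows the profile mean equals the
mask's overall nuclear fraction. Correlation with a concentration map uses
an explicit user-supplied ROI patch (no automatic registration), averages
the map over the patch's short axis, resamples the NC profile onto the
concentration profile's normalized abscissa, and reports Pearson r with a
two-sided t-test p-value. The synthetic slide generator draws
non-overlapping ellipses at per-strip target densities (rejecting targets
above the ~0.5 random packing limit); at its default 0.005-mm pixels a
0.05-mm window holds only a couple of nuclei, so strip-scale windows are
the appropriate choice for profile-level comparisons on synthetic slides.

## Known limitations

* The diffusion-approximation reflectance is a closed-form stand-in; its
  absolute values (not just trends) should not be compared against
  measured reflectance spectra.
* δ is concentration-scale-dependent by construction; maps in different
  units need their own δ selection.
* The q exponent and the absolute concentration scale are empirical
  calibrations; transferring them between instruments (or from simulator to
  instrument) is not supported by anything tested here.
* NC-ratio definitions vary across the literature; the area-fraction
  reading is a documented choice, not a measured equivalence.
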