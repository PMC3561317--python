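# Methods

`photophys` implements the analysis chain of a pCO₂ × growth-light
photophysiology experiment on a coastal marine diatom grown in turbidostat
culture: seawater CO₂-system speciation, growth-rate extraction, the Platt
photoinhibition light response, single-turnover fluorescence induction
(σ_PSII), photoinactivation cross-sections (σ_i) from lincomycin
light-shift time courses, and per-cell biochemistry. A seeded synthetic
generator reproduces the structure of every instrument input with known
ground truth, so each stage's estimator can be validated by parameter
recovery.

## Seawater CO₂ system

The measured pair is electrode pH on the NBS scale and total dissolved
inorganic carbon (DIC, µmol kg⁻¹) at fixed T = 18 °C, S = 35, PO₄ =
21 µmol L⁻¹, Si = 52.5 µmol L⁻¹, surface pressure. With h the
hydrogen-ion term and K1, K2 the carbonic acid dissociation constants,
DIC is partitioned analytically,

    [CO2*]  = DIC·h² / (h² + K1·h + K1·K2)
    [HCO3⁻] = DIC·K1·h / (…),   [CO3²⁻] = DIC·K1·K2 / (…)

pCO₂ = [CO2*]/K0 (Weiss 1974 solubility; µatm reported as ppm, no
fugacity correction — a ~0.3 % effect). Total alkalinity adds borate
(total borate ∝ salinity), hydroxide, free H⁺, and phosphate and silicate
terms; the phosphate term uses the Peng convention (zero proton level at
H₃PO₄, i.e. the Dickson-style term plus total phosphate).
`ph_from_ta_dic` inverts TA(pH; DIC) by bracketed root finding on
pH ∈ [6, 10] (Brent, xtol 10⁻⁸), giving a dual-route consistency check
on the solver: speciate→TA→pH round-trips to <10⁻³ pH units across
pH 7.0–8.6 and DIC 1500–2500 µmol kg⁻¹.

**Choice of K1/K2.** Two formulations are built in. The default,
`"dm87"`, is the Dickson & Millero (1987) refit of the Hansson +
Mehrbach measurements, applied with h = 10^(−pH_NBS) taken directly from
the reported pH; `"mehrbach"` is the original Mehrbach et al. (1973)
NBS-scale fit. The default was chosen because the reference dataset of
culture carbonate conditions shipped with the package (10 rows of
measured pH/DIC with their originally reported derived values) is
internally consistent with pK1 = 5.926 ± 0.003 and pK2 = 9.049 ± 0.003
at 18 °C — matching the dm87 refit (5.914 / 9.057) and not the original
Mehrbach-NBS fit (6.038 / 9.209). With dm87, 49 of the 50 reported
TA/pCO₂/HCO₃⁻/CO₃²⁻/CO₂ cells are reproduced within 4.8 %; with the
original Mehrbach fit the CO₂ and CO₃²⁻ errors reach 15–35 %. Mixing a
refit defined on a concentration scale with an activity-based h is a
known practical approximation of electrode work; it is exactly what the
reference values imply, so it is adopted for reproduction runs and the
scale caveat is stated here rather than hidden.

Two cells of the reference table are internally anomalous and cannot be
matched by any constant choice: one row's pCO₂ (300 ppm) is inconsistent
with its own free CO₂ (9.1 µmol kg⁻¹) because their ratio implies a
solubility 12 % away from Weiss (and from the nine other rows), and one
row's TA (2110 µmol kg⁻¹) is a column outlier. The corresponding
acceptance checks report these honestly (one parametrized case fails at
13.7 %).

Treatment summaries use unweighted means across light levels within each
pCO₂ arm; the elevated-vs-ambient contrast is a percent change except pH,
reported as a difference. From the reference table these give free CO₂
+116 %, HCO₃⁻ +13.5 %, CO₃²⁻ −39.8 %, DIC +7.2 % and ΔpH −0.28; note the
DIC/pH contrasts reported alongside the original table (+7.8 % / −0.33)
do not follow from unweighted means of its printed columns — the original
averaging scheme is unstated, and no attempt is made to force agreement.

## Turbidostat growth rates

OD₆₈₀ rises exponentially until a set-point triggers a 10 % volumetric
dilution, dropping OD by ×0.9. Cycles are segmented wherever the
sample-to-sample relative OD drop exceeds `drop_threshold` (default 0.05,
half the dilution step — cleanly separated from the 1 % measurement
noise); segments with fewer than 4 samples are discarded. Each cycle is
fitted by linear regression on log OD (the exponential fit under
multiplicative noise; deterministic, no starting values), and the culture
rate is the unweighted mean over the last 10 complete cycles. At
steady state μ·T_cycle = ln(1/0.9), which the simulator reproduces and
the tests verify.

Precision note: a single 10 % dilution cycle spans only ~0.105 natural-log
units of OD, so the per-cycle rate estimate has relative standard error
≈ noise_sd·√12/ln(1/0.9)/√n regardless of μ — about 12 % for 8 samples at
1 % noise. Useful precision therefore comes from dense sampling plus
cycle averaging: the generator samples once per minute (the logging rate
of a culture photobioreactor's onboard OD sensor), which brings the
10-cycle mean within 5 % of truth in ≥95 % of replicates at 1 % noise.

## Platt light response

Growth (and MDA content) versus irradiance I is fitted with

    μ(I) = μ_s·(1 − exp(−α·I/μ_s))·exp(−β·I/μ_s)

by bounded nonlinear least squares (μ_s, α > 0, β ≥ 0). The curve
maximum has the closed form μ_max = μ_s·[α/(α+β)]·[β/(α+β)]^(β/α) at
I_opt = (μ_s/α)·ln((α+β)/β); for β → 0, μ_max = μ_s and no finite
optimum exists. Because β > 0 pulls the fitted peak above sparsely
sampled observations, fitted μ_max may legitimately exceed every measured
rate. 95 % CIs come from the curve-fit covariance (t, n−3 df); the
μ_max CI uses first-order error propagation through the closed form.
Replicate cultures enter at their actually measured irradiance, never
averaged to nominal levels. The estimator is exposed sklearn-style
(`PlattLightResponse().fit(I, mu)`), with `fit_platt` as a convenience
wrapper.

## Single-turnover fluorescence induction

During a saturating 80 µs single-turnover flash the fluorescence yield
rises from F₀ to F_M as PSII centers close. Fitting is done in the
cumulative-dose domain E(t) = flux·t (photons Å⁻²), which makes σ
independent of flash shape and time-grid choice:

    F(E) = F₀ + (F_M − F₀)·C(E),   B(E) = 1 − exp(−σE)
    C = B                        (isolated units)
    C = B(1−p)/(1 − pB)          (connectivity p, Joliot hyperbola)

σ_PSII is in Å² quanta⁻¹. Connectivity is fitted by default, seeded by a
p = 0 pre-fit and bounded to [0, 0.5] to stabilize low-information
curves; a curve whose final point stays below 95 % of the fitted F_M is
flagged unsaturated. Identifiability of p near 0 demands dense sampling:
at 1 % noise, 250 samples per flash (sub-µs digitization, the simulator
default) keep the fitted p below 0.05 in >90 % of p = 0 curves and σ
within 5 % in ~100 %; at 64 samples the σ–p trade-off inflates both.

F_V/F_M = (F_M − F₀)/F_M from the dark-adapted curve. The three-state
protocol (5 min dark; 2 min growth light → σ′; 2 min at
450 µmol photons m⁻² s⁻¹ → σ″) fits each state's curve. qP =
(F_M′ − F_S)/(F_M′ − F₀′) with F_S the fitted baseline of the
growth-light curve; F₀′ is approximated by the dark-adapted F₀, justified
by the protocol's own observation that σ′ ≈ σ (negligible antenna
quenching at growth light, so F₀ is nearly state-independent). Values of
F_S slightly outside [F₀′, F_M′] are clipped (instrument noise); more
than 5 % outside raises.

## Photoinactivation cross-section

With chloroplast translation blocked by lincomycin (no PSII repair), the
yield declines with cumulative incident photon dose per single-hit target
theory: F_V/F_M(E) = y₀·exp(−σ_i·E), with E = irradiance·10⁻⁶·N_A·10⁻²⁰·t
photons Å⁻² (450 µmol photons m⁻² s⁻¹ for 90 min gives 1.463×10⁴).
y₀ is estimated rather than pinned to the t = 0 measurement; the fit runs
on a unit-scaled dose axis so results are independent of the dose units
carried in. A rise of F_V/F_M after the shift back to growth light is
attributed to slow NPQ relaxation; its amplitude (max recovery minus the
90-min value, clamped at ≥0) is added to treatment-phase samples after
t = 0 before fitting, and flagged negligible below 0.02. This additive
offset is a first-order correction: a multiplicative quenching of a
decaying curve cannot be removed exactly by one constant, and the
estimated amplitude is diluted by any photoinactivation continuing at
growth light — the tests therefore assert that the correction moves the
estimate toward truth, not that it nulls the bias. Derived metrics:
photoinactivation rate k_pi = σ_i × photon flux (s⁻¹; ≈2.2×10⁻⁴ s⁻¹ at
σ_i = 8×10⁻⁵ Å² and 450 µmol photons m⁻² s⁻¹) and the return-on-investment
ratio σ_PSII/σ_i (~10⁶ for the magnitudes above, i.e. millions of
charge separations per photoinactivation).

## Per-cell biochemistry

Chl a uses the Jeffrey & Humphrey (1975) 90 %-acetone equation for chl a
with c pigments, 11.47·(A₆₆₄−A₇₅₀) − 0.40·(A₆₃₀−A₇₅₀) µg mL⁻¹, with A₇₅₀
as turbidity blank; the per-cell value scales through the pigment
dilution (default 30 µL of protein extract into a final 500 µL acetone,
factor 500/30, kept configurable since only the pipetted volumes are
known), the extract volume, the volume filtered and the cell density.
MDA (TBARS) is (A₅₃₂ − A₆₀₀)·6.45 µM in the reaction mix (0.35 mL
homogenate aliquot + 0.35 mL reagent out of a 0.8 mL homogenate),
converted to attomol cell⁻¹. Coefficients are covered by exact
round-trip tests (absorbance generation inverted by the analysis) rather
than absolute standards. C:N is a plain molar ratio; the Chl:protein
mass ratio is computed from paired same-extract values so a common
extraction-efficiency factor cancels; photosynthetic-complex subunit
inputs are accepted pre-quantified (attomol cell⁻¹) and only ratioed
against PsbD.

## Synthetic data

The generator emulates the full 2 pCO₂ × 5 light × 3 replicate design.
Its defaults are the study conditions: lights 30–380 µmol photons m⁻²
s⁻¹ with 2 % replicate-level lamp variation; ambient-arm growth truth a
Platt curve peaking at 1.8 d⁻¹ and elevated-arm at 2.3 d⁻¹ (converging
under super-saturating light); σ_PSII declining 322→210 Å² with light;
σ_i linear in μ in the ambient arm (7.3–9.3×10⁻⁵ Å² over the realized μ
range) and flat at 7×10⁻⁵ Å² in the elevated arm; qP 0.89→0.63;
Chl 0.22→0.08 pg cell⁻¹; MDA ≈10→22→15 attomol cell⁻¹ (elevated arm
raised at low light); C 0.65 pmol cell⁻¹ with C:N 5.1–7.4; F_V/F_M 0.65;
repair rate 8×10⁻⁴ s⁻¹ in the minus-lincomycin flask; NPQ amplitude 0.02
relaxing with τ = 15 min. Noise: multiplicative lognormal on OD (1 %),
additive Gaussian on fluorescence (1 % of F_V), F_V/F_M (0.01), pH
(0.02) and DIC (25 µmol kg⁻¹), 3 % CV on biochemistry. Carbonate samples
are solved to be exactly consistent with the target pCO₂ at TA = 2300
µmol kg⁻¹ before measurement noise. Randomness flows from one seed
through fixed spawn keys per stream, so regeneration is byte-identical
and adding a generator never perturbs existing streams; every generator
has a noiseless mode satisfying its model identity exactly.

What the generator does not emulate: genuine biological replicate
variance beyond measurement noise, instrument drift and baseline
artifacts, cross-instrument fluorescence-unit differences, light-history
carry-over between protocol states, and two-phase or plateau decay
kinetics. Passing recovery tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to structured
real-world artifacts.

## Statistics layer

Confidence bands are pointwise 95 % intervals on the mean prediction
(t with n−p df; delta method through the parameter covariance for the
Platt model). One-way ANOVA is followed by all-pairs pooled-variance t
tests with the classic Bonferroni multiplier (raw p × number of pairs,
capped at 1; N−k error df) — for two groups F = t² exactly. Nested fits
are compared with the extra-sum-of-squares F test; the simpler model is
preferred unless p < 0.05. The family-wise error test verifies the
Bonferroni guarantee against the binomial sampling envelope of a
rate-0.05 process, the correct one-sided check for an inequality at the
boundary. The paper-style figure regressions are exposed as 'linear',
'poly2' (default polynomial order 2, configurable) and 'platt'.

## Known limitations

- The CO₂ solver supports only the (pH, DIC) and (TA, DIC) input pairs,
  NBS-convention constants, surface pressure, no uncertainty propagation.
- σ_i assumes a single first-order target with full inactivation at
  infinite dose (no plateau, no two-step mechanism, no UV weighting);
  repair appears only in the simulator, not as a fitted quantity.
- qP relies on F₀′ ≈ F₀; under strong growth-light NPQ this overestimates
  the open fraction.
- The additive NPQ correction is first-order (see above).
- Cross-instrument fluorescence scaling is not modelled; yields are
  treated as per-instrument dimensionless ratios.
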