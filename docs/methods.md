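# Methods

## Physical model

A FIDA measurement pushes a short plug of fluorescent indicator through a
coated fused-silica capillary (defaults: 75 µm inner diameter, 1 m total
length, detection window 84 cm from the inlet) by pressure-driven laminar
flow. The four-step program (75 s equilibration at 3500 mbar, 20 s analyte
load at 3500 mbar, 10 s indicator injection at 50 mbar, 180 s mobilization
at 400 mbar during which data are recorded) is the package default and is
fully configurable. The cross-section-averaged Poiseuille velocity is
v = ΔP·r²/(8ηL); at 400 mbar with water-like viscosity this gives a 106 s
transit to the window, which bounds the in-capillary reaction time for
capmix experiments (~1.8 min) — binders with slow association under-read,
and the titration simulator exposes an optional (k_on, k_off) equilibration
factor 1 − exp(−(k_on[B] + k_off)·t_contact) to model exactly that.

In the Taylor–Aris regime (dimensionless residence time
τ = D·t_R/r² ≥ 1.4, checked on every fit and flagged as `TAYLOR_INVALID`
below the bound) the plug elutes as a near-Gaussian peak with temporal
variance σ_t² = r²·t_R/(24·D) for cross-section-averaged detection. The
equivalent bookkeeping via the effective axial dispersion coefficient
K = v²r²/(48D) + D (σ_x² = 2Kt, σ_t = σ_x/v) is algebraically identical and
is what the brute-force oracle integrates. R_h follows from Stokes–Einstein,
R_h = k_B·T/(6πηD), with defaults T = 298.15 K and η = 8.9×10⁻⁴ Pa·s
(water at 25 °C) — neither is a measured fact of any particular instrument;
both are configurable, and a salt-corrected buffer viscosity belongs in the
method config.

The finite injection plug (10 s at 50 mbar ≈ 1 cm) adds a top-hat of
temporal width w = plug_length/v_mobilize, i.e. variance w²/12, which the
simulator adds in quadrature and the fitter subtracts by default
(`subtract_plug_sigma=False` mimics an idealized point-injection analysis;
whether commercial software subtracts it is not public, so both behaviors
are exposed).

## Peak fitting

Baseline and noise come from the trace flanks (first and last 10% of
samples): baseline is the pooled flank median, noise the flank MAD × 1.4826,
and the *mismatch score* |pre-flank − post-flank| / peak height detects
buffer/lysate composition mismatch (score > 0.05 → `BASELINE_MISMATCH`).
S/N below 50 → `LOW_SNR`.

The Gaussian fit is two-pass: pass 1 fits (amplitude, t_R, σ, baseline) on
the whole trace; pass 2 refits (amplitude, t_R, σ) inside the "Taylorgram
fraction" window — the region where the pass-1 model exceeds
(1 − fraction) of peak height, default fraction 0.75 — with the baseline
frozen at its pass-1 value. Two details matter and were found empirically:

* the window must come from the fitted model, not from thresholding the
  noisy samples (selection correlated with noise biases σ low by several
  percent at S/N 50);
* the baseline cannot be refitted from top-of-peak points alone (it is
  nearly collinear with σ there and inflates the width variance ~4-fold).

The vendor definition of "Taylorgram fraction" is not public; fitting the
points above (1 − fraction) of peak height is this package's documented
interpretation (an alternative — the central 75% of peak area — was
considered and rejected as it complicates the two-species model for no
observed benefit on synthetic data).

Two-species mode locks the second species' radius (e.g. 0.6 nm for
hydrolysed free label), shares t_R between the species, computes the locked
width from the locked radius at the shared t_R, and reports the main
species' radius plus its amplitude fraction. With the locked amplitude at
zero it reduces exactly to the single-species fit.

Viscosity normalization divides the apparent R_h by f = t_R/t_R(buffer):
a sample f× more viscous slows the flow and the diffusion by the same
factor, so t_R and the apparent radius are both inflated by f. f < 0.8
triggers a warning (faster-than-buffer elution is physically suspicious).

## Binding model

The bound fraction uses the exact 1:1 mass-action solution with indicator
depletion, evaluated in the cancellation-free form
f_b = 2B/(S + √(S² − 4IB)), S = I + B + K_D (the textbook
(S − √·)/(2I) form loses ~10 significant digits when 4IB ≪ S²; the package
form matches a bisection solver to <10⁻¹⁰ relative everywhere tested).
Apparent R_h under fast exchange is the population-weighted arithmetic mean
of R_h (vendor convention); a diffusivity-weighted (harmonic in R_h)
alternative is available via `average="diffusivity"` — it is lower at
intermediate saturation and identical at the endpoints. K_D is fitted by
weighted least squares on a log₁₀ scale within [10⁻¹², 10⁻²] M; standard
errors come from the covariance (delta method for K_D). R_h,free is fixed
to the separately measured indicator value by default; fitting it instead
changes noiseless fits by <0.5%. Flat titrations and bound-pinned fits
return explicit non-converged results, never silent numbers.

## Synthetic data: what it emulates, what it does not

The simulator reproduces the statistical structure of lysate screening
campaigns: per-species Gaussian peaks with plug broadening; lysate
autofluorescence (constant offset), a smoothed baseline-mismatch step
across the peak, and a nonspecific R_h shift, all decaying as 1/dilution;
viscosity relaxing as f(d) = 1 + (f₀ − 1)/d (ideal mixing — no functional
form is published, so the simplest physically sensible one is used);
additive i.i.d. Gaussian detector noise from a single explicit seed.

Defaults state the campaign world once: indicator 200 nM in screens
(50–80 nM in titrations), triplicates, dilution ladder 1:2…1:100,
expression 50–150 µM at stock, true K_D between 44.1 nM and 10 µM, complex
radii ~2× the free indicator for the peptide tag and +8…22% for the
two-domain target. Lysate defaults — heat: viscosity 1.4× at stock,
nonspecific shift 1.2 nm at stock; chemical: 1.25× and 15 nm — are
calibrated to reproduce the qualitative screening pattern (nonspecific
shifts dominate at low dilution; heat lysis cleans up by 1:30; chemical
lysis never does within the ladder), not to any quantitative measurement:
no quantitative lysate data exist to calibrate against. The preculture
control carries the lysate matrix but no expressed protein, hence no
nonspecific shift — the shift is attributed to the overexpressed candidate,
which dominates the lysate's protein content.

Not modelled: shot noise (additive Gaussian only), adsorption/tailing peak
shapes, >2 species, expression biology, radial hydrodynamics. A green
campaign test therefore establishes that the *decision rules* behave as
described under the stated noise model, not that any particular instrument
will show the same false-positive counts.

### The finite-difference oracle

`pde_oracle` integrates ∂c/∂t = K∂²c/∂x² − v∂c/∂x (FTCS with the
forward-time anti-diffusion −v²Δt/2 folded back into K, a Danckwerts
zero-net-flux inlet, free outflow, and an initial top-hat plug of the
physical injection length), recording c(L_d, t). It shares only the value
of K with the closed-form pipeline and is used purely as a test oracle.
Grids that violate the stability/resolution bounds (cell Péclet ≥ 2,
unresolved plug) are refused, never silently integrated.

The exact fixed-detector profile is skewed at order σ/t_R
(c ∝ t^(−1/2)·exp(−t_R(t_R−t)²/(2σ²t))). Fitting a plain Gaussian to only
the top 75% of that skewed peak biases R_h by −2% (1.15 nm) to −9% (5 nm);
with the full peak the bias is under ~2% at all radii tested. The
oracle-equivalence tests therefore use `taylorgram_fraction=1.0`; the 0.75
default applies to instrument-like traces, which this package's forward
model generates as symmetric Gaussians (where the window is unbiased).

## Hit calling

*Threshold rule*: hit iff mean R_h ≥ (1 + θ)·reference, default θ = 0.10.
The reference (indicator alone for purified screens, matched preculture for
lysate screens) is always supplied by the caller, never inferred.

*Statistical rule*: one-way ANOVA context with Dunnett's many-to-one
comparison of each candidate group against the control (scipy
implementation), one-sided greater — binding can only increase R_h.
Technical triplicates are used as the test's n, with the standard caveat:
with very tight replicates, sub-threshold nonspecific shifts become
"significant", so statistically significant hits with small R_h changes
deserve skepticism. Per-dilution tests are run independently (a one-way
simplification of a two-factor dilution × candidate design). The null
family-wise error rate is validated by simulation in the test suite
(0.044 over 1000 null campaigns at α = 0.05).

The package recommends the statistical rule whenever the predicted complex
size change is below 2θ.

## Size prediction

Two routes: empirical power laws in chain length N
(folded R_h = 4.75·N^0.29 Å; disordered R_h = 2.49·N^0.509 Å — standard
literature coefficients; a 13-residue folded peptide predicts 1.0 nm), and
the Kirkwood double-sum over atomic beads,
1/R_h = (1/N²)[Σᵢ 1/aᵢ + Σ_{i≠j} 1/r_ij], with bead radii aᵢ = van der
Waals radius + hydration shell (default 1.9 Å, in the 1–3 Å range used by
atomic bead models).

**Known limitation (important):** the Kirkwood sum saturates in the bead
radius — as aᵢ grows, 1/R_h approaches the purely geometric cross term
Σ1/r_ij / N², which for an ideal 13-residue α-helix caps R_h at ~0.70 nm,
~30% below the power-law value, with heavy-atom representations worse
(bonded pairs at ~1.5 Å inflate the cross term). No hydration shell can
close that gap, and no empirical rescaling is applied because the
closed-form bead identities (single bead → R_h = a; two beads →
2ad/(a + d)) are part of the module's contract. Structure-based
predictions of sub-nanometre species should be treated as lower bounds;
for proteins above a few kDa the known Kirkwood bias is the generic ~10–20%
underestimate of compact-body radii, consistent with the ~9% error such
predictors carry against measurement. The power law is the primary
predictor for small peptides.

## Numerical conventions

Pressures are mbar at every interface (Pa internally); lengths metres;
R_h nanometres in user-facing tables, metres in the physics layer.
k_B = 1.380649×10⁻²³ J/K exactly. Replicate summaries report the sample SD
(ddof = 1) and NaN — never 0 — for n = 1. K_D ties at equal residual are
broken toward the smaller K_D by the log-scale lower bound of the search.
All randomness flows from one explicit seed (numpy Generator); identical
seeds give bit-identical traces, sheets and tables.
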