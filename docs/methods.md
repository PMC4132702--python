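# Methods

## The excision mechanism and its observables

The package models glycosylase-initiated base excision as

    E + S  <==>[k_on, k_off]  ES  -->[k_chem]  EP  -->[k_pd]  E + P

with mass-action kinetics, `k_off = K_D · k_on`, and irreversible product
release (product rebinding is off by default: release of the enzyme from
its AP-site product is the measured turnover step, and rebinding would
fold that signal back into the trace). Only `active_fraction ×
enzyme_total` participates; partially active preparations are the norm
for purified glycosylases.

**What "product" means.** The gel-based excision assay heat-inactivates
the enzyme and then cleaves all AP-sites before electrophoresis, so the
quantified band is *all cleaved substrate*, i.e. `[EP] + [P]`, not free
product alone. The ODE simulator therefore reports `[EP] + [P]` as its
product trace. This is what makes the single-turnover rate reflect
`k_chem` (chemistry converts ES to EP, which is immediately visible)
while the multiple-turnover linear phase reflects `k_pd` (the enzyme must
vacate EP before it can process another substrate molecule).

Closed-form limits used throughout:

* STO (E ≫ S, binding fast): `[P] = A₀(1 − exp(−k_obs t))` with
  `k_obs = k_chem · E/(E + K_D) ≈ k_chem`.
* Burst (S ≫ E): `[P] = A₀(1 − exp(−k_obs t)) + k_ss t`, burst amplitude
  `A₀ ≈` active enzyme, steady-state slope `k_ss = k_pd · A₀ ·
  occupancy`, where the EP occupancy `1/(1 + k_pd/k_chem + k_pd/(k_on·S))`
  approaches 1 in the turnover-limited regime `k_chem ≫ k_pd`. At
  `k_chem/k_pd ≈ 20` the occupancy correction is still ≈5%, so tests of
  the "slope = k_pd·A₀" limit use a deeper separation.

**Turnover number.** `k_pd = k_ss / A₀` — forced by dimensional analysis
(`nM·min⁻¹ / nM = min⁻¹`). The inverted ratio `A₀/k_ss` (minutes) is the
mean residence time on product, not a rate, and is used only as a
deliberate-bug sentinel in report validation.

## Fitting

All fits are bounded (non-negative) trust-region nonlinear least squares
(`scipy.optimize.least_squares`, `x_scale='jac'`, tolerances 1e-15).
Initialization:

* STO: `A₀ ← max(product)`, `k_obs ← ln2 / t(half-max)` (ties broken by
  earliest index).
* Burst: a line through the final third of points gives `k_ss` (slope)
  and `A₀` (intercept); `k_obs` from the half-rise of the de-trended
  burst. The amplitude is bounded above by the curve's total enzyme.
* Half-life: `percent = plateau(1 − exp(−k t))`, plateau ∈ (0, 100],
  `t₁/₂ = ln2/k`.

Standard errors come from the local linearization,
`cov = (JᵀJ)⁻¹ · RSS/(n − p)`; `k_pd` and `t₁/₂` SEs by the delta method
(parameter correlation ignored — adequate for the well-conditioned
noise-free and low-CV regimes exercised here). Degenerate inputs:
all-zero traces return flagged results with `A₀ = 0` and an undefined
rate rather than silent numbers; non-convergence sets a flag.

Replicates are fitted independently and parameters averaged; group
comparisons pool all replicate-level values (the assays were run in
triplicate, and comparing "all non-hotspot values with all hotspot
values" at replicate level is what makes the two-group half-life
comparison significant — the five codon means alone do not reach
p < 0.05 under the pooled Student's t-test).

## In-cell repair quantification

The qPCR readout uses the amplification-blocking model: unrepaired
lesions are converted to nicked template that cannot amplify, so the
amplifiable fraction *is* the repaired fraction,
`fraction = E^(Ct_ref − Ct_sample)` with per-cycle efficiency
E ∈ (1, 2], default 2.0. Whether the original assay normalized to a
co-transfected control amplicon is not recoverable from the main text;
this formula is a declared stand-in and is exactly inverted by the
Ct-table generator (round-trip identity to 1e-12).

Repair time courses are modeled as a single-exponential approach to a
plateau (default 100%). The true in-cell curve shape is not derivable
from the published text; the exponential makes `t₁/₂` well defined and
matches saturating behavior. Two estimators are provided:
`exponential_fit` (default) and `linear_interpolation` (first 50%
crossing); on noise-free dense sampling they agree to <2%. Curves that
never reach 50% are *censored*, reported as a lower bound at the last
harvest time (48 h by default), never as infinity — this covers the
glycosylase-null control in which no repair is detectable.

The in-cell time axis is assay time with t = 0 at first harvest; the 5-h
post-transfection offset of the original protocol is metadata only.

## Statistical choices

Group comparison is the unpaired two-tailed Student's t-test with pooled
(equal) variance — Welch's correction is deliberately not applied, to
match the published analysis. The degenerate zero-variance/equal-means
case returns t = 0, p = 1. The sign convention is group a minus group b,
with a = non-hotspot. No multiple-testing correction is applied by
default (single pooled test per table); a Bonferroni option exists in the
run config.

Mixing-standard linearity is ordinary least squares of observed on
expected percent; slopes, intercepts and R² are reported and an
experiment needs ≥3 distinct expected levels.

## SPR binding

1:1 Langmuir kinetics only: association
`R(t) = Req(1 − exp(−(k_a C + k_d)t))`, `Req = Rmax·k_aC/(k_aC + k_d)`;
dissociation mono-exponential at `k_d`; `K_D = k_d/k_a`. Mass-transport
limitation, baseline drift and heterogeneous-ligand models are out of
scope (the original analysis reported simple 1:1 fits; assay temperature
is metadata). The global fit shares (k_a, k_d, Rmax) across the
concentration series; the per-concentration `k_obs = k_aC + k_d`
regression is kept as an independent diagnostic, and the two agree to
≈1% at 1% CV noise. A single-concentration series confounds k_a with
Rmax and is flagged.

## Synthetic data: what it does and does not emulate

The generators reproduce: biphasic burst curves whose amplitude is the
active-enzyme concentration and whose slope is `k_pd·A₀`; single-turnover
exponentials; titration series at 3.5/7/10/20 nM enzyme; saturating
repair curves with codon-specific half-lives sampled at 0/5/16/24/48 h;
mixing standards at 0/10/30/50/70/90/100%; Ct tables; and mono-exponential
sensorgrams at 0–40 nM analyte. Noise is multiplicative Gaussian (CV)
plus an additive floor, clamped to physical bounds ([0, substrate] for
product, [0, 100] for percentages), with a mandatory seed — identical
parameters and seed give bit-identical output.

Not emulated: sequence-level structure of the oligonucleotide substrates
(sequence context is a label), PCR chemistry beyond the Ct↔fraction map,
transfection efficiency or copy-number normalization, AP-site lability
before transfection, and the direct-reversal (ABH2/ABH3) repair pathway.
A green round-trip test therefore establishes that the *analysis
recovers the stated generating model*, not that the model is the true
data-generating process of the wet-lab assay.

## Fixture catalog provenance

Values printed as single numbers are tagged `printed` (εA `k_pd` 0.24 and
0.11 min⁻¹; Hx 0.25 and 0.26 min⁻¹; activity 22% and 83%; HepG2 `t₁/₂`
3.0 and 16.5 h; HUVEC 4.0 and 5.0 h). Hotspot values printed only as
group ranges are assigned within-range per-codon values tagged
`range-interpolated` (εA 0.02/0.03/0.04; Hx 0.01/0.04/0.08 min⁻¹; HepG2
18.5/19.5/20.5 h; HUVEC 9.1/12.2/15.3 h for codons 249/179/255). Values
never printed are tagged `chosen`: burst `k_obs` = `k_chem` = 1.2 min⁻¹
(turnover recovery is insensitive to it), `K_D` = 10 nM (mid-range for a
0–40 nM SPR series), `k_on` = 10 nM⁻¹min⁻¹ (diffusion-limited scale in
assay units), and the AP-site per-codon half-lives 1.4/1.6 and
1.2/1.3/1.4 h, chosen to reproduce the published group medians (1.5 and
1.3 h).

## Numerical notes

* ODE integration: LSODA, rtol 1e-10 / atol 1e-12; total substrate
  (S + ES + EP + P) is conserved to 1e-9 relative at every output time,
  and integration failure raises an error naming the parameter set.
* The acceptance-style checks in `scripts/acceptance.py` run all
  deterministic quantities noise-free; the only stochastic quantity (the
  mixing-linearity minimum R²) uses a 20-seed panel derived from the
  `--seed` argument.
* Grid-search oracles in the test suite (log-grid plus golden-section
  refinement) are deliberately independent of scipy's optimizers; the
  fitters must always reach an RSS at least as low.

## Known limitations

* The percent-repair formula is a stand-in for an unpublished protocol
  detail (see above).
* Bootstrap SEs are not implemented; linearized SEs only.
* `analyze` mode fits user CSVs but performs no unit inference — inputs
  must be in the package's canonical units (nM/min, %/h, RU/s).
* No global multi-curve mechanistic ODE fitting; closed forms only, as in
  the original analysis. No Michaelis–Menten steady-state analysis.
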