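# mpgkin

Kinetic and quantification analyses for codon-specific DNA base excision
repair: pre-steady-state kinetics of the DNA glycosylase MPG
(N-methylpurine-DNA glycosylase), 1:1 Langmuir SPR binding analysis, and a
real-time-PCR-based in-cell repair assay, together with synthetic-data
generators that emulate each assay from explicit mechanistic parameters.

## The scientific problem

Mutation hotspots in cancer genes such as p53 may arise not only because
some sites acquire more DNA damage, but because some sequence contexts are
repaired more slowly. For the lipid-peroxidation adduct
1,N6-ethenoadenine (εA), excised by MPG to initiate base excision repair,
the question is *which step* of the excision reaction is sequence
sensitive. The minimal mechanism is

```
E + S  <==>  ES  -->  EP  <==>  E + P
      K_D       k_chem     k_pd
```

with `K_D` the equilibrium dissociation constant of substrate binding
(nM), `k_chem` the glycosidic-bond cleavage rate (min⁻¹), and `k_pd` the
product (AP-site) dissociation rate (min⁻¹) — the turnover number. The
assays that separate these steps:

* **Single turnover (STO)**, enzyme ≫ substrate:
  `[P] = A₀(1 − exp(−k_obs t))` with `k_obs ≈ k_chem`.
* **Burst / multiple turnover (MTO)**, substrate ≫ enzyme:
  `[P] = A₀(1 − exp(−k_obs t)) + k_ss t`; the burst amplitude `A₀`
  estimates active enzyme and `k_pd = k_ss / A₀`.
* **Active-site titration**: burst fits at several enzyme concentrations;
  regressing `A₀` on total enzyme through the origin gives the active
  fraction of the preparation.
* **SPR**: 1:1 Langmuir kinetics, `K_D = k_d / k_a`.
* **In-cell repair**: a lesion-bearing plasmid is transfected, recovered
  over time, and the amplifiable fraction measured by qPCR (unrepaired
  lesions are converted to nicked, non-amplifiable template);
  `fraction = E^(Ct_ref − Ct_sample)`. Time courses are summarized by the
  repair half-life `t₁/₂`.

The packaged fixture catalog (`mpgkin.paper_fixtures()`) encodes the
published constants for p53 codons 246/247 (non-hotspots) and 249/179/255
(adenine-mutation hotspots): εA turnover `k_pd` of 0.24 and 0.11 min⁻¹ at
the non-hotspots versus 0.02–0.04 min⁻¹ at hotspots, the 22%/83% active
enzyme preparations, and the HepG2/HUVEC/AP-site half-life tables. Every
value carries a provenance tag (`printed`, `range-interpolated`, or
`chosen`); see `docs/methods.md`.

## Worked example

Generate a noise-free burst curve from the codon-246 εA fixture
(7 nM enzyme, 22% active, 75 nM substrate, 0–10 min) and fit it:

```python
import numpy as np
from mpgkin import paper_fixtures, generate_mto_curve, fit_burst

cat = paper_fixtures()
t = np.arange(0, 10.125, 0.25)
p = cat.mechanism("eA", "246")
A0 = p.active_fraction * 7.0            # burst amplitude = active enzyme
curve = generate_mto_curve(A0, 1.2, p.k_pd * A0, t,
                           enzyme_total=7.0, substrate_total=75.0)
fit = fit_burst(curve)
print(f"A0   = {fit.A0_hat:.3f} nM (active enzyme)")
print(f"kobs = {fit.k_obs_hat:.3f} min^-1 (burst constant)")
print(f"kss  = {fit.k_ss_hat:.4f} nM/min (steady-state slope)")
print(f"kpd  = {fit.k_pd_hat:.3f} min^-1 (= kss/A0, turnover)")
```

prints

```
A0   = 1.540 nM (active enzyme)
kobs = 1.200 min^-1 (burst constant)
kss  = 0.3696 nM/min (steady-state slope)
kpd  = 0.240 min^-1 (= kss/A0, turnover)
```

i.e. the fit recovers the generating constants: 1.54 nM of the 7 nM
preparation is active (22%), and the enzyme turns over at 0.24 min⁻¹ —
each catalytic cycle ends with a slow, ~4-minute wait for the enzyme to
leave its AP-site product.

## Command line

```sh
mpgkin simulate --seed 1 --outdir sim/      # synthetic CSVs for all assays
mpgkin fit-burst sim/progress_curves.csv    # per-codon turnover table
mpgkin titrate sim/progress_curves.csv      # active-site titration
mpgkin repair sim/repair_timecourses.csv    # per-codon half-life table
mpgkin spr sim/sensorgrams.csv              # global 1:1 Langmuir fit
mpgkin report --seed 1 --outdir out/        # full simulate->fit->compare run
mpgkin validate out/report.json             # check against fixture values
```

`mpgkin report` accepts a YAML config (`--config run.yaml`) controlling
mode (simulate/analyze), noise CV, seed, half-life method and stages;
unknown keys are rejected before any computation.

## Acceptance script

`scripts/acceptance.py` regenerates every assay from the fixture catalog
and recomputes the headline quantities end to end — the burst-fit turnover
numbers, titration activity percentages, in-cell half-lives, the
mixing-standard linearity minimum R² over a 20-seed panel, and the AP-site
group median:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
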