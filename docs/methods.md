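# Methods

## The labeling model

The simulator treats the 24-hour ¹³C₆-glucose incubation as an isotopic
steady state: metabolite pool sizes are constant, and each pool's
positional isotopomer distribution equals the flux-weighted mixture of its
production terms.  A distribution over the 2ⁿ labeling patterns of an
n-carbon metabolite is a dense vector indexed by the pattern read as a
binary number, with string position k = carbon Ck in IUPAC numbering.

The network is fixed: pyruvate(3), lactate(3), alanine(3), acetyl-CoA(2),
OAA(4), α-ketoglutarate(5), glutamate(5), succinate(4), fumarate(4),
malate(4), aspartate(4), G-3-P(3), and an external CO₂ pool.  Atom maps:

- glycolysis supplies pyruvate as a two-point mixture — fully labeled
  `111` with probability `tracer_enrichment`, else `000`.  The positional
  glucose→pyruvate map is collapsed because a uniformly labeled hexose
  makes both trioses identical; G-3-P is reported as the same mixture.
- LDH and ALT copy pyruvate to lactate and alanine carbon-for-carbon.
- PDH releases pyruvate C1 as CO₂ and sends C2→acetyl-CoA C1,
  C3→acetyl-CoA C2.
- PC keeps pyruvate C1–C3 as OAA C1–C3 and adds a CO₂-pool carbon as
  OAA C4 (unlabeled by default; `co2_enrichment` is a sensitivity option).
- the condensed citrate-synthase/aconitase/IDH step maps
  α-KG C1←OAA C4, C2←OAA C3, C3←OAA C2, C4←AcCoA C2, C5←AcCoA C1, and
  releases OAA C1 as CO₂.  This is why PDH-only flux labels glutamate as
  `00011`, the dominant labeled glutamate species under default fluxes.
- α-KGDH/SCS maps succinate C1–C4 ← α-KG C2–C5 (C1 lost as CO₂); SDH and
  fumarase pass carbons through unchanged; succinate and fumarate are
  rotationally symmetric and their distributions are replaced by the
  50/50 mixture with the carbon-reversed pattern at every update.
- MDH returns malate to OAA; the malic-enzyme/PEPCK return truncates
  malate C1–C3 back to pyruvate (so `malate 1100 → pyruvate 110`, the
  TCA-derived lactate signature) and releases C4.
- glutamate↔α-KG and aspartate↔OAA exchange carbon-for-carbon; a
  dilution reaction feeds unlabeled carbon into glutamate (standing in
  for glutamine-derived influx).
- a reversible MDH/fumarase backbone exchange (`v_fum_exchange`) lets
  OAA-derived label visit the symmetric fumarate pool and come back
  scrambled (`OAA 1110 ↔ 0111`) without passing the decarboxylating
  steps.  This near-equilibrium exchange is standard biochemistry and is
  the route by which PC-specific carbon reaches `pyruvate 011` and hence
  `lactate 011`; without it the 011 signal would not rise with PC flux.

Condensation of two substrate pools assumes they mix independently — the
standard isotopomer-balance approximation; covariance between pools is
ignored.  The model is a single well-mixed compartment: α-cell, exocrine
and mitochondrial/cytosolic heterogeneity appear only through the
unlabeled-dilution fluxes and the tracer enrichment, not as separate
compartments.

### Flux configuration

`FluxConfig` carries relative fluxes (arbitrary units; only ratios
matter).  Defaults: `v_PDH=0.8`, `v_PC=0.2` (so f_PC = 0.20 of TCA
entry), `v_LDH=0.4`, `v_ALT=0.2`, `v_TCA=0.8`, `v_ME=0.2`,
`v_glu_exchange=2.0` (glutamate is in rapid exchange with α-KG),
`v_glu_dilution=0.5`, `v_asp_exchange=1.0`, `v_fum_exchange=0.5`,
`tracer_enrichment=0.5`.  `v_glycolysis` is balanced so pyruvate
production equals consumption.  Exchange-flux magnitudes are not
observable quantities here; they are documented constants, and the
inference treats the two that matter most for the observed fractions
(tracer enrichment and glutamate dilution) as profiled nuisance
parameters.  `v_ME` is deliberately independent of `v_PC` (the return
path exists even without net anaplerosis), which is also why a PC-free
network still produces a small, quantified `lactate 011` rather than a
structural zero.  Strict molecule-count balance of every pool is not
enforced: at steady state only production-weighted mixing determines
label distributions.

### Solving

The fixed point is found by Gauss-Seidel sweeps in declared metabolite
order, with scrambling applied to the symmetric pools inside the sweep.
Convergence is geometric; every few sweeps the remaining geometric tail
is extrapolated from the residual ratio (clipped to the simplex), which
cuts the sweep count several-fold.  If the residual ever rises, updates
are damped by 0.5.  Defaults: tolerance 1e-10 (1e-8 inside the fitting
loop), max 10,000 iterations; non-convergence raises with the final
residual.  The accelerated solution agrees with plain iteration to
<1e-9.

## GC-MS processing

Totals are ion counts summed over channels divided by the sample's
internal-standard counts.  Natural-abundance correction builds an
(n+1)×(n+1) matrix whose column j is the theoretical channel distribution
of a molecule with exactly j labeled backbone carbons: Binomial(n−j, p13)
shifted by j, with p13 = 0.0107 by default.  When a fragment formula is
supplied, the isotope envelope of the non-backbone atoms (C beyond the
backbone, H, N, O, S, Si — covering TBDMS-derivatized fragments) is
convolved in.  Mass shifts beyond m+n are truncated and columns left
unrenormalized, so columns sum to ≤1.  The measured vector is deconvolved
by nonnegative least squares (never matrix inversion, which produces
negative fractions on noisy data) and renormalized; the fit residual and
the matrix condition number are reported, with a warning above 1e6.
Correctness rests on round-trip tests (convolve-then-correct is the
identity to 1e-8 for n ≤ 6) and Poisson-noise recovery, not on matching
any particular external software.

## NMR multiplet model

Only protonated carbons are observable (lactate/alanine C2–C3, glutamate
C2–C4, aspartate/malate C2–C3), and only one-bond ¹³C-¹³C couplings are
modeled — long-range couplings are unresolved at the acquisition scheme
this targets.  A ¹³C carbon contributes a singlet when both backbone
neighbors are ¹²C, a doublet_low/doublet_high when only the lower-/
higher-numbered neighbor is ¹³C, and a doublet of doublets when both are.
Intensities are linear in isotopomer fractions up to one scale factor per
(sample, metabolite); no position-specific T1/NOE response correction is
applied (a flagged limitation).

Inversion solves `scale · A·x = intensities`, stacked with the corrected
MID when available, under x ≥ 0 and Σx = 1, alternating nonnegative least
squares on x with a closed-form scale update.  Without a MID the scale is
fixed at 1, because the split between the unlabeled pool and an arbitrary
intensity unit is not identifiable.  Every pattern gets an
identifiability flag (its unit vector lies in the design row space);
non-identifiable patterns are reported, never silently resolved — e.g.
with only lactate C3 observed, `001` and `101` are flagged and only their
sum is constrained.  Fractions are reported absolutely (MID-anchored);
conditional-on-labeled fractions are available as a derived view.

## PC-fraction inference

`estimate_pc_fraction` fits the simulator to a long cohort table whose
keys may be isotopomer patterns, MID channels (`m+2`), or multiplet
components (`C2:doublet_low`, in fraction units after dividing by the
fitted scale).  The pipeline fits in **measurement space** (MID channels
plus scale-normalized multiplet intensities) rather than against fitted
isotopomer fractions: for glutamate the pattern-level inversion is
underdetermined, and any representative of the data-equivalence class
would bias a pattern-space fit, while the measurement-space objective is
invariant to that choice.

The objective is the inverse-variance-weighted squared deviation between
predictions and observed means (weights from cross-sample standard errors
when ≥3 samples are available, floored at 5% of the median SE).  f_PC is
scanned on a grid over [0, 0.5] at 0.005 resolution — coarse step 0.05
first, then refinement around the coarse minimum; `exhaustive=True`
evaluates the full grid and is tested to agree — with the nuisances
(tracer enrichment, glutamate dilution) profiled out at every grid point
by warm-started Nelder-Mead.  All other fluxes are held at the template
configuration; in the synthetic studies the template is the generating
profile, so recovery is self-consistent, and in application to real data
the template constants are explicit modeling assumptions.  A flat
objective across the grid raises an identifiability flag.

Confidence intervals: when per-sample replication exists, a bootstrap
over samples re-evaluates the objective against the stored prediction
path along the grid (predictions depend only on the parameters, so no new
simulator solves are needed) and takes percentile bounds of the argmin
distribution (200 resamples, seeded).  Without replication, an F-threshold
profile interval on the objective curve is used, interpolating the
crossing between grid points.

The m+2/m+3 lactate partition and the m+3 G-3-P / m+3 lactate ratio are
reported as labeling proxies, explicitly not flux estimates; undefined
ratios (zero denominators) are flagged rather than dropped.

## Auxiliary statistics

Sample size for a two-sample two-tailed t test is the smallest n whose
power — from the noncentral t with df = 2n−2 and noncentrality d·√(n/2) —
reaches the target; α = 0.05 and power 0.80 are the stated defaults (at
d = 1.5 this gives n = 9, the tracing cohort size).  MR harmonization
aligns outcome effect alleles to the exposure coding, sign-flipping
swapped codings and excluding strand-ambiguous A/T and C/G SNPs by
default (a single-instrument analysis cannot absorb a harmonization
error); the Wald ratio uses the first-order delta SE
`se_out/|β_exp|`, adequate when the instrument is strong.  CTCF is
integrated density minus area × mean background; Hi/Lo classification is
strictly greater-than at 8×10⁴ CTCF units.  Traces are normalized by the
baseline-window mean (frames 0–20 by default) or the trace minimum, with
ratio channels divided first; AUC is the trapezoidal integral of the
normalized trace minus 1 over an inclusive frame window.  Group
comparisons run exactly the named procedure — Welch t, Mann-Whitney,
one-/two-way ANOVA with Sidak-adjusted pairwise Welch tests, or
Kruskal-Wallis with Dunn's rank z tests (Bonferroni-style, Dunn's
classical adjustment) — with a D'Agostino-Pearson normality screen
reported but never used to switch tests.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
steady-state labeling under configurable fluxes; per-sample biological
pool variation (lognormal, σ=0.10) and per-channel multiplicative GC-MS
noise (lognormal, σ=0.05) around internal-standard-scaled ion counts;
additive Gaussian NMR noise at 2% of the maximum component intensity
under an arbitrary per-sample spectrometer scale; a two-component CTCF
mixture per marker; saturating glucose-step biosensor traces with an
inhibitor arm that multiplies the response; and linear instrument-effect
MR summary statistics with randomized allele coding plus one palindromic
SNP.  Noise levels are stated choices — within-group variances for such
MIDs are not published — picked so that recovery holds with margin.

Cohort truths are encoded deliberately: f_PC = 0.20 in both profiles; the
human-like v_LDH and v_ALT are calibrated on the noiseless simulator so
the labeled-lactate output ratio is exactly 6 and the alanine-111 output
ratio exactly 1.2; mouse-like glutamate dilution sets a 3-fold total-pool
ratio; Hi weights are 0.19 (GCG) and 0.74 (INS); the inhibitor multiplies
the trace response by 1.15 (human-like) / 1.12 (mouse-like).  The
mouse-like cohort also runs relatively more of its pyruvate through the
TCA return (v_ME 0.35 vs 0.15) with less LDH flux, which is what makes
its m+3 G-3-P / m+3 lactate ratio structurally higher.  Because the
pipeline is asked to recover exactly these numbers, every end-to-end
check in the test suite is a self-consistency result about the
implementation, not evidence about real islets.

What the generator does **not** emulate: chromatogram peak integration
and retention-time drift, spectral reconstruction artifacts from
non-uniform sampling, cell-type heterogeneity beyond a bulk dilution
term, donor covariates, batch effects, or LD structure between MR
instruments.  Passing tests therefore say nothing about robustness to
those features.

Determinism: all outputs are pure functions of the master seed
(default 20240411); named child streams come from
`SeedSequence(master).spawn` in a fixed order, the seed is written into
every CSV header and the manifest, and regeneration is byte-identical.

## Problem sizes and numerical choices in the test suite

The acceptance-level studies use n = 9 samples per cohort (the power-
calculation size), 150 cells per marker, 12 islets per trace arm, 200
trials for the measurement-module noise studies, 50 replicates per true
f_PC for parameter recovery, 20 master seeds for the end-to-end study
(asserting ≥90% CI coverage per truth at the nominal 95% level), and
5,000 replicates for test calibration.  Degenerate inputs are errors,
never silent: all-zero raw channel vectors, empty multiplet tables, zero
exposure betas, zero baselines, inverted windows, unproduced metabolites,
and non-convergence all raise with context.

## Known limitations

- Steady state only; no kinetic (time-course) label simulation.
- One bulk compartment; no PEP-cycle or mitochondrial/cytosolic split,
  so f_PC is an islet-average quantity.
- The delta-method Wald SE ignores exposure uncertainty (first-order).
- The profile-likelihood fallback CI for f_PC is approximate when
  residuals are correlated; the sample bootstrap is preferred and is the
  default whenever replication exists.
- Absolute fluxes (nmol·islet⁻¹·h⁻¹) are out of scope; everything is
  relative.
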