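# Methods

## The screen model

The pipeline analyzes an arrayed RNAi screen in which each well of a
384-well plate (16 rows A–P × 24 columns) holds one dsRNA amplicon
silencing one host gene in a *Wolbachia*-infected *Drosophila* cell
population, read out in triplicate. Two quantities are measured per well:

- **Wolbachia level** — total bacterial FISH fluorescence divided by the
  number of DAPI-stained nuclei (average bacteria-proportional signal per
  cell);
- **proliferation** — nuclei divided by the number of microscope fields of
  view needed to scan the well (cell density).

Each plate-replicate is normalized independently to robust Z scores,
`z = (x − m) / (1.4826·MAD)` with `m` the median and `MAD` the median
absolute deviation over the plate's *experimental* wells. The 1.4826
constant makes the denominator a consistent estimate of a normal standard
deviation, so thresholds are interpretable on a classical Z scale while
the statistics resist the very outliers the screen is looking for. Control
wells and well A1 are scored against that reference but excluded from it:
controls have designed non-null effects, and A1 carries a systematic
plate-handling artifact (strongly depressed, high-variance scores), so
leaving either in the reference would bias the plate center and spread.
Wells with zero nuclei are a staining/seeding failure; they are emitted
flagged with NaN scores and propagate as missing replicates rather than
fabricated values. Plates with fewer than 8 scorable experimental wells
are skipped with a logged reason; a plate whose experimental wells have
zero MAD raises, naming the plate.

Normalization scale and location invariance means any affine drift in raw
intensity units (gain, exposure) cancels exactly; this is tested as a
property.

## Hit calling

An amplicon is called when at least `min_replicates` (default 2 of 3) of
its replicate scores pass `|z| ≥ z_hit` (default 1.5) **on the same side**.
The same-side requirement is this package's design decision: replicates
crossing the limit in opposite directions are biologically incoherent and
do not reinforce a call; such amplicons are logged. Gene calls take the
majority direction among the gene's hit amplicons (exact ties → no call,
logged) with a confidence bin:

| confidence | rule |
|---|---|
| high   | ≥ 2 amplicons hit concordantly |
| medium | the gene's only library amplicon hit |
| low    | exactly 1 of ≥ 2 library amplicons hit |

The bin rule instantiates the usual reagent-redundancy logic (independent
reagents agreeing is strong evidence; a sole reagent is untestable for
off-target effects; one of several is weak). It is configurable in code.

Proliferation classes use the gene's median proliferation robust-Z across
replicates, then across amplicons, with a strict `|z| > 1` limit (a score
of exactly 1.0 is "none"). Cross-tabulation percentages are reported per
titer-direction row at two significant figures, the precision at which
screen summaries of this kind are printed.

Raising `z_hit` can only shrink the hit set (monotonicity, tested as a
property).

## Amplicon QC

Three exclusions are applied with fixed precedence
outdated > multi-target > positional, so every removed amplicon is counted
under exactly one reason and `n_input = n_retained + Σ removals` holds
exactly. At genome scale (24,036 amplicons: 1,499 zero-target, 1,481
multi-target, 66 in well A1, disjoint) this retains 20,990 screened
amplicons. The expression filter keeps genes with expression strictly
above a configurable threshold (default 0: anything detectable); genes
missing from the expression table are dropped with their own reason. It is
intended for candidate hits after calling, but is generic.

## The synthetic screen and its calibration

Generators are pure functions of (config, seed); all randomness flows
through `numpy.random.default_rng`.

**Manifest.** Amplicons fill experimental wells plate by plate in
row-major order, A1 first. Zero-target and multi-target flags are sampled
among non-A1 amplicons so the three QC categories are disjoint and their
counts additive — the reading under which the genome-scale arithmetic
closes. With `n_amplicons` fixed, category counts are `round(frac·total)`
exactly. The `genome_scale_config()` conditions (24,036 amplicons, 66
plates, 16 control wells per plate → 368 experimental wells, so A1 is
occupied on all 66 plates) reproduce the printed category counts exactly.

**Effects and intensities.** Effects are specified in robust-Z units, the
scale on which every screen result is reported. The key calibration
constraint: plate normalization standardizes whatever bulk spread the
experimental wells have to unit robust scale, so injected effects come
back on their intended scale *only if the simulated bulk has unit spread
in effect space*. Genes without an explicit `effect_map` entry therefore
carry a persistent per-gene background effect ~ N(0, √(1 − noise_sd²));
genes pinned in `effect_map` (including explicit nulls at 0) get exactly
their stated value; replicate noise is N(0, noise_sd) (default 0.3).
Zero-target reagents draw a persistent per-amplicon background effect
(residual off-target activity), and multi-target reagents sum their
targets' effects — both choices keep the plate bulk at unit spread and are
biologically sensible. Observed z maps to raw intensity per cell as
`baseline·exp(s·z)` with `s = 0.02` per z unit: the exponential keeps raw
intensities positive while the small slope keeps the quadratic recovery
bias of the back-transform, ≈ (s/2)·z², below 0.13 even at z = −3.5.
Control wells carry their designed effects (defaults: increase control
+2.2, decrease control −3.5, two neutral controls at 0, four wells each
per plate); the A1 well adds a −4 ± 2 artifact. Proliferation effects
flow through the same mapping into cell counts (default 450 cells per
field of view, 4 fields).

Consequences, verified by the tests: an injected z = +3 gene is recovered
within ±1 in ≥ 95% of replicate measurements (Monte-Carlo over 1000
seeds); the increase control's plate-wise median comes back within ±0.3 of
+2.2 on a 10-plate screen; designated-null genes are essentially never
called (their replicate scores spread only by noise_sd), while background
genes are called at a realistic ~10% rate — those are genuine (simulated)
biology, not false positives, and the recall / false-call recovery
criteria are measured on the explicitly pinned genes.

**Cells, qPCR, translation.** Per-cell counts are 0 with probability
1 − infected_fraction (default 0.14), else uniform within the class range
(1–10 / 11–30 / 31–`count_max`, default 90) chosen by the class mix
(default 0.73/0.135/0.135); the within-class uniform is the minimal
assumption given only class boundaries and frequencies. Cq pairs satisfy
E[Cq_ref − Cq_target] = log_E(true_ratio) with Gaussian technical noise
per replicate. Translation triples (count, level, area) use a latent
bivariate normal: level is linear in one margin, counts are a
floored/discretized transform of the other (≈ 9% of cells at zero, mean
12, SD 9 — a plausible infected-population profile). Because
Cov(X, h(Y)) = ρ·Cov(Y, h(Y)) for bivariate normals, the count transform's
attenuation factor (computed once by deterministic quadrature) is divided
out of the latent correlation, making the sample Pearson r converge to the
requested target exactly in expectation; |target| = 1 is handled as an
exact affine monotone coupling.

## Infection profiling and qPCR

Class bins are inclusive as printed — low 1–10, medium 11–30, high > 30;
0 is always uninfected — and boundary counts (10/11/30/31) are tested
explicitly. Population summaries report class fractions *among infected
cells*; the medium+high fold change between conditions is computed on that
scale and reported to one decimal (half-up rounding, matching how such
percentages are printed).

ΔΔCq quantification uses mean technical-replicate Cq and a default
amplification efficiency of 2.0 (perfect doubling; configurable — no
standard-curve estimation is in scope). The doubling-time formula
`(t2−t1)/(3.32·(log10 n2 − log10 n1))` uses base-10 logs with
3.32 ≈ 1/log10(2); the denominator grouping is the only dimensionally
sensible reading, and exact doubling over 24 h returns 24.01 h (the 0.06%
offset of the rounded constant).

## Enrichment and per-cell statistics

Over-representation is the one-sided hypergeometric upper tail
(scipy's exact survival function; verified against full draw enumeration
for all configurations with N ≤ 12). The background is the screened gene
set; with an expressed-gene list, both the background and set memberships
are restricted before sizing, which is what makes "k of K expressed
members" denominators meaningful. Sets with fewer than 3 expressed members
in the background are skipped with a reason, every input set appears in
the output exactly once, raw p < 0.05 flags enrichment, and BH q-values
are reported alongside without changing the flag.

The Mann–Whitney test enumerates all group assignments of the pooled
sample for combined n ≤ 12 (exact even under ties, with 0.5 credit per
tied pair), summing both tails at the observed U extremity; larger samples
use scipy's tie-corrected normal approximation. The switch point balances
enumeration cost (C(12,6) = 924 assignments) against approximation
quality. Pearson correlation and its t-transform p come from scipy. For
grouped translation comparisons, cells are coarsened to none / low (1–10)
/ medium-high (≥ 11) — a deliberate merge of the two upper infection
classes, which are individually sparse at per-cell sample sizes.

## Problem sizes

The test suite and acceptance script run entirely on generated data at
desk scale: the genome-scale manifest (24,036 amplicons) for QC
arithmetic; 10-plate screens (~2,800 wells × 3 replicates) for control
recovery; 20 single-plate screens with 30+30 injected and 100 pinned-null
genes for recall/false-call rates; 10⁵ cells for mixture recovery; 500
seeds for qPCR and 500–1000 seeds at n = 653 cells for correlation
recovery. These sizes put Monte-Carlo error well inside every stated
tolerance while keeping a full run in seconds.

## Limitations

- The simulator emulates the *statistical* structure of a screen, not its
  physics: no optics, no image segmentation, no spatial row/column
  gradients beyond the A1 artifact, and a log-linear intensity map that is
  a stand-in, not an inference about the instrument.
- Background gene effects are Gaussian; real screens have heavier-tailed
  effect distributions, so real false-call behaviour at the ±1.5 threshold
  may differ from the simulated one.
- Replicate noise is homoscedastic in robust-Z space; no per-plate batch
  effects or edge effects are modelled, so passing recovery tests does not
  certify performance on plates with strong positional structure.
- B-score / median-polish positional correction is deliberately out of
  scope (the analyzed screen applied none beyond A1 exclusion).
- The confidence-bin rule and the same-side replicate requirement are this
  package's declared instantiations of verbal descriptions; both are
  configurable or localized in code.
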