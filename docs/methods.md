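# Methods

This note records the statistical model, the synthetic-screen generator,
the numerical choices, and the known limitations of the pipeline. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Screen design assumed by the model

A dual-promoter cassette expresses two guides (hU6 and sU6 slots) in one
cell. For each gene pair, all guides of one gene (3–5) are crossed with
all guides of the other in a single fixed orientation; every targeting
guide is additionally paired with a non-targeting *Fluc* control under
hU6, with the targeting guide under sU6, to measure its single-gene
effect. Screens run in triplicate with a triplicate Cas9-negative
baseline harvested at day 7; screen samples are taken at days 14 and 28
and sequenced to ~500-fold representation with two forward reads, one per
promoter cassette.

Orientation convention: the gene with the lexicographically smaller
symbol occupies the hU6 slot in enumerated paired constructs. The
screen's assay fixes one orientation but does not determine which gene
goes where; this convention is configurable
(`enumerate_constructs(..., smaller_gene_in_hu6=False)`) and nothing
downstream depends on it.

## Quantification

Read pairs are assigned by exact (optionally 1-mismatch) spacer match at
a fixed offset inside the constant vector context of each read — anchored
matching, not alignment, because the amplicon structure fixes the spacer
position; a pair counts only if the (hU6, sU6) guide combination exists
in the library, otherwise it is tallied as unassigned, so assigned +
unassigned equals the number of input pairs. Reads with a 1-mismatch tie
between two spacers are unassigned. Counts are depth-normalized
(median-ratio by default, as in DESeq size factors; total-count
optionally), and log2 fold changes use a pseudocount of 1 after scaling.
Constructs whose raw baseline count falls below 30 are flagged low-count
and excluded from scoring (but reported). Every screen replicate is
compared against every baseline replicate: 3 × 3 = 9 comparisons.

## Interaction scoring

Per comparison, the Bliss expectation of a paired construct is the sum of
its two guides' single-targeting log2FCs from the same comparison; a
construct is excluded from a comparison when it or either single is
missing or low-count flagged. The (expected, observed) population is
fitted with LOESS — locally weighted polynomial regression, tricube
weights, span 0.75, degree 2, three bisquare robustifying iterations
(canonical local-regression defaults; the method's description names
LOESS without parameters). The fit is evaluated on a quantile grid of up
to 200 points (every point for smaller populations) and interpolated
linearly, with linear extension beyond the fitted range; populations
under 30 points fall back to an ordinary least-squares line with a
warning, and a degenerate design (all expected values equal) is an
error. The residual is observed − fitted.

Variance smoothing: within each comparison, constructs are ranked by
expected log2FC and cut into bins of 200; a final bin shorter than
bin_size/4 is merged into its neighbour (tiny bins have unstable
variances; the bin size itself is arbitrary). Each residual is divided by
its bin's unbiased variance — the literal published procedure — with
`divisor="sd"` offered because dividing by the variance rescales rather
than equalizes spread when bin variances are far from 1 (division by the
standard deviation is the studentization that provably yields unit
per-bin variance, which is what the acceptance check verifies). Bins are
formed per comparison, consistent with the per-comparison LOESS; whether
the original procedure binned per comparison or on the pooled table is
not determinable from its description, and this choice is flagged as an
assumption.

Rationale for dividing residuals rather than modelling variance inside
the fit: the heteroscedasticity is a property of the *residual*
distribution (more lethal expectation → noisier observation), and binned
studentization makes residuals comparable across the expected-log2FC
axis before they are pooled into rank and t statistics.

## Hit calling

Per gene pair, all variance-adjusted residuals across its paired
constructs and the nine comparisons are pooled (up to 25 × 9 = 225 for a
5 × 5 pair; residuals are never averaged before testing). Two tests must
agree:

* **t test** — `t = mean(r) / sqrt(var(r) / (n − 1))` with unbiased
  variance, implemented exactly as printed (the conventional one-sample t
  would divide by n; the printed statistic is smaller by
  `sqrt((n−1)/n)`, i.e. slightly conservative), two-sided p on n − 1
  degrees of freedom. Pairs with n < 3 or zero variance are flagged
  `insufficient_residuals`, not errored. A two-sided p plus an explicit
  mean < 0 requirement is used rather than a one-sided test — the
  conservative, sign-explicit reading of "significantly more lethal".
* **α-RRA** — all residuals pooled and ranked ascending (average ranks on
  ties), normalized ranks u = rank/N; for a pair with k of its n
  residuals in the bottom α = 10%, ρ = min over j ≤ k of
  BetaCDF(u(j); j, n − j + 1); ρ = 1 when k = 0. The permutation null
  reassigns rank sets of size n (10,000 draws per pair size by default,
  p ≥ 1/(n_perm + 1), seeded); residuals within a pair are treated as
  exchangeable with the pool, matching the published RRA construction,
  and per-comparison dependence is deliberately ignored just as the
  method prescribes (see Limitations).

Both p-value families are Bonferroni-corrected over the tested pair
universe and thresholded at 0.1 — the literal reading of the published
"Bonferroni … FDR < 0.1" procedure; Benjamini–Hochberg is exposed as an
option but is not the default. A hit requires both significances, a
negative mean adjusted residual, and no filter. The intersection guards
against two failure modes: pairs driven by a single outlier guide
(caught by the t test) and pairs with a diffuse shift but no strongly
ranked constructs (caught by the RRA).

**Lethal-in-isolation filter.** Genes lethal on their own produce
significant pair residuals for reasons unrelated to genetic interaction
(enhanced activity in the hU6 slot in the original report; additionally,
see Limitations on regression dilution), so any pair containing such a
gene is removed from the hit list with its statistics retained. The
internal caller summarizes each single-targeting construct by its mean
day-14 log2FC across comparisons — one value per guide, the guide-level
ranking unit of MAGeCK-style callers; a guide's nine comparisons share
samples and are not independent evidence — then applies the same α-RRA
machinery grouped by gene, with Benjamini–Hochberg correction across
genes at 0.1 (FDR semantics, mirroring a MAGeCK FDR < 0.1 call). An
external essential-gene list (the analogue of an independent essentiality
screen) is merged with per-gene provenance.

**Competitive-assay residual.** For the two-colour validation assay, each
transduced population's phenotype is its log2 growth relative to the
untransduced population between two timepoints, and the interaction
residual is phenotype(double) − [phenotype(A) + phenotype(B)].

## Synthetic screens

The generator produces the inputs the analysis assumes, with ground truth
recorded for every run. True log2FC of a construct carrying guide i
(efficiency e_i, promoter activity m1) against gene A and guide j against
gene B over t days:

    lfc = ( e_i·m1·f_A + e_j·m2·f_B + e_i·e_j·ε_AB ) · t/28

The interaction scales with e_i·e_j because both genes must actually be
cut for epistasis to manifest. Baseline samples emulate the Cas9-negative
day-7 harvest: no fitness effects. Defaults (units are log2 fold-change
over 28 days unless noted):

| parameter | default | why |
|---|---|---|
| guides per gene | 4 | middle of the 3–5 library design |
| guide efficiency e | U(0.6, 1) | guides differ in disruption efficiency |
| promoter multipliers | hU6 1.0, sU6 0.85 | subtle promoter-strength imbalance |
| gene fitness f | 80%: N(0, 0.15); 20%: N(−2, 0.7) clipped ≤ 0 | libraries include essential/non-essential panels; gives the expected-log2FC axis its multi-log2 spread, without which the population trend is not modellable (genes inside SL pairs always draw from the non-lethal bulk — SL presupposes individually viable genes) |
| SL effect ε | −1.5 (5% of pairs) | a strong, plausibly detectable interaction |
| interaction noise sd | 0.15 + 0.10·\|lfc\| | heteroscedastic by construction: more lethal ⇒ noisier |
| baseline abundance | log-normal, sdlog 0.5 | typical library skew |
| depth | 500 reads/construct/sample | the screen's 500× representation |
| NB inverse-dispersion | 50 (α = 0.02) | replicate-level count scatter of a well-executed screen |
| replicates / timepoints | 3 + 3, days 14 & 28, baseline day 7 | the screening design |

Counts: one log-normal baseline abundance per construct shared by all
samples; screen samples multiply it by 2^(lfc + noise) with noise drawn
per construct per sample; every sample is sequenced to depth ×
n_constructs expected reads (fixed-depth sequencing introduces the
compositional shift that median-ratio normalization handles); counts are
negative-binomial. FASTQ emission writes exactly count read pairs per
construct with the spacers embedded at the fixed offsets, shuffled under
a seed; identical (config, seed) gives byte-identical counts and FASTQ.

What the generator does **not** emulate: PCR jackpotting, recombination
between promoter slots (guide swapping), copy-number-driven cutting
toxicity, off-target effects, and cell-to-cell infection multiplicity.
Passing tests therefore demonstrate correctness of the statistical
machinery on data obeying the model's assumptions, not robustness to
these real-data artefacts.

## Numerical choices

* LOESS local fits solve weighted normal equations on x centred at the
  evaluation point; agreement with an independent local-regression
  implementation is at machine precision for the shared (degree-1)
  configuration.
* Bin variances use ddof = 1; a zero-variance bin is an error naming the
  bin (it indicates a degenerate simulation).
* Permutation p-values are floored at 1/(n_draws + 1); tie ranks are
  averaged; every stochastic stage takes an explicit seed and the
  pipeline records all seeds in provenance sidecars.
* Problem sizes in the test and acceptance runs — 200 gene pairs with 4
  guides/gene (4,800 constructs), 20 null screens, 10 recovery screens,
  10,000 permutations — were chosen so a full calibration study runs in
  minutes on one CPU while keeping ≥ 140 residuals per pair, the same
  order as the 225 of a 5 × 5 pair.

## Limitations

* **Crossed comparisons are not independent.** The nine comparisons
  reuse six physical samples, so a construct's nine log2FCs have
  pairwise correlation ≈ 0.5 and a pair's pooled residuals are
  group-correlated: the effective sample size of a 225-residual pool is
  ≈ 75, overdispersing the null t by ≈ √3. The prescribed tests ignore
  this (by design, following the published construction), so
  pipeline-level null p-values are anti-conservative even though the t
  statistic itself is exactly calibrated on independent residuals (shown
  by Monte-Carlo in the test suite). In practice specificity rests on the
  dual-test intersection, Bonferroni correction, and the
  lethal-in-isolation filter; the acceptance run reports the realized
  null hit count and the false-discovery proportion on screens with
  planted effects rather than asserting a calibration the construction
  does not possess.
* **Regression dilution of the population fit.** The Bliss expectation is
  itself measured with error (it sums two noisy single-guide values), so
  the LOESS trend of observed on expected is attenuated and pairs
  containing genuinely lethal genes inherit systematically negative
  residuals — an analysis-level reason, alongside hU6 slot enhancement,
  why filtering pairs with lethal-in-isolation genes is essential to the
  method's specificity. The filter's power therefore matters: the
  internal day-14 caller catches strong dropout, and supplying an
  external essential list (as the original design does with independent
  screens) is recommended whenever one exists.
* Dividing residuals by the bin *variance* (the literal default) leaves
  residuals on a scale that depends on whether bin variances straddle 1;
  rank- and t-based tests are unaffected within a bin but cross-bin
  comparability is better under `divisor="sd"`.
* Spacer matching is anchored and tolerates at most one mismatch; indels
  or reads from recombined cassettes are unassigned rather than
  rescued.
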