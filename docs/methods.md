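# Methods

This note documents the models behind `srftarget`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Count model and normalization

Gene counts are modeled as negative binomial with Var = μ + αμ²
(α = dispersion). Samples are put on a common scale by invariant-gene
normalization: for sample *s* against a reference *r*, per-gene differences

    d_g = log2(c_gs + ½) − log2(c_gr + ½)

are computed, and genes with |d_g − μ_diff| ≤ σ_diff (population standard
deviation, one pass) form the invariant set; the size factor is
2^mean(d over invariant genes), with the reference pinned at 1. Differences
are taken on the log2 scale because the one-σ band is then symmetric in
fold change and the quasi-normal assumption is plausible; a `linear` scale
is available as a switch. Genes with zero counts in both samples are
excluded (they carry no scale information). If σ_diff = 0 (all differences
identical) every gene is kept.

Total and intronic read columns are separate count universes — intronic
reads are roughly a 20% subset of the library — so differential testing
uses factors computed *within* each read class
(`per_class_size_factors`). Rescaling all counts and the supplied factors
by the same constant leaves every call unchanged.

**Limitation.** Like any invariant-set method, the normalization assumes a
majority of non-changing genes and a roughly two-sided perturbation. A
strongly one-sided response (e.g. >20% of genes induced with nothing
downregulated) drags μ_diff and deflates every estimated fold change by
~0.1 log2 units at those compositions. The stimulation modeled here
induces and downregulates comparable gene numbers, which cancels the bias;
the synthetic power scenario plants both sets symmetrically for the same
reason.

## Induction testing

The two-condition test is a conditional exact NB test: given a gene's total
normalized count K across both conditions, the observed split (S_A, S_B) is
compared against the null in which each condition sum is NB with a common
per-sample mean μ₀ = K/(n_A+n_B) and dispersion α/n per condition sum. The
two-sided p-value sums the probabilities of all splits no more likely than
the observed one, normalized over all splits of K. For K ≤ 30,000 the sum
is exact over the full grid; above that the grid is restricted to the mode
and observed-split neighbourhoods (±12 SD + 50), which the log-concavity of
the split pmf makes exact to floating-point precision.

Dispersion is estimated per gene by method of moments on normalized counts
(pooled within-condition variances), floored at 1e-8. With two replicates
per condition the raw moment estimate collapses to the floor for >10% of
genes even when the true dispersion is 0.02, which would make the test
wildly anti-conservative; the estimate used is therefore
max(gene estimate, mean-binned trend of positive estimates) — the
conservative "maximum" sharing rule, with no empirical-Bayes shrinkage. An
explicit `dispersion` argument overrides estimation.

Per read class, a gene is significant when BH-adjusted p ≤ 0.01 (α) with
fold change ≥ 1.10 (`min_change = 0.10`, interpreted as a fold-change
ratio, not absolute counts). The combined call uses the `either` rule by
default: one read class suffices, provided the other class does not make a
significant opposite call; `both` (both classes must agree) is available.
A gene present in only one read class is evaluated on that class.

## Dependence partition

Genes induced in the reference background are compared by their paired
log2 inductions x (wild type) and y (knockout), in both read classes.
The systematic relation y = βx is fit through the origin by least absolute
deviations (the weighted median of y/x with weights |x| — robust to the
independent-gene cloud at y ≈ x). Iteration: initialize the dependent set
as genes with y < x in both classes; refit β on the pooled dependent
points; reassign a gene to dependent iff |y − βx| ≤ τ in both classes and
β < 1 − δ_min; stop at a fixed point or `max_iter` (reassignment is from
the full induced set each round). Spearman r is reported over the final
dependent cloud.

Defaults: τ = 0.75 log2 units, δ_min = 0.2, max_iter = 50. τ was sized to
the measurement noise of the weaker read class: at typical depths the
intronic log2FC standard error is ~0.3, so 0.75 covers ~2.5σ while the
independent cloud sits at residual ≈ (1−β)x ≥ 0.85 for x ≥ 1 and stays
excluded. Genes with x ≤ 0 in either class (no reference induction) are
excluded before fitting: they carry no slope information.

Rescue classification reuses the same machinery on pairs (x = wild-type,
y = rescue-background induction), initialized with genes reaching at least
half their wild-type induction; a gene is *rescued* when it lies within τ
of the fitted rescue relation, provided the fitted rescue slope is at
least `min_slope = 0.5` — a rescue background identical to the knockout
fits an attenuated slope and yields zero rescued genes.

## Peak consensus and coincidence

Pseudo-replicate peak calls are pooled and clustered by ≥1 bp overlap
(single linkage, per chromosome). A cluster is retained when ≥3 distinct
replicates contribute a peak with p < 1e-4 (scores are −log10 p, strict
inequality). The reported interval is the cluster union (conservative for
downstream distance rules) with summit = mean of member summits.
Differential occupancy against a control keeps peaks with fold ≥ 1.5 and
NB-test p ≤ 0.05. An Elk-1 peak is *SRF-associated* when its summit falls
inside an SRF interval extended ±100 bp (`slop`, matching the motif-window
convention), else *solo*.

## Hi-C interaction calling

Expected counts account for linear genomic distance and sequencing depth:

    expected(i, j) = distance_mean(|i−j|) · c_i · c_j

with coverage factors c_i = (bin total)/(mean bin total) over covered bins
and per-distance means over all covered pairs (zeros included). Distances
above 20 bins are pooled into log2-spaced bands ([21,42), [42,84), …) to
stabilize sparse long-range estimates; bins with zero coverage are masked
everywhere. A pair at distance ≥ 2 bins (self and adjacent bins are
dominated by self-ligation) is significant when the Poisson upper-tail
p ≤ 0.05 *and* Z = (obs − exp)/√exp ≥ 2. Poisson is the natural law for
the product-form expectation; zero-count pairs are never evaluated in
production since an upper-tail p at obs = 0 is 1.

**Limitation.** The expected model does not correct for compartment
structure: same-compartment pairs sit systematically above the
distance-mean and inflate the long-range false-positive rate of the caller.
This is a property of distance+depth background models generally; the
synthetic end-to-end scenario therefore exercises TSS–site linking on a
plaid-free map, and compartment recovery is tested in its own scenario.

## Compartment PCA

Observed/expected for covered bins → Pearson correlation matrix → first
eigenvector v₁. The sign is oriented so the score correlates positively
with a per-bin gene (TSS) density track — A regions are gene-rich. Scores
are scaled by the signal strength:

    score_i = 1000 · (λ₁ / (trace/2)) · √n · v₁ᵢ

i.e. unit loadings map to ±1000 when PC1 explains half of the correlation
variance (a strongly compartmentalized map). A structureless map's λ₁ is
the random-matrix share of the trace, leaving nearly all scores inside the
±100 unassigned band; a quantile-based scale cannot make this distinction
because it renormalizes noise and signal alike. Labels: A above +100, B
below −100, otherwise unassigned.

## Target classification

A gene enters classification with its induction call, dependence label,
TSS set, the retained SRF sites, and its Hi-C links (a TSS bin is linked
to a site-bearing bin iff that pair is a significant interaction; the
partner bin must contain a retained site *summit*). For induced, dependent
genes:

- **Direct**: nearest-site distance ≤ 10 kb *or* linked at any distance;
  Direct genes further split into proximal vs *remote-controlled*
  (distance > 10 kb, qualified by the link).
- **Indirect**: distance > 100 kb and no link.
- **Unassigned**: everything else — notably the 10–100 kb unlinked gap,
  which is reported separately, never merged into either class.

Multi-TSS genes use the TSS minimizing the nearest-site distance and are
linked if any TSS is linked. Distances are measured from the single TSS
base to the nearest interval edge (0 inside). Gene-set enrichment is the
upper-tail hypergeometric test with Bonferroni adjustment over the number
of sets tested (the convention for these figure-style summaries; BH
remains the adjustment for genome-wide DE testing).

## Synthetic data: what it emulates, and what it does not

`SimConfig` defaults define the study conditions: 2,000 genes with
log-uniform baseline means 50–5,000, 400 TPA-induced (log2FC uniform in
[1, 3]), 200 downregulated (mirrored), 60% of induced genes
TCF-dependent with knockout induction attenuated to 0.15× in log2 space,
NB dispersion 0.02, two replicates per condition, per-library size
factors, intronic counts by binomial thinning (0.2) of a latent
transcription draw. Contact maps: 500 bins of 10 kb (a 5-Mb chromosome),
power-law distance decay (exponent 1), optional alternating 20-bin A/B
blocks with plaid factor 1.4, planted loops as multiplicative enrichments,
Poisson sampling. Peak pseudo-replicates: each true peak appears with
probability 0.9 per replicate, jittered ≤ 50 bp, −log10 p uniform in
[4.5, 10]; decoys (30% of the true count) appear in single replicates.

The integrated study scenario (`simulate_study`) places six SRF sites in
three bins near one end of the chromosome (site density mirrors ~1 site
per Mb genome-wide), TPA-induced fraction ~22% so the invariant-gene
majority assumption holds, and splits the dependent genes into
direct-proximal (TSS within 2 kb of a site), direct-remote (TSS > 2 Mb
away with a planted loop), indirect (TSS > 2 Mb away, no loop) and a small
intermediate group (20–90 kb, no loop) that belongs to neither class. The
map is shallow (depth 30) with strong loops (enrichment 80): planted loops
then yield ~5–10 contacts while stray distal pairs expect 0.06–0.15
counts, where the Poisson test's discreteness keeps per-pair false
positives at the percent level — a desk-scale stand-in for the
detectability that deep combined maps give real loops. Compartment plaid
is off in this scenario (see the interaction-calling limitation above);
the compartment scenario uses depth 200 instead.

What the generator does **not** emulate: read-level artifacts (mappability,
GC, duplicates), library-complexity differences between pseudo-replicates,
gene-length effects, correlated gene-gene expression noise,
inter-chromosomal contacts, and TAD-scale structure beyond the plaid
blocks. Recovery results on synthetic data therefore certify the
*inference machinery* under the stated statistical model, not performance
on any particular sequencing run.

Recovery metrics for the end-to-end scenario are computed over genes that
are planted induced-dependent *and* recovered as induced-dependent — the
classification stage's own precision/recall; upstream induction and
partition recovery are measured by their own scenarios, so errors are
attributed to the stage that makes them.

## Numerical choices and degenerate inputs

- All-zero genes: p = 1, log2FC = 0. Fold changes use pseudocount 0.5.
- BH adjustment delegates to statsmodels (`fdr_bh`); hypergeometric tail
  and Poisson tails to scipy.
- LAD slope ties: the weighted median takes the first ratio whose
  cumulative weight reaches half the total.
- Partition non-convergence at `max_iter` returns the last labels with
  `converged=False`; a dependent set shrinking below 2 genes, or a fitted
  β ≥ 1 − δ_min, terminates with zero dependent genes.
- Contact-map entries are canonical (i ≤ j, counts > 0); duplicate or
  transposed input entries accumulate. Chromosome names are matched
  exactly (no "chr" normalization).
- Peak scores of `None` never count toward consensus support.
- Problem sizes in tests and the acceptance script (2,000 genes, 500-bin
  maps, 10 seeds, 500 consensus replicates) are the package's desk-scale
  defaults; they complete in well under a minute each on one core.
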