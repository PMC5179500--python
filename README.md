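# srftarget

Integrated RNA-seq / ChIP-seq / Hi-C classification of TCF-dependent SRF
target genes.

## The problem

Serum response factor (SRF) drives mitogen-induced immediate-early
transcription together with its ERK-regulated ternary complex factor (TCF)
cofactors (Elk-1, Net, SAP-1). Deciding which TPA-inducible genes are
*direct* TCF–SRF targets requires integrating three data modalities:

1. **RNA-seq** in wild-type vs TCF triple-knockout (TKO) fibroblasts, using
   both total and intronic read counts (intronic reads proxy ongoing
   transcription), to find TPA-induced genes and partition them into
   TCF-dependent and -independent sets;
2. **ChIP-seq** pseudo-replicate peak calls to define high-confidence SRF
   and Elk-1 binding sites;
3. **Hi-C** contact maps at 10-kb resolution to link transcription start
   sites (TSSs) to remote binding sites through significant chromatin
   interactions, and to partition chromosomes into A/B activity regions.

`srftarget` implements this pipeline as reusable scikit-learn-style
estimators plus plain set operations, together with a synthetic-data
generator that plants known truth for every stage, so the whole chain is
testable without any sequencing downloads.

## The method in brief

- **Invariant-gene normalization** (`InvariantNormalizer`): for sample *s*
  vs reference *r*, per-gene differences d_g = log2(c_gs + ½) − log2(c_gr + ½);
  genes with |d_g − μ_diff| ≤ σ_diff form the invariant set and the size
  factor is 2^mean(d over invariant genes).
- **Induction testing** (`InductionTester`): per-gene conditional exact NB
  test on the split of the total normalized count between conditions
  (dispersion by method of moments with a conservative trend floor); BH
  adjustment; a gene is *induced* when adj-p ≤ 0.01 and fold change ≥ 1.10
  in at least one read class with no significant opposite call in the other.
- **Dependence partition** (`DependencePartitioner`): iterative least-absolute-
  deviation fit of the through-origin relation y = βx between knockout (y)
  and wild-type (x) log2 induction; genes within the residual band τ in both
  read classes are *dependent* (β must satisfy β < 1 − δ_min). The same
  machinery classifies rescue by cofactor re-expression.
- **Peak consensus** (`consensus`): peaks clustered across pseudo-replicates
  by ≥1 bp overlap; retained when called at p < 1e-4 in ≥3 replicates;
  optional differential-occupancy filter (fold ≥ 1.5, p ≤ 0.05) and SRF/Elk-1
  coincidence labels (summit within partner interval ± 100 bp).
- **Hi-C analysis** (`InteractionCaller`, `CompartmentPCA`): expected
  contacts = distance mean × coverage factors; a pair is significant when
  Poisson upper-tail p ≤ 0.05 and Z = (obs − exp)/√exp ≥ 2; compartments are
  the oriented, variance-weighted PC1 of the O/E correlation matrix with A/B
  labels beyond ±100.
- **Target integration** (`classify`): an induced, dependent gene is
  **Direct** when its TSS is within 10 kb of an SRF site *or* linked to a
  site-bearing bin by a significant interaction at any distance; **Indirect**
  when >100 kb from every site with no link; the 10–100 kb unlinked gap is
  reported as Unassigned. Gene-set enrichment is hypergeometric with
  Bonferroni adjustment.

## Worked example

```python
>>> import srftarget as st
>>> study, result, ev = st.run_synthetic_study(seed=3)
>>> {k: result.report[k] for k in
...  ("n_induced", "n_dependent", "dependent_pct", "n_direct",
...   "n_indirect", "remote_direct_pct")}
{'n_induced': 220, 'n_dependent': 133, 'dependent_pct': 60.45454545454545,
 'n_direct': 64, 'n_indirect': 56, 'remote_direct_pct': 59.375}
>>> round(result.partition.fit_.slope, 3)
0.133
>>> {k: round(ev[k], 3) for k in
...  ("direct_precision", "direct_recall", "indirect_precision", "indirect_recall")}
{'direct_precision': 0.984, 'direct_recall': 1.0,
 'indirect_precision': 1.0, 'indirect_recall': 0.982}
```

The synthetic study plants 220 TPA-induced genes (60% TCF-dependent) on a
5-Mb chromosome with six SRF sites and TSS–site loops; the pipeline calls
220 induced genes, labels 133 dependent (60.5%), and classifies 64 Direct
(59% of them remote-controlled, i.e. qualified only through a Hi-C link) and
56 Indirect targets, recovering the planted architecture with precision and
recall ≥ 0.98. The fitted knockout/wild-type induction slope 0.13 reflects
the planted attenuation of 0.15.

The same chain is scriptable from a shell:

```bash
srftarget simulate --seed 3 --out-prefix sim
srftarget normalize sim.counts.tsv --out factors.tsv
srftarget test-induction sim.counts.tsv --background WT  --out de_wt.tsv
srftarget test-induction sim.counts.tsv --background TKO --out de_ko.tsv
srftarget partition de_wt.tsv de_ko.tsv --out labels.tsv
srftarget consensus sim.peaks.rep*.bed --out peaks.tsv
srftarget hic call sim.contacts.tsv --out interactions.tsv
```

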