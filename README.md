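# regcouple

**What makes a transcription-factor / target-gene pair transcriptionally
coupled?** Genome-wide binding data (e.g. DAP-seq) nominate hundreds of
thousands of TF→target relationships, yet only a small minority of those
pairs show correlated expression across conditions. `regcouple` is an
analysis pipeline that (i) builds TF–target pairs from PWM promoter scans,
(ii) labels them by expression correlation under a resampling-based
"active TF" filter, (iii) assembles a ~130-feature panel of molecular
properties of the TF, the target and the pair, and (iv) identifies which
features — and which feature interactions — separate correlated from
uncorrelated pairs, using univariate statistics and a random forest under
component-disjoint cross-validation. A fully parameterized synthetic-data
generator with a ground-truth manifest stands in for the original data
sources, so every stage is testable end to end.

It is written for computational biologists studying regulatory networks
who want a transparent, reproducible implementation of this analysis
pattern — or a harness to probe when and why it works.

## The method in brief

* **Pairs.** A pair (TF, g) exists when the TF's PWM matches the promoter
  `[−500, −1]` of g with relative log-odds score
  `(s − s_min)/(s_max − s_min) ≥ 0.8`, both strands. The per-pair
  binding-site distance is signed, nearest-edge, negative upstream.
* **Labels.** Expression is quantile-normalized; a TF is *active* when the
  mean pairwise Pearson correlation of its targets exceeds the 97.5th
  percentile of size-matched random non-target sets (≤ 3000 targets,
  subsampled). Pairs of active TFs are `correlated` (r > 0.4),
  `uncorrelated` (−0.1 < r < 0.1) or `excluded` (strict bounds).
* **Features.** Four categories: TFBS information (motif entropy
  `SE = mean_i [−Σ_j p_ij ln p_ij]`, composition, TFBS–TSS distances,
  network position), post-transcriptional/post-translational/PPI (BFS
  distance to Pol-II with sentinels 2000/1000, half-lives, phosphosites,
  miRNA targeting, DNA-binding domains), genomic annotation (isoform
  aggregates, promoter composition, TATAWA box, gene ages, neighbors) and
  epigenetics (DMR/DHS interval overlaps, stable vs dynamic open
  chromatin). Medians impute missing cells; features correlated at
  r > 0.85 merge into clusters.
* **Screen and model.** Wilcoxon–Mann–Whitney + BH FDR + Cohen's D per
  cluster; Fisher enrichment for categorical labels; a 3000-tree random
  forest (mtry 5, terminal nodes ≥ 150) evaluated over 20 repeats of an
  80/20 split in which **no TF or TG identifier is shared** between
  training and test, with majority-class undersampling on training only.
  Importance is permutation MDA; interactions are conditional split
  depths across the forest.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run one coherent study — 60 TFs
(half with genuine activity) against 9000 genes, three auxiliary features
planted with a class shift of 0.8 SD — and write their tables under
`results/`:

```bash
cd analysis
python 01_simulate_inputs.py   # inputs + ground-truth manifest
python 02_build_pairs.py       # PWM scan -> pair set
python 03_label_pairs.py       # correlation, active TFs, labels
python 04_assemble_features.py # 130-feature panel
python 05_univariate_screen.py # clusters + Wilcoxon/Cohen's D screen
python 06_random_forest.py     # component-disjoint CV, MDA, interactions
```

Output at seed 1 (abridged):

```
02: planted-pair recall: 10200/10200 (100.0%)
    background (unplanted) pairs: 3481 (25.4% of the pair set)
03: active TFs: 30/60 (true positives 30, false positives 0)
    mean r of coupled pairs: 0.7030 (model expectation 0.7071)
05: 130 features -> 120 clusters (merged at r > 0.85)
    top clusters by FDR:
      halflife_tg                 D=+0.679  p_fdr=2.9e-86 (planted)
      mirna_max_energy_ratio_tg   D=+0.667  p_fdr=3.0e-85 (planted)
      mirna_target_sites_tg       D=+0.661  p_fdr=3.1e-83 (planted)
      halflife_product            D=+0.508  p_fdr=1.7e-47
      tf_target_count             D=-0.345  p_fdr=6.1e-26
06: median ROC-AUC 0.756 (SD 0.030); median PR-AUC 0.444 (SD 0.063)
    mean cross-pair drop per split: 31.9%
    top features by MDA: mirna_max_energy_ratio_tg, mirna_target_sites_tg,
    halflife_tg (all three planted)
```

Reading this: the scanner recovers every planted binding site; the
activity filter finds exactly the TFs that were simulated as active; the
univariate screen and the forest's permutation importance both rank the
three planted features first (their realized effect size ≈ 0.66–0.68 —
the configured 0.8 attenuated by the coupled share of the gene pool, see
the methods note); and the forest separates correlated from uncorrelated
pairs well above its permuted-label baseline of 0.5 even though no TF or
TG seen in training occurs in the test set. Secondary signals such as
`halflife_product` (derived from a planted feature) and `tf_target_count`
(leaky motifs generate more background pairs, which are mostly
uncorrelated) emerge from the simulation's mechanics rather than from
planted shifts.

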