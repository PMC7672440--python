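# Methods

`regcouple` reimplements, as a tested pipeline over synthetic data, an
analysis that asks which molecular properties distinguish transcription
factor (TF) / target gene (TG) regulatory pairs whose expression is
correlated from pairs whose expression is not. This note documents the
models, the conventions, the synthetic-data generator and the numerical
choices, including the places where the design was genuinely open.

## Pair construction

A regulatory pair is a TF whose binding motif matches the upstream promoter
of a gene. Promoters are the interval −500..−1 bp from the annotated TSS.
Motifs are position weight matrices (PWMs): per-position base probabilities
`p_ij` over A,C,G,T with a background base composition (uniform by default,
configurable per TF). Windows are scored as

    score = Σ_i log2((p_i,base + ε) / bg_base),   ε = 1e−4,

and a window is a hit when its *relative* score — `(score − min) / (max −
min)` over the per-column attainable extremes — is at least 0.8. Ties at
exactly the threshold are kept. Both strands are scanned (binding events
are effectively strandless; a forward-only flag exists). The ε pseudocount
only prevents −∞ on zero cells and is negligible at the 0.8 threshold.

**Distance convention.** The signed TFBS–TSS distance is measured to the
hit boundary nearest the TSS: 0 if the hit covers (or abuts) the TSS,
negative upstream, positive downstream, mirrored for − strand genes so that
"upstream" is always negative in the gene's own orientation. The anchor
(nearest edge rather than hit start or center) was an open choice; nearest
edge matches interval-closest semantics of standard genome arithmetic.
When a pair has several hits, the retained distance is the one with
minimal |d|, ties broken toward upstream. Genes without an annotated 5′UTR
are removed (as TFs and as TGs) before pairing. Per-TF and per-TG distance
statistics use all hits in the wider window −1000..+500; the SD is the
sample SD (ddof = 1), defined as 0 for a single hit.

## Expression, activity, labels

Expression (log scale) is quantile-normalized: each sample column receives
the cross-sample mean of order statistics; tied values get the mean of
their tied order-statistic means. Pair correlation is plain Pearson r over
all samples.

A TF is **active** when the mean all-against-all pairwise correlation of
its TGs exceeds the 97.5th percentile of the same statistic computed on
size-matched random non-TG sets (excluding the TF and its TGs), pooled over
all TFs. TFs with more than 3000 TGs are subsampled to 3000. The numeric
threshold is recomputed from the null in every run — it is a property of
the data set, not a constant (an override flag exists). Whether the
percentile should be pooled across TFs or taken per TF was open; pooled is
the default (`pooled=False` is available). TFs with fewer than two usable
TGs are inactive by default.

Pairs of active TFs are labeled `correlated` (r > 0.4), `uncorrelated`
(−0.1 < r < 0.1) or `excluded`, with strict inequalities at every boundary.

## Feature panel

130 features in four categories are assembled per pair, each tagged with
its provenance (TF, TG or pair level):

* **tfbs_info** — motif length, sequence entropy `SE = mean_i S_i` with
  `S_i = −Σ_j p_ij ln p_ij` (natural log; a bits flag exists), core-motif
  entropy (mean of the five lowest `S_i`; all positions when the motif is
  shorter), per-base percentages, AT/GC and AG/TC ratios (denominator guard
  1e−9); per-TF and per-TG TFBS–TSS distance mean/SD, target and regulator
  counts, the pair's closest-TFBS distance; the TF's position in the TF–TF
  regulatory network as in/(in+out) edge ratio (0 marks top-level TFs, TFs
  without TF–TF edges get 0).
* **post_tx_ptm_ppi** — BFS hop distance from the TF to the polymerase-II
  subunit in the protein–protein interaction graph, with sentinel 2000 for
  TFs absent from the PPI data and 1000 for TFs disconnected from Pol-II;
  PPI degree (distinct partners) and a self-interaction flag; phosphosite
  counts; mRNA half-lives of TF and TG and their product; miRNA target-site
  counts (mRNA and intron), mimicry counts and maximal free-energy ratios
  (consumed as tables — target prediction itself is out of scope); number
  and relative start positions of DNA-binding domains.
* **genomic_annotation** — min/mean/max of mRNA, protein, 5′UTR and 3′UTR
  lengths over isoforms, isoform count, protein-length difference,
  5′UTR-intron flag, upstream-gene distance (for both pair members);
  TG-promoter mono- and dinucleotide composition (sliding window of 2,
  step 1; ambiguity codes excluded from numerator and denominator);
  TATA-box flag (TATAWA, forward strand only, within 60 bp upstream);
  phylostratum ages of TF and TG and their difference age_TG − age_TF;
  adjacent-gene context at 0.5/1/2/5 kb boundary-to-boundary thresholds
  (mean neighbor expression, mean neighbor regulator count, shared-TF
  count).
* **epigenetics** — DMR counts per context/source in promoter, TSS±100 and
  gene body (gene body = [gene_start, gene_end) including introns); stable
  DHS (intersection of all condition tracks) and dynamic DHS (union minus
  intersection) counts in promoter and gene body; per-pair flags for the
  closest TFBS lying in a stable/dynamic DHS; the fraction of configured
  epigenetic mark types with at least one feature in the promoter. The
  denominator of that fraction is configuration-defined (default: the DMR
  context/source layers plus the two DHS classes, i.e. 5 + 2 = 7), since
  no canonical enumeration exists.

Missing values are imputed with per-column medians, separately within the
TF-entity table and the gene-entity table (then once more over assembled
pair-level columns); every imputed cell is flagged. Median imputation
replaces multiple imputation by chained equations deliberately: it is
deterministic and dependency-free, and with ~1–2% missing cells the choice
is immaterial to the downstream screen.

## Statistics

Features are z-scored and merged into clusters wherever pairwise Pearson
r > 0.85. Merging is transitive (connected components): if r(A,B) and
r(B,C) exceed the threshold but r(A,C) does not, all three merge. This
resolves an ambiguity in favor of determinism and column-order
independence. Cluster values are the mean of the z-scored members. At the
default study scale this turns 130 features into ~117 clusters (the
reference analysis went from 135 to 112).

The univariate screen is a two-sided Wilcoxon–Mann–Whitney test per
cluster (exact null for ≤ 50 per class without ties, continuity-corrected
normal approximation otherwise — sidedness was unstated, a one-sided flag
exists), Benjamini–Hochberg FDR across clusters, and Cohen's D with
(n1−1, n2−1)-weighted pooled SD, signed correlated-minus-uncorrelated.

Categorical enrichment (TF families, GO terms) uses pair-based 2×2 tables
— every TF enters once per TG — with a one-tailed Fisher test (the lesser
tail gives the depletion direction) and BH FDR. The odds ratio is the
unconditional sample OR `n11·n22 / (n12·n21)` (which can be exactly 0),
not the conditional MLE.

## Random forest

The classifier separates correlated from uncorrelated pairs with a random
forest: 3000 trees, 5 candidate variables per split (the `mtry` convention;
5 ≈ round(0.5·√112) and `None` applies that rule to the actual cluster
count), minimal terminal node of 150 observations. Cross-validation is
**component-disjoint**: TF and TG identifiers are partitioned 80/20 (an
identifier used in both roles is assigned once), pairs straddling the
partition are dropped and counted; on a complete bipartite pair set the
expected drop is 1 − 0.8² − 0.2² = 32%. Training data are balanced by
undersampling the majority class; **test sets stay imbalanced**, so the
PR-AUC baseline of a random classifier equals the class prevalence.
Degenerate splits (a side missing a class) are redrawn with derived seeds,
up to 50 attempts. The whole procedure repeats 20 times; a permuted-label
arm with identical splits provides the chance baseline.

Importance is permutation MDA: accuracy (0.5 probability cutoff) on the
intact test set minus the mean accuracy over 5 permutations of one feature
column, averaged over repeats (raw, unscaled). Interactions are conditional
depths: for an ordered feature pair (v, w) and each tree in which v splits,
take v's closest-to-root split; if w splits inside that subtree, record w's
minimal depth from the subtree root. Reported per pair: the number of such
trees, the mean conditional depth, and w's unconditional mean minimal root
depth — small conditional depths at high frequency against a larger
unconditional depth indicate interaction. PR-AUC is computed as average
precision; ROC-AUC is the rank statistic (identical to Mann–Whitney
U/(n⁺·n⁻)).

One sklearn-specific caveat matters at desk scale: bootstrap resampling is
weight-based, and the terminal-node minimum counts *unique* in-bag rows
(~63% of the training set). Balanced training sets below ≈ 2·150/0.63 ≈ 480
rows therefore produce trees with no splits at all, and the forest degrades
to chance. `train_forest` warns in this regime; the packaged studies size
their pair sets so training stays well above it.

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes; it
is the study's data source, not a fixture.

* **Genome** — 5 chromosomes, genes with lognormal intergenic gaps (median
  ≈ 1.3 kb, so kilobase-scale neighbors exist), 1–3 isoforms with UTR and
  protein lengths, 2% of genes lacking a 5′UTR (they exercise the filter
  and are never planted on). Each gene gets an independent random sequence
  covering −1000..+500 around its TSS; overlap between neighboring genes'
  sequence records is not modeled.
* **Motifs** — one PWM per TF, lengths 12–18, columns with one consensus
  base at probability p and (1−p)/3 elsewhere, p solved by bisection so the
  per-position entropy hits its target level exactly (defaults 0.05, 0.15,
  0.3 nat, cycled). Low-entropy motifs of this length keep spurious
  promoter hits at the 0.8 threshold to roughly 15–25% of the pair set
  (growing with the gene pool). These background pairs are a feature, not
  a flaw: they create *emergent* class signals — TFs with leakier motifs
  accumulate more (mostly uncorrelated) background pairs, so motif length
  and per-TF target count acquire genuine effect sizes without being
  planted — which is exactly the kind of entanglement the real analysis
  navigates.
* **Pairs** — each TF receives `targets_per_tf` planted targets; the
  consensus is written into the target's promoter at a drawn offset in
  [L−500, −1], avoiding overlap with previously planted sites (overlap
  would clobber them). Every planted pair is therefore recoverable by the
  scanner at relative score 1.0.
* **Expression** — each TF has a latent per-sample activity x ~ N(0,1) and
  its own expression row equals x; a coupled TG is β·x + N(0, σ), so the
  expected pair correlation is β/√(β²+σ²) (0.7071 at the default β = σ =
  1) and coupled TGs of one TF correlate mutually at β²/(β²+σ²) — exactly
  the signal the activity filter detects. All other genes are independent
  N(0,1). Per-gene baselines N(6,1) set a log-like scale. The Gaussian
  latent model is an assumption, recorded as such in the manifest; real
  microarray noise is neither Gaussian nor homoscedastic, so passing tests
  demonstrate method correctness, not robustness to real-data noise.
* **Coupling layout** — the first half of the TFs are designated active; a
  fraction `frac_coupled_pairs` (default 0.15) of each active TF's targets
  is coupled, with coupled TGs unique to their TF. Uncoupled targets are
  drawn from the whole eligible pool *including* other TFs' coupled TGs —
  this keeps regulator counts exchangeable between classes (no accidental
  "regulator count" signal) at the cost of attenuating planted TG-level
  shifts by the coupled share of the pool (≈ 15%: a configured D of 0.8
  realizes ≈ 0.65–0.7 at pair level). The default 0.15 balances the
  reference prevalence (~9% correlated among labeled) against per-TF
  activity detectability at desk scale; the analytic activity signal at
  frac 0.15 and 100 targets is ≈ 0.011 versus a null SD of ≈ 0.001.
* **Auxiliary tables** — half-lives, phosphosites, miRNA tables, ages,
  DBDs drawn from simple unimodal distributions with ~5% missingness.
  Planted shifts displace the generating mean by `shift × SD` for genes on
  the coupled side; TF-level shifts separate pair classes only when
  coupled and uncoupled pairs have disjoint TF sets (frac = 1), so the
  default shifts target TG-level features (halflife, miRNA target sites,
  miRNA energy ratio, each at 0.8). The PPI graph attaches each TF to the
  Pol-II node through a chain of dummy nodes whose length sets the hop
  distance (mean 4); 10% of TFs are absent, 10% disconnected, extra leaf
  edges vary degree without creating shortcuts. DMR tracks are Poisson
  counts per region; DHS condition tracks share "stable" intervals in all
  four conditions and distribute "dynamic" ones over 1–3.
* **Determinism** — every stage derives its generator from
  `(seed, stage_index)`, so identical configurations give byte-identical
  outputs in every format.

## Packaged studies and problem sizes

`regcouple.studies` holds the end-to-end computations the analysis scripts,
the tests and `scripts/acceptance.py` share:

* classifier baselines: uniform scores at n = 50 000 (ROC-AUC 0.50; PR-AUC
  = prevalence, 0.08 at 8% positives) and a permuted-label CV arm on a
  20 000-pair noise matrix (sized so the median over 20 repeats is stable
  to ≈ ±0.01);
* the printed pair-set arithmetic 4340/104369 and 43750/104369 (the counts
  are inputs; the percentages are recomputed);
* activity-filter null calibration: 50 seeds × 200 TFs of uncoupled
  expression, expected active fraction 2.5%;
* analytic correlation recovery at n_sample = 2000;
* the planted-recovery study: 60 TFs, 9000 genes, 170 targets per TF,
  frac 0.25 → ≈ 5000 labeled pairs at ≈ 21% prevalence, forest reduced to
  300 trees (600 in the analysis drivers), 20 repeats. The sizes are set
  so the balanced training set (~1600 rows) supports 150-observation
  terminal nodes (see the caveat above) while a single run stays at
  desk scale.

## Known limitations

* Promoter sequences are independent i.i.d. backgrounds: no composition
  gradients, no shared enhancers, no real TATA frequency.
* The expression model has a single latent factor per TF; combinatorial
  regulation, repression (negative β) and time shifts are not generated.
* Feature shifts are applied post hoc to tables, not mechanistically; the
  acceptance surface is feature *recovery*, not biological mechanism.
* Real-data mode covers the formats (GFF3/FASTA/PWM/TSV expression) for
  pair building and labeling; assembling the full feature panel on real
  data additionally needs the auxiliary tables in the documented schemas.
* The phylostratum generator assigns age labels 1–13; it does not simulate
  sequence evolution.
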