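# Methods

This note documents the statistical model behind `guidescreen`, every
parameter default and its rationale, the scope of the synthetic-data
generator, numerical choices, and known limitations. Nothing here claims an
empirical result that is not computed by the test suite or
`scripts/acceptance.py`.

## 1. Count model and normalization

A screen is an sgRNA × sample matrix of non-negative integer read counts with
one plasmid/T0 reference sample and one or more endpoint samples. Guides carry
one of three control classes: `gene_targeting`, `targeting_control` (cuts a
phenotypically neutral locus), `non_targeting_control` (no genomic match).

Normalization: `value(g, s) = (count(g, s) + c) / median_tc(count(·, s) + c)`
with pseudocount `c = 1` and the median taken over targeting controls only.
The per-sample targeting-control median of the output is therefore exactly 1.
Normalizing to targeting controls rather than to the whole library makes the
generic double-strand-break fitness cost cancel out of every fold change of a
cutting guide — depletion then measures the gene-specific phenotype.

Fold change: `fc(g) = log2(value(g, endpoint) / value(g, plasmid))`;
replicates are averaged per guide. Two sub-library screens over the same
samples are merged by rescaling each input per sample to the median of all
counts of both inputs (round half-up) after checking that gene-targeting guide
ids are disjoint; control guides present in both are kept as separate
`__A`/`__B` suffixed rows.

Replicate agreement is summarized by Pearson and Spearman correlation over
matched guides (≥ 3 guides, error on zero variance).

## 2. Essentiality scoring

Per gene, the Bayes factor is the mean over bootstrap rounds of the summed
per-guide log2 likelihood ratios `log2 f_ess(fc) − log2 f_non(fc)`, where
`f_ess` and `f_non` are Gaussian kernel density estimates trained on guide
fold changes of core-essential and nonessential reference genes. Each round
resamples the reference guides with replacement; reference genes are scored by
leave-fold-out training (a gene never contributes to its own density).
Densities are floored at 1e-12 before the log.

Defaults (`EssentialityConfig`):

| parameter | default | rationale |
| --- | --- | --- |
| `n_bootstrap` | 100 | bootstrap mean stable to ~1% of gene BF spread; 1000-gene screen scores in seconds |
| `n_folds` | 10 | standard leave-out granularity; capped at the per-class reference gene count |
| `kde_bandwidth` | `"silverman"` | scipy's rule-of-thumb; robust on unimodal reference classes |
| `bf_cut` | 6.0 | conventional strong-evidence cutoff on the log2 scale (strict inequality) |
| `fdr` | 0.05 | reference-set FDR budget for the threshold-scan caller |
| `min_pr_auc` | 0.9 | screens separating the reference classes worse than this carry little calling signal; screens at exactly 0.9 are retained |

Calling modes: `bf` returns genes with BF strictly above `bf_cut`; `fdr`
scans unique scores from strict to lenient, estimates FDR at each threshold as
FP/(TP+FP) over reference genes at/above it (thresholds with no reference
genes above count as FDR 0), and returns everything at or above the most
lenient qualifying threshold.

Screen quality: precision-recall AUC for recovering core-essential vs
nonessential reference genes from the BF ranking. Tied scores enter the curve
as one block; the area is a trapezoid over recall starting from (0, 1).

## 3. Distribution metrics

**ECDF-AUC.** Area under a guide subset's empirical CDF over a [0, 1]
x-axis covering all guides. Two x-mappings are provided:

* `domain="rank"` (default): a fold change maps to its mid-rank quantile
  among all guides, i.e. the curve is the subset's ECDF against the all-guide
  ECDF. A random subset scores 0.5 exactly in expectation; strongly depleted
  subsets approach 1.
* `domain="range"`: linear rescaling over the global [min, max].

The rank mapping is the default because the linear mapping is dominated by the
single most extreme count: in deeply sequenced screens the global minimum
fold change is itself produced by a fully depleted guide (a zero count at the
endpoint), which compresses the depleted subset into the left tail of the
linear axis and caps its area at ≈ 0.8 regardless of true effect size. The
rank axis is invariant to that single point; under the default simulation
conditions it scores ≈ 0.94 for truth-essential guides and ≈ 0.46 for
nonessential guides (computed in `scripts/acceptance.py`). The subset ECDF is
integrated exactly as a step function; constant fold changes are an error.

**Skew ratio.** 90th / 10th percentile of one sample's raw counts
(numpy linear-interpolation percentiles), a library-uniformity metric; an
error when the 10th percentile is 0.

## 4. Empirical guide selection

Per retained screen, a guide is *active* when (a) its target gene was called
essential in that screen and (b) its fold change is at or below the
screen-wide 20% quantile (ties inclusive). Activity is tallied across the
screens that used the guide; guides with active fraction ≥ 5% are selected as
`empirical_essential` evidence.

Off-target proxy: each guide's aggregate effect score (per-screen fold-change
ranks scaled to [−1, 1], averaged over screens) is compared with the other
guides of its gene; |z| > 1.25 (sample standard deviation, groups of ≥ 3 with
non-zero spread) flags the guide and removes it.

Sequence filters (any flag removes a candidate): homopolymer runs of ≥ 4 A/T
or ≥ 5 G/C; a BbsI recognition site (GAAGAC / GTCTTC — the cloning enzyme);
GC fraction strictly above 75% or below 20%.

Ranking within a gene: empirically active guides first (by active count, then
active fraction), then the remainder by annotation quality — many overlapping
transcripts, small TSS distance, few off-targets — with the guide sequence as
a final deterministic tie-break. Ranks 1–4 form sub-library A, ranks 5–8
sub-library B. Genes with fewer than 8 surviving candidates are backfilled by
de-novo design (exhaustive NGG-adjacent 20-mers in the longest transcript's
exons, ordered by exon rank, off-target count, sequence); genes that still
cannot fill a sub-library are recorded in a failed-genes report for that
sub-library (so A can target more genes than B) rather than aborting the
design. Both sub-libraries share the same 300 non-targeting + 135 targeting
controls; with `guides_per_sublibrary = 4` a two-gene design has
2×4 + 300 + 135 = 443 entries per sub-library.

Defaults (`SelectionConfig`): `active_quantile 0.20`,
`min_active_fraction 0.05`, `z_cut 1.25`, `guides_per_sublibrary 4`,
`n_nontargeting_controls 300`, `n_targeting_controls 135`,
`min_group_size_for_z 3`, `max_offtargets None` (off).

## 5. Off-target counting and annotation

Off-targets are counted by an exhaustive full-length Hamming scan of every
20-mer window on both genome strands with a mismatch budget of 3
substitutions; one on-target site is subtracted when an exact match exists.
No PAM requirement is imposed (an alignment-style upper bound on near
matches). The scan is vectorized with numpy sliding windows; a per-position
Python oracle verifies it exactly in the tests.

Guide annotation requires a unique exact genomic match. The cut position sits
between protospacer bases 17 and 18 (3 bp from the PAM): `start + 17` on the
plus strand, `start + 3` on the minus strand. `exon_rank` is the 1-based rank
(in transcription order) of the exon containing the cut in the gene's longest
transcript, falling back to the longest transcript that actually overlaps the
cut; `n_transcripts` counts transcripts with an exon overlapping the cut;
`tss_distance` is measured to the longest transcript's TSS. Annotation I/O is
a GFF3 subset (gene/mRNA/exon, 1-based closed converted to 0-based half-open)
plus FASTA via Biopython.

## 6. Cutting classification

A 4-component univariate Gaussian mixture is fitted by EM to the pooled fold
changes of targeting and non-targeting controls. Numerical choices: means
initialized at evenly spaced data quantiles with a small seeded jitter
(1e-3 × data spread), variances floored at 1e-4 throughout (degenerate inputs
converge with equal means instead of collapsing), convergence at an absolute
log-likelihood change < 1e-8, at most 2000 iterations (non-convergence warns
and returns the fit), log-likelihood trace recorded and non-decreasing.
Components are reported in descending-mean order: 1 = non-targeting-like,
2 = targeting-like, 3 = moderate toxicity, 4 = severe toxicity.

Classification: guides of core-essential reference genes are excluded up
front (`excluded_core_essential` — their depletion is expected and carries no
information about cutting). Every other guide maps to the control with the
smallest |fc difference| (ties → lower-fc control) and inherits that
control's posterior: p3+p4 ≥ 0.8 → `target_phenotype`; else p2 ≥ 0.8 →
`likely_cutting`; else p1 ≥ 0.8 → `likely_not_cutting`; else `undetermined`.
The EM is hand-written because the contract (trace, variance floor, seeded
quantile init) is not exposed by library implementations;
`sklearn.mixture.GaussianMixture` serves as an independent cross-check in the
tests. The classifier's recovery guarantee — ≥ 90% correct when component
means are ≥ 3 standard deviations apart — is verified on purpose-built
control mixtures; when the control pool genuinely contains no toxic
subpopulation the 4-component fit is misspecified and posteriors are not
interpretable.

## 7. Coverage analysis

The library is subsampled to k = 2…8 gene-targeting guides per gene (controls
always retained in full), 5 seeded samplings per k; each subsample is
renormalized from raw counts and re-analyzed, and the number of called
essential genes is summarized as mean ± s.e.m. (sample sd / √n) per k for
both callers. Note that under a strong depletion signal recall saturates at
small k and extra calls at low k are noise-driven false positives, so the hit
*count* is not monotone in k; accuracy against the true essential count is.

## 8. Synthetic data generator

Scope: the generator emulates genome-scale negative-selection viability
screens well enough to validate calling, selection and classification logic —
it is not a sequencing-error or cell-population model.

Per guide, endpoint expectation is
`plasmid_abundance × 2^(efficacy × gene_effect + toxic_effect + dsb_effect)`;
counts are negative-binomial via Gamma–Poisson mixing. Defaults
(`SimulationConfig`), chosen once as study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| `n_genes` | 1000 | large enough for stable reference KDEs and FDR scans, seconds to analyze |
| `guides_per_gene` | 4 | one sub-library's multiplicity |
| `essential_fraction` | 0.12 | typical cell-line essential fraction; count is `round(n·f)` exactly |
| `essential_effect` | −3.0 | strong but not saturating log2 depletion at full efficacy |
| `efficacy_dist` | Beta(5, 1.5) | most guides decent, a tail of poor cutters (post-filter library) |
| `toxic_offtarget_rate` | 0.01 | rare gene-independent toxic guides |
| `toxic_effect` | −4.0 | toxic guides deplete regardless of target |
| `nb_dispersion` | 0.05 | moderate overdispersion typical of count data |
| `sequencing_depth` | 500 | reads/guide; realistic coverage |
| `n_replicates` | 2 | standard screen design |
| `n_nontargeting` / `n_targeting` | 300 / 135 | matches the library's control complement |
| `targeting_dsb_effect` | −0.3 | generic cut cost; cancels under targeting-control normalization |
| `screen_essential_fraction` | 1.0 | < 1 makes screens context-dependent (used in the design scenario) |

Ground truth returned with the counts: essential genes, per-guide efficacy,
toxic guides, per-screen active essentials, unique flag-free 20-mer guide
sequences, and reference sets built from sorted halves of the essential /
nonessential genes (omitted when either class has < 10 genes).

Two named scenarios are used by the acceptance artifacts:

* **Default screen-analysis conditions** — the defaults above with
  `seed` varied; used for PR-AUC, FDR recall, ECDF-AUC and effect recovery.
* **Unfiltered-pool design scenario** — 200 genes × 12 guides/gene,
  uniform(0, 1) efficacy, 8 screens, `screen_essential_fraction 0.8`. This
  emulates selecting from a first-generation pool that still contains poor
  cutters, which is the regime where empirical selection has something to
  choose between; high-efficacy guides are then strongly enriched in
  sub-library A relative to low-efficacy guides (quantities in
  `scripts/acceptance.py`).

The genome generator plants single-transcript genes (3 exons × 120 bp,
60 bp introns) in a random sequence, adds an NGG-adjacent candidate guide in
each exon 1, and can copy candidate sites elsewhere with a chosen number of
substitutions to create exact off-target truth at the 3-mismatch budget.

## 9. Determinism

Every stochastic routine takes an explicit seed. The CLI derives per-module
substream seeds as `(seed × 1_000_003 + crc32(name)) mod (2^31 − 1)`, so all
derived seeds fit in 31 bits and identical config + seed produce
byte-identical primary outputs (verified by test and acceptance script).

## 10. Limitations

* The Bayes-factor scorer is a simplified reimplementation of the
  reference-set KDE approach: bootstrap count, bandwidth rule and fold
  assignment are this package's choices; scores agree in ranking, not
  numerically, with other implementations.
* The off-target scanner counts substitution-only near matches without PAM
  context and does not model bulges; it upper-bounds alignment-based counts.
* The effect-score aggregate (rank-scaled mean across screens) is a stand-in
  for cross-study standardized effect sizes when only fold changes are
  available.
* The mixture classifier presumes the control pool actually spans the four
  behavioural modes; with clean controls it degenerates (see §6).
* The generator draws guide efficacy independently of sequence, so sequence
  filters and efficacy are uncorrelated in simulation.
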