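# guidescreen

Empirical sgRNA library design and pooled CRISPR viability-screen analysis.

Genome-scale CRISPR knockout screens measure gene fitness contributions by
tracking the abundance of single-guide RNAs (sgRNAs) in a proliferating cell
population: guides that disrupt an essential gene deplete between the plasmid
pool and the screen endpoint. Two practical problems dominate this field.
First, most guides in first-generation libraries cut poorly or not at all, so
libraries carry 6–10 guides per gene to compensate. Second, calling essential
genes from noisy count data needs careful normalization, reference-calibrated
scoring and screen-level quality control.

`guidescreen` implements an *empirical* answer to the first problem and a
standard, reference-set-based answer to the second:

* **Screen data model** — sgRNA × sample count tables, pseudocount +
  targeting-control median normalization, log2 fold changes, sub-library
  merging, replicate correlation (`guidescreen.screen_data`). Normalizing to
  *targeting* controls (guides that cut a phenotypically neutral locus) rather
  than to the whole library means the generic cost of a double-strand break
  cancels out of every fold change.
* **Essentiality scoring** — a Bayes factor per gene: the log2 likelihood
  ratio that the gene's guide fold changes follow the distribution of
  core-essential reference genes rather than nonessential ones, with
  bootstrapped kernel density estimates and leave-fold-out scoring of the
  reference genes themselves. Hits are called either by a hard Bayes-factor
  cutoff (BF > 6) or at the most lenient threshold keeping the reference-set
  false-discovery rate within 5%. Screens are gated by the precision-recall
  AUC for separating the two reference classes (`guidescreen.essentiality`).
* **Empirical guide selection** — across a collection of quality-gated
  screens, a guide is *active* in a screen when its target gene was called
  essential there and its fold change ranks in the strongest 20% of depletion.
  Guides active in ≥ 5% of their screens are selected on evidence; guides
  whose aggregate effect deviates from their gene's other guides by more than
  1.25 z units are flagged as likely off-target and excluded; sequence filters
  remove homopolymer runs, BbsI sites and extreme-GC guides. Survivors are
  ranked and split into two mutually exclusive sub-libraries A (ranks 1–4) and
  B (ranks 5–8), backfilled by de-novo NGG-site design where the empirical
  pool runs short, plus 300 non-targeting and 135 targeting controls shared by
  both halves (`guidescreen.empirical_selection`).
* **Cutting classification** — a 4-component Gaussian mixture fitted by EM to
  control fold changes; library guides inherit the posterior of their
  nearest control and are classed as target-phenotype / likely cutting /
  likely not cutting / undetermined at an 80% posterior rule
  (`guidescreen.cutting_classifier`).
* **Coverage analysis** — subsample the library to k = 2…8 guides per gene
  and re-run the caller to see how hit detection depends on guide multiplicity
  (`guidescreen.coverage_analysis`).
* **Synthetic data** — a seeded generator for screen collections with full
  ground truth (per-gene essentiality, per-guide efficacy and toxicity,
  negative-binomial counts) and for annotated genomes with planted off-target
  structure, so every pipeline stage can be validated end to end
  (`guidescreen.synthetic_data`).

## Worked example

Simulate a 200-gene screen with two endpoint replicates, analyze it, and
compare the calls against the generator's ground truth:

```python
import guidescreen as gs

cfg = gs.SimulationConfig(n_genes=200, guides_per_gene=4, n_replicates=2, seed=7)
screens, truth = gs.simulate_screen_collection(cfg)
counts = screens[0]

norm = gs.normalize_counts(counts)
fc = gs.mean_fold_change(
    [gs.log2_fold_change(norm, s, "plasmid") for s in ("T14_rep1", "T14_rep2")]
)

ess_cfg = gs.EssentialityConfig(seed=1)
scores = gs.bayes_factor_scores(fc, counts.gene_of, truth.reference_sets, ess_cfg)
pr = gs.precision_recall_auc(scores, truth.reference_sets)
called = gs.call_essentials(scores, truth.reference_sets, "fdr", ess_cfg)

print(f"screen PR-AUC:          {pr:.3f}")
print(f"essential genes called: {len(called)} (truth: {len(truth.essential_genes)})")
recall = len(called & truth.essential_genes) / len(truth.essential_genes)
print(f"recall of truth set:    {recall:.2f}")

ess_guides = {g for g in counts.guides_of_class("gene_targeting")
              if counts.gene_of[g] in truth.essential_genes}
print(f"ECDF-AUC (essential guides): {gs.ecdf_auc(fc, ess_guides):.3f}")
print(f"plasmid skew ratio:          {gs.skew_ratio(counts, 'plasmid'):.2f}")
```

Output:

```
screen PR-AUC:          1.000
essential genes called: 32 (truth: 24)
recall of truth set:    1.00
ECDF-AUC (essential guides): 0.955
plasmid skew ratio:          4.16
```

The reference sets here hold half of the simulated essential genes and an
equal number of nonessentials, so the 32 calls at 5% reference FDR include all
24 truth essentials plus a handful of borderline false positives — the
expected behaviour of an FDR-calibrated caller on a strong-signal screen.

## Command-line interface

Each subcommand takes a flat YAML config, rejects unknown keys (exit code 2),
derives all randomness from a single `seed`, and writes its outputs plus the
resolved config into `out_dir`:

```bash
guidescreen simulate         --config sim.yml        # counts + ground truth
guidescreen qc               --config qc.yml         # PR-AUC gate report
guidescreen analyze          --config analyze.yml    # Bayes factors + calls
guidescreen design           --config design.yml     # sub-libraries A/B
guidescreen classify-cutting --config classify.yml   # mixture classification
guidescreen coverage         --config coverage.yml   # guides-per-gene curve
```

A minimal design run:

```yaml
# design.yml
seed: 17
out_dir: design_run
counts: [run/counts_screen001.tsv, run/counts_screen002.tsv]
refs_essential: run/refs_essential.txt
refs_nonessential: run/refs_nonessential.txt
sequences: run/sequences.tsv
```

Identical config + seed gives byte-identical primary outputs.

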