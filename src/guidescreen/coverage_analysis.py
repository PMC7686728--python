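"""Essential-gene detection power as a function of guides per gene.

The combined library is repeatedly subsampled to k guides per gene (k = 2..8,
five seeded samplings each, controls always retained), each subsample is
renormalized and re-analyzed, and the number of called essential genes is
summarized as mean +/- s.e.m. per k for both calling modes (Bayes-factor
cutoff and reference-set FDR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from guidescreen.essentiality import (
    EssentialityConfig,
    bayes_factor_scores,
    call_essentials,
)
from guidescreen.screen_data import (
    GENE_TARGETING,
    CountMatrix,
    ReferenceSets,
    log2_fold_change,
    mean_fold_change,
    normalize_counts,
)


@dataclass
class CoverageCurve:
    """Rows of (k, caller, mean_hits, sem, n_rep)."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def subsample_guides(counts: CountMatrix, k: int, seed: int) -> CountMatrix:
    """Keep exactly k random guides per gene (controls retained in full)."""
    rng = np.random.default_rng(seed)
    by_gene: dict[str, list[str]] = {}
    keep: list[str] = []
    for g in counts.guide_ids:
        if counts.control_class_of[g] == GENE_TARGETING:
            by_gene.setdefault(counts.gene_of[g], []).append(g)
        else:
            keep.append(g)
    for gene in sorted(by_gene):
        guides = by_gene[gene]
        if len(guides) < k:
            raise ValueError(f"gene {gene} has only {len(guides)} guides, need {k}")
        chosen = rng.choice(len(guides), size=k, replace=False)
        keep.extend(guides[i] for i in sorted(chosen))
    return counts.subset(keep)


def coverage_curve(
    counts: CountMatrix,
    refs: ReferenceSets,
    reference_sample: str,
    treatment_samples: list[str],
    cfg: EssentialityConfig | None = None,
    k_range: range = range(2, 9),
    n_rep: int = 5,
    seed: int = 0,
) -> CoverageCurve:
    """Hit counts vs guides-per-gene for the bf and fdr callers.

    Each (k, replicate) subsample is renormalized from raw counts; replicate
    fold changes over ``reference_sample`` are averaged before scoring.
    ``sem`` is the sample standard deviation over replicates divided by
    sqrt(n_rep).
    """
    cfg = cfg or EssentialityConfig()
    root = np.random.default_rng(seed)
    rows = []
    for k in k_range:
        hits = {"bf": [], "fdr": []}
        for rep in range(n_rep):
            sub_seed = int(root.integers(0, 2**31 - 1))
            sub = subsample_guides(counts, k, seed=sub_seed)
            norm = normalize_counts(sub)
            fcs = [
                log2_fold_change(norm, s, reference_sample) for s in treatment_samples
            ]
            fc = mean_fold_change(fcs) if len(fcs) > 1 else fcs[0]
            rep_cfg = EssentialityConfig(
                fdr=cfg.fdr,
                bf_cut=cfg.bf_cut,
                n_bootstrap=cfg.n_bootstrap,
                n_folds=cfg.n_folds,
                min_pr_auc=cfg.min_pr_auc,
                seed=sub_seed,
            )
            scores = bayes_factor_scores(fc, sub.gene_of, refs, rep_cfg)
            hits["bf"].append(len(call_essentials(scores, refs, "bf", rep_cfg)))
            hits["fdr"].append(len(call_essentials(scores, refs, "fdr", rep_cfg)))
        for caller in ("bf", "fdr"):
            vals = np.array(hits[caller], dtype=float)
            sem = float(vals.std(ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else 0.0
            rows.append((k, caller, float(vals.mean()), sem, n_rep))
    return CoverageCurve(
        table=pd.DataFrame(rows, columns=["k", "caller", "mean_hits", "sem", "n_rep"])
    )
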