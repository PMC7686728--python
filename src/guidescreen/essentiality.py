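"""Reference-set essentiality scoring and screen quality metrics.

Gene essentiality is scored with a Bayes factor: the log2 likelihood ratio
that a gene's guide depletion phenotypes were drawn from the fold-change
distribution of core-essential reference genes rather than that of
nonessential reference genes. Both densities are estimated per screen by
Gaussian kernel density estimation over bootstrap resamples of the reference
guides; reference genes themselves are scored with leave-fold-out training so
no gene contributes to its own density. Calling modes mirror common practice:
a hard Bayes-factor cutoff (BF > 6) or the most lenient score threshold whose
reference-set false-discovery rate stays within a budget (default 5%).

Screen quality is summarized by the area under the precision-recall curve for
separating the two reference classes; screens below 0.9 are discarded before
any cross-screen aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from guidescreen.screen_data import FoldChangeTable, CountMatrix, ReferenceSets

_DENSITY_FLOOR = 1e-12


@dataclass
class EssentialityConfig:
    """Tuning knobs for scoring and calling.

    fdr : reference-set FDR budget for ``call_essentials(mode="fdr")``.
    bf_cut : Bayes-factor cutoff for ``mode="bf"`` (strict inequality).
    n_bootstrap : bootstrap rounds for density estimation.
    n_folds : leave-out folds for scoring reference genes.
    min_pr_auc : screens with PR-AUC strictly below this are excluded.
    seed : RNG seed for the bootstrap.
    """

    fdr: float = 0.05
    bf_cut: float = 6.0
    n_bootstrap: int = 100
    n_folds: int = 10
    kde_bandwidth: str = "silverman"
    min_pr_auc: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")


@dataclass
class GeneScoreTable:
    """Per-gene Bayes factors (log2 units) and guide counts."""

    table: pd.DataFrame  # index gene, columns bayes_factor, n_guides

    def __post_init__(self) -> None:
        if not np.isfinite(self.table["bayes_factor"].to_numpy()).all():
            raise ValueError("Bayes factors must be finite")
        if (self.table["n_guides"].to_numpy() < 1).any():
            raise ValueError("every gene needs at least one guide")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def bf(self, gene: str) -> float:
        return float(self.table.at[gene, "bayes_factor"])

    def to_tsv(self, path) -> None:
        out = self.table.reset_index().rename(columns={"index": "gene", "bayes_factor": "bf"})
        out.to_csv(path, sep="\t", index=False)


@dataclass
class ScreenQC:
    """Quality verdict for one screen."""

    screen: str
    pr_auc: float
    retained: bool = field(init=False)
    min_pr_auc: float = 0.9

    def __post_init__(self) -> None:
        self.retained = self.pr_auc >= self.min_pr_auc


def _log2_density_ratio(
    values: np.ndarray, ess_train: np.ndarray, non_train: np.ndarray, bw: str
) -> np.ndarray:
    kde_ess = gaussian_kde(ess_train, bw_method=bw)
    kde_non = gaussian_kde(non_train, bw_method=bw)
    f_ess = np.maximum(kde_ess(values), _DENSITY_FLOOR)
    f_non = np.maximum(kde_non(values), _DENSITY_FLOOR)
    return np.log2(f_ess) - np.log2(f_non)


def bayes_factor_scores(
    fc: FoldChangeTable,
    gene_of: dict[str, str],
    refs: ReferenceSets,
    cfg: EssentialityConfig | None = None,
) -> GeneScoreTable:
    """Bootstrapped KDE log-likelihood-ratio Bayes factors per gene.

    For every bootstrap round, guide fold changes of the core-essential and
    nonessential reference genes are resampled (with replacement) to train the
    two class densities. Non-reference guides are scored against densities
    trained on the full resample; guides of reference genes are scored with
    the density pair trained on the folds that exclude their own gene. A
    gene's Bayes factor is the mean over rounds of the summed per-guide log2
    likelihood ratios. Deterministic given ``cfg.seed``.
    """
    cfg = cfg or EssentialityConfig()
    ids = sorted(fc.guide_ids)  # guide row order must not matter
    genes = np.array([gene_of[g] for g in ids])
    vals = fc.fc.loc[ids].to_numpy()

    ess_mask = np.isin(genes, sorted(refs.core_essential))
    non_mask = np.isin(genes, sorted(refs.nonessential))
    if ess_mask.sum() < 10 or non_mask.sum() < 10:
        raise ValueError(
            "need >= 10 reference guides per class "
            f"(got {int(ess_mask.sum())} essential, {int(non_mask.sum())} nonessential)"
        )

    ess_genes = sorted(set(genes[ess_mask]))
    non_genes = sorted(set(genes[non_mask]))
    ref_genes = ess_genes + non_genes
    rng = np.random.default_rng(cfg.seed)

    n_folds = min(cfg.n_folds, len(ess_genes), len(non_genes))
    guide_sum = np.zeros(len(ids))
    for _ in range(cfg.n_bootstrap):
        # stratified fold assignment so both classes appear in every training set
        fold_of: dict[str, int] = {}
        for class_genes in (ess_genes, non_genes):
            perm = rng.permutation(class_genes)
            for i, g in enumerate(perm):
                fold_of[g] = i % n_folds
        boot_ess = rng.choice(vals[ess_mask], size=int(ess_mask.sum()), replace=True)
        boot_non = rng.choice(vals[non_mask], size=int(non_mask.sum()), replace=True)
        nonref_mask = ~(ess_mask | non_mask)
        round_scores = np.zeros(len(ids))
        if nonref_mask.any():
            round_scores[nonref_mask] = _log2_density_ratio(
                vals[nonref_mask], boot_ess, boot_non, cfg.kde_bandwidth
            )
        gene_folds = np.array([fold_of.get(g, -1) for g in genes])
        for k in range(n_folds):
            hold = gene_folds == k
            if not hold.any():
                continue
            train_ess_mask = ess_mask & ~hold
            train_non_mask = non_mask & ~hold
            t_ess = rng.choice(vals[train_ess_mask], size=int(train_ess_mask.sum()), replace=True)
            t_non = rng.choice(vals[train_non_mask], size=int(train_non_mask.sum()), replace=True)
            round_scores[hold] = _log2_density_ratio(
                vals[hold], t_ess, t_non, cfg.kde_bandwidth
            )
        guide_sum += round_scores
    guide_bf = guide_sum / cfg.n_bootstrap

    df = pd.DataFrame({"gene": genes, "bf": guide_bf})
    agg = df.groupby("gene", sort=True).agg(bayes_factor=("bf", "sum"), n_guides=("bf", "size"))
    return GeneScoreTable(table=agg)


def call_essentials(
    scores: GeneScoreTable,
    refs: ReferenceSets | None,
    mode: str = "fdr",
    cfg: EssentialityConfig | None = None,
) -> set[str]:
    """Call essential genes by Bayes-factor cutoff or reference-set FDR.

    ``mode="bf"``: genes with BF strictly greater than ``cfg.bf_cut``.
    ``mode="fdr"``: scan thresholds from strict to lenient; at each threshold
    the FDR estimate is FP/(TP+FP) over reference genes only (TP =
    core-essential at/above, FP = nonessential at/above); return all genes at
    or above the most lenient threshold with estimated FDR <= ``cfg.fdr``.
    """
    cfg = cfg or EssentialityConfig()
    if len(scores.table) == 0:
        raise ValueError("empty score table")
    if mode == "bf":
        tbl = scores.table
        return set(tbl.index[tbl["bayes_factor"] > cfg.bf_cut])
    if mode != "fdr":
        raise ValueError(f"unknown mode {mode!r}")
    if refs is None:
        raise ValueError("fdr mode requires reference sets")
    tbl = scores.table
    bfs = tbl["bayes_factor"].to_numpy()
    gene_idx = tbl.index.to_numpy()
    is_tp = np.isin(gene_idx, sorted(refs.core_essential))
    is_fp = np.isin(gene_idx, sorted(refs.nonessential))
    if not is_tp.any() or not is_fp.any():
        raise ValueError("fdr mode requires both reference classes in the score table")
    best_threshold = None
    for t in np.unique(bfs)[::-1]:  # descending: strict -> lenient
        above = bfs >= t
        tp = int((above & is_tp).sum())
        fp = int((above & is_fp).sum())
        fdr_here = fp / (tp + fp) if (tp + fp) > 0 else 0.0
        if fdr_here <= cfg.fdr:
            best_threshold = t
    if best_threshold is None:
        return set()
    return set(gene_idx[bfs >= best_threshold])


def precision_recall_auc(scores: GeneScoreTable, refs: ReferenceSets) -> float:
    """PR-AUC for recovering core-essential vs nonessential reference genes.

    Genes are ranked by Bayes factor descending; precision/recall are
    evaluated per tied-score block (all genes of equal score enter together)
    and the area is integrated by trapezoid over recall.
    """
    tbl = scores.table
    gene_idx = tbl.index.to_numpy()
    is_pos = np.isin(gene_idx, sorted(refs.core_essential))
    is_neg = np.isin(gene_idx, sorted(refs.nonessential))
    ref_mask = is_pos | is_neg
    if not is_pos.any() or not is_neg.any():
        raise ValueError("PR curve requires both reference classes")
    bfs = tbl["bayes_factor"].to_numpy()[ref_mask]
    pos = is_pos[ref_mask]
    order = np.argsort(-bfs, kind="stable")
    bfs, pos = bfs[order], pos[order]
    n_pos = int(pos.sum())

    recalls = [0.0]
    precisions = [1.0]
    tp = fp = 0
    i = 0
    while i < len(bfs):
        j = i
        while j < len(bfs) and bfs[j] == bfs[i]:
            j += 1
        tp += int(pos[i:j].sum())
        fp += (j - i) - int(pos[i:j].sum())
        recalls.append(tp / n_pos)
        precisions.append(tp / (tp + fp))
        i = j
    return float(np.trapezoid(precisions, recalls))


def screen_quality_gate(
    qcs: list[ScreenQC], cfg: EssentialityConfig | None = None
) -> list[str]:
    """Screen ids passing the PR-AUC gate (excluded only when strictly below)."""
    cfg = cfg or EssentialityConfig()
    return [qc.screen for qc in qcs if qc.pr_auc >= cfg.min_pr_auc]


def ecdf_auc(fc_all: FoldChangeTable, subset: set[str], domain: str = "rank") -> float:
    """Area under the subset's ECDF over the rescaled global fold-change axis.

    The x-axis maps every fold change into [0, 1] over *all* guides: with
    ``domain="rank"`` (default) a value maps to its mid-rank quantile among
    all guides, so the curve is the subset's ECDF plotted against the
    all-guide ECDF and the area is insensitive to single extreme values;
    ``domain="range"`` rescales linearly over the global [min, max]. The
    subset ECDF is integrated exactly on the step function. Strongly depleted
    subsets sit near the left edge and score close to 1; a subset drawn at
    random from all guides scores about 0.5.
    """
    subset = set(subset)
    if not subset:
        raise ValueError("empty subset")
    all_ids = set(fc_all.guide_ids)
    if not subset <= all_ids:
        raise ValueError("subset contains guides absent from the fold-change table")
    lo = float(fc_all.fc.min())
    hi = float(fc_all.fc.max())
    if hi == lo:
        raise ValueError("constant fold changes: ECDF-AUC undefined (zero range)")
    vals = fc_all.fc.loc[sorted(subset)].to_numpy()
    if domain == "range":
        xs = np.sort((vals - lo) / (hi - lo))
    elif domain == "rank":
        quantiles = (fc_all.fc.rank(method="average") - 0.5) / len(fc_all.fc)
        xs = np.sort(quantiles.loc[sorted(subset)].to_numpy())
    else:
        raise ValueError(f"unknown domain {domain!r}")
    n = len(xs)
    # step-function ECDF integrated exactly: area right of each jump
    grid_x = np.concatenate([[0.0], xs, [1.0]])
    grid_y = np.concatenate([[0.0], np.arange(1, n + 1) / n, [1.0]])
    # ECDF is right-continuous: between jumps the value is the previous level
    area = 0.0
    for i in range(1, len(grid_x)):
        area += (grid_x[i] - grid_x[i - 1]) * grid_y[i - 1]
    # add the final plateau value at x=1 handled above; trapezoid on steps == rectangle rule
    return float(area)


def skew_ratio(counts: CountMatrix, sample: str) -> float:
    """90th over 10th percentile of one sample's counts (uniformity metric)."""
    if sample not in counts.samples:
        raise KeyError(f"unknown sample {sample!r}")
    vals = counts.counts[sample].to_numpy()
    p10, p90 = np.percentile(vals, [10, 90])
    if p10 == 0:
        raise ValueError("undefined skew ratio: 10th percentile is zero")
    return float(p90 / p10)
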