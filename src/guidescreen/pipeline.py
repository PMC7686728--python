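"""End-to-end orchestration of the screen-analysis and design stages.

These helpers wire the per-module operations into the standard runs the CLI
exposes: screen QC, per-screen essentiality analysis, cross-screen guide
selection and sub-library assembly. They operate purely on in-memory objects;
file handling lives in the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from guidescreen.cutting_classifier import fit_control_mixture, classify_guides
from guidescreen.empirical_selection import (
    CONTROL,
    GuideCandidate,
    SelectionConfig,
    aggregate_activity,
    aggregate_effect_scores,
    assemble_library,
    label_active,
    rank_candidates,
)
from guidescreen.essentiality import (
    EssentialityConfig,
    ScreenQC,
    bayes_factor_scores,
    call_essentials,
    precision_recall_auc,
    screen_quality_gate,
)
from guidescreen.guide_annotation import GuideSequence, sequence_flags
from guidescreen.screen_data import (
    GENE_TARGETING,
    NON_TARGETING_CONTROL,
    TARGETING_CONTROL,
    CountMatrix,
    FoldChangeTable,
    ReferenceSets,
    log2_fold_change,
    mean_fold_change,
    normalize_counts,
)


@dataclass
class ScreenAnalysis:
    """Per-screen analysis products."""

    screen: str
    fc: FoldChangeTable  # replicate-averaged fold changes
    replicate_fcs: list[FoldChangeTable]
    scores: "pd.DataFrame | None"
    pr_auc: float
    essentials: set[str]


def analyze_screen(
    counts: CountMatrix,
    refs: ReferenceSets,
    cfg: EssentialityConfig | None = None,
    reference_sample: str = "plasmid",
) -> ScreenAnalysis:
    """Normalize, fold-change, score and call one screen."""
    cfg = cfg or EssentialityConfig()
    norm = normalize_counts(counts)
    treatment = [s for s in counts.samples if s != reference_sample]
    rep_fcs = [log2_fold_change(norm, s, reference_sample) for s in treatment]
    fc = mean_fold_change(rep_fcs) if len(rep_fcs) > 1 else rep_fcs[0]
    scores = bayes_factor_scores(fc, counts.gene_of, refs, cfg)
    pr = precision_recall_auc(scores, refs)
    essentials = call_essentials(scores, refs, "fdr", cfg)
    return ScreenAnalysis(
        screen=str(counts.meta.get("screen", "screen")),
        fc=fc,
        replicate_fcs=rep_fcs,
        scores=scores.table,
        pr_auc=pr,
        essentials=essentials,
    )


@dataclass
class SelectionRun:
    """Products of a cross-screen selection run."""

    analyses: list[ScreenAnalysis]
    retained: list[str]
    activity: "pd.DataFrame"
    design: object
    qc_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_selection(
    screens: list[CountMatrix],
    refs: ReferenceSets,
    guide_sequences: dict[str, str],
    sel_cfg: SelectionConfig | None = None,
    ess_cfg: EssentialityConfig | None = None,
    de_novo_provider=None,
) -> SelectionRun:
    """Full empirical selection over a screen collection.

    Every screen is analyzed and quality-gated; guide activity is tallied
    across retained screens; per-gene effect z outliers are flagged; ranked
    candidates are assembled into sub-libraries with shared controls drawn
    from the screens' own control guides.
    """
    sel_cfg = sel_cfg or SelectionConfig()
    ess_cfg = ess_cfg or EssentialityConfig()
    analyses = [analyze_screen(s, refs, ess_cfg) for s in screens]
    qcs = [
        ScreenQC(screen=a.screen, pr_auc=a.pr_auc, min_pr_auc=ess_cfg.min_pr_auc)
        for a in analyses
    ]
    retained = screen_quality_gate(qcs, ess_cfg)
    retained_set = set(retained)
    kept = [a for a in analyses if a.screen in retained_set]
    if not kept:
        raise ValueError("no screen passed the quality gate")

    per_screen_flags = [label_active(a.fc, a.essentials, sel_cfg) for a in kept]
    effect = aggregate_effect_scores([a.fc for a in kept])
    gene_of = screens[0].gene_of
    activity = aggregate_activity(per_screen_flags, effect, gene_of, sel_cfg)

    flags = {
        gid: sequence_flags(GuideSequence(id=gid, seq=seq))
        for gid, seq in guide_sequences.items()
    }
    by_gene: dict[str, list[GuideSequence]] = {}
    nontargeting_pool: list[GuideCandidate] = []
    targeting_pool: list[GuideCandidate] = []
    ccls = screens[0].control_class_of
    for gid, seq in guide_sequences.items():
        cls = ccls.get(gid, GENE_TARGETING)
        if cls == NON_TARGETING_CONTROL:
            nontargeting_pool.append(
                GuideCandidate(id=gid, seq=seq, gene=gene_of[gid], category=CONTROL)
            )
        elif cls == TARGETING_CONTROL:
            targeting_pool.append(
                GuideCandidate(id=gid, seq=seq, gene=gene_of[gid], category=CONTROL)
            )
        else:
            by_gene.setdefault(gene_of[gid], []).append(GuideSequence(id=gid, seq=seq))
    nontargeting_pool.sort(key=lambda c: c.id)
    targeting_pool.sort(key=lambda c: c.id)

    ranked = {
        gene: rank_candidates(gene, cands, activity, {}, flags, sel_cfg)
        for gene, cands in sorted(by_gene.items())
    }
    design = assemble_library(
        ranked, nontargeting_pool, targeting_pool, sel_cfg, de_novo_provider
    )
    qc_table = pd.DataFrame(
        {
            "screen": [a.screen for a in analyses],
            "pr_auc": [a.pr_auc for a in analyses],
            "retained": [a.screen in retained_set for a in analyses],
        }
    )
    return SelectionRun(
        analyses=analyses,
        retained=retained,
        activity=activity.table,
        design=design,
        qc_table=qc_table,
    )


def classify_screen_cutting(
    counts: CountMatrix,
    core_essential: set[str],
    seed: int = 0,
    threshold: float = 0.80,
    reference_sample: str = "plasmid",
):
    """Fit the control mixture on one screen and classify its library guides."""
    norm = normalize_counts(counts)
    treatment = [s for s in counts.samples if s != reference_sample]
    rep_fcs = [log2_fold_change(norm, s, reference_sample) for s in treatment]
    fc = mean_fold_change(rep_fcs) if len(rep_fcs) > 1 else rep_fcs[0]
    control_ids = [
        g
        for g in counts.guide_ids
        if counts.control_class_of[g] in (TARGETING_CONTROL, NON_TARGETING_CONTROL)
    ]
    control_fcs = fc.fc.loc[control_ids].to_numpy()
    fit = fit_control_mixture(control_fcs, seed=seed)
    classes = classify_guides(fc, fit, control_fcs, core_essential, threshold)
    return fit, classes
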