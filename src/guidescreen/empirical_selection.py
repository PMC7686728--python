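"""Empirical guide selection and sub-library assembly.

The design algorithm mines a collection of quality-gated viability screens for
guides with reproducible on-target activity:

1. per screen, a guide is *active* if its target gene was called essential in
   that screen and its fold change ranks among the strongest 20% of depletion
   phenotypes;
2. activity is aggregated across screens; guides active in at least 5% of the
   screens that used them are selected on empirical-essential evidence;
3. guides whose aggregate effect score deviates from the other guides of the
   same gene by more than 1.25 gene-wise z units are flagged as likely
   off-target and excluded;
4. survivors are ranked (activity first; otherwise isoform coverage, TSS
   proximity, predicted off-target count) and split into two mutually
   exclusive sub-libraries A (ranks 1-4) and B (ranks 5-8), backfilled with
   freshly designed guides where the empirical pool runs short, plus a shared
   set of 300 non-targeting and 135 targeting controls.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from guidescreen.guide_annotation import (
    FilterFlags,
    Genome,
    GuideContext,
    GuideSequence,
    count_offtargets,
    cut_position,
    reverse_complement,
    sequence_flags,
)
from guidescreen.screen_data import FoldChangeTable

EMPIRICAL_ESSENTIAL = "empirical_essential"
EMPIRICAL_NONESSENTIAL = "empirical_nonessential"
DE_NOVO = "de_novo"
CONTROL = "control"


@dataclass
class SelectionConfig:
    active_quantile: float = 0.20
    min_active_fraction: float = 0.05
    z_cut: float = 1.25
    guides_per_sublibrary: int = 4
    n_nontargeting_controls: int = 300
    n_targeting_controls: int = 135
    min_group_size_for_z: int = 3
    max_offtargets: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.active_quantile < 1:
            raise ValueError("active_quantile must lie in (0, 1)")
        if self.z_cut <= 0:
            raise ValueError("z_cut must be positive")


@dataclass(frozen=True)
class GuideCandidate:
    """A guide with sequence and provenance, ready for library assembly."""

    id: str
    seq: str
    gene: str
    category: str


@dataclass
class ActivityTable:
    """Cross-screen activity tallies, effect z-scores and outlier flags."""

    table: pd.DataFrame
    # index guide; columns n_used, n_active, active_fraction,
    #                offtarget_outlier, effect_z

    def eligible(self, min_active_fraction: float) -> set[str]:
        t = self.table
        mask = (t["n_used"] > 0) & (t["active_fraction"] >= min_active_fraction)
        return set(t.index[mask])


@dataclass
class LibraryDesign:
    """Two mutually exclusive sub-libraries plus shared controls."""

    sublibraries: dict[str, dict[str, list[GuideCandidate]]]  # "A"/"B" -> gene -> guides
    controls: list[GuideCandidate]
    guides_per_sublibrary: int = 4
    failed_genes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids_a = {g.id for gs in self.sublibraries["A"].values() for g in gs}
        ids_b = {g.id for gs in self.sublibraries["B"].values() for g in gs}
        if ids_a & ids_b:
            raise ValueError("sub-libraries A and B share gene-targeting guides")
        for lib, genes in self.sublibraries.items():
            seqs = [g.seq for gs in genes.values() for g in gs] + [c.seq for c in self.controls]
            counts = Counter(seqs)
            dupes = {s for s, n in counts.items() if n > 1}
            if dupes:
                raise ValueError(
                    f"duplicate sequence within sub-library {lib}: {sorted(dupes)[:3]}"
                )
            for gene, gs in genes.items():
                if len(gs) != self.guides_per_sublibrary:
                    raise ValueError(
                        f"gene {gene} has {len(gs)} guides in sub-library {lib}, "
                        f"expected {self.guides_per_sublibrary}"
                    )

    def entries(self, lib: str) -> list[GuideCandidate]:
        out = [g for gs in self.sublibraries[lib].values() for g in gs]
        return out + list(self.controls)

    def size(self, lib: str) -> int:
        return len(self.entries(lib))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lib in ("A", "B"):
            for gene in self.sublibraries[lib]:
                for rank, g in enumerate(self.sublibraries[lib][gene], start=1):
                    rows.append((g.id, g.seq, g.gene, lib, g.category, rank))
            for rank, c in enumerate(self.controls, start=1):
                rows.append((c.id, c.seq, c.gene, lib, CONTROL, rank))
        return pd.DataFrame(
            rows, columns=["sgRNA_id", "sequence", "gene", "sublibrary", "category", "rank"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.to_frame().itertuples(index=False):
                fh.write(f">{row.sgRNA_id}|{row.sublibrary}\n{row.sequence}\n")


# ---------------------------------------------------------------------------
# per-screen activity


def label_active(
    fc: FoldChangeTable, essential_genes: set[str], cfg: SelectionConfig | None = None
) -> dict[str, bool]:
    """Mark guides active: essential target gene AND fold change at or below
    the screen-wide ``active_quantile`` quantile (ties inclusive)."""
    cfg = cfg or SelectionConfig()
    if len(fc.guide_ids) == 0:
        raise ValueError("empty fold-change table")
    threshold = float(np.quantile(fc.fc.to_numpy(), cfg.active_quantile))
    return {
        g: (fc.gene_of.get(g) in essential_genes) and (float(fc.fc.loc[g]) <= threshold)
        for g in fc.guide_ids
    }


def aggregate_activity(
    per_screen_flags: list[dict[str, bool]],
    effect_scores: dict[str, float] | None = None,
    gene_of: dict[str, str] | None = None,
    cfg: SelectionConfig | None = None,
) -> ActivityTable:
    """Tally activity over retained screens; optionally attach outlier flags.

    ``per_screen_flags`` must already be restricted to screens passing the
    quality gate. When ``effect_scores`` and ``gene_of`` are given, per-gene
    z-scores and off-target outlier flags are computed as well.
    """
    cfg = cfg or SelectionConfig()
    guides = sorted({g for flags in per_screen_flags for g in flags})
    n_used = {g: 0 for g in guides}
    n_active = {g: 0 for g in guides}
    for flags in per_screen_flags:
        for g, active in flags.items():
            n_used[g] += 1
            if active:
                n_active[g] += 1
    frac = {g: (n_active[g] / n_used[g] if n_used[g] > 0 else 0.0) for g in guides}
    tbl = pd.DataFrame(
        {
            "n_used": pd.Series(n_used),
            "n_active": pd.Series(n_active),
            "active_fraction": pd.Series(frac),
        }
    )
    if effect_scores is not None and gene_of is not None:
        flags_map, z_map = flag_offtarget_outliers(effect_scores, gene_of, cfg)
        tbl["offtarget_outlier"] = pd.Series(flags_map).reindex(tbl.index).fillna(False)
        tbl["effect_z"] = pd.Series(z_map).reindex(tbl.index).fillna(0.0)
    else:
        tbl["offtarget_outlier"] = False
        tbl["effect_z"] = 0.0
    return ActivityTable(table=tbl)


def aggregate_effect_scores(fc_tables: list[FoldChangeTable]) -> dict[str, float]:
    """Stand-in aggregate effect score: per screen, fold changes are rank
    normalized to [-1, 1] (most depleted -> -1); scores are averaged across
    the screens containing the guide."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for fc in fc_tables:
        vals = fc.fc.to_numpy()
        n = len(vals)
        ranks = pd.Series(vals, index=fc.guide_ids).rank(method="average") - 1
        scores = 2 * ranks / (n - 1) - 1 if n > 1 else ranks * 0.0
        for g in fc.guide_ids:
            sums[g] = sums.get(g, 0.0) + float(scores.loc[g])
            counts[g] = counts.get(g, 0) + 1
    return {g: sums[g] / counts[g] for g in sums}


def flag_offtarget_outliers(
    effect_scores: dict[str, float],
    gene_of: dict[str, str],
    cfg: SelectionConfig | None = None,
) -> tuple[dict[str, bool], dict[str, float]]:
    """Per-gene z-scores of aggregate effect; |z| > z_cut flags a guide.

    Uses the sample (n-1) standard deviation; gene groups smaller than
    ``min_group_size_for_z`` or with zero spread are never flagged.
    """
    cfg = cfg or SelectionConfig()
    by_gene: dict[str, list[str]] = {}
    for g in effect_scores:
        by_gene.setdefault(gene_of[g], []).append(g)
    flags: dict[str, bool] = {}
    zs: dict[str, float] = {}
    for gene, guides in by_gene.items():
        vals = np.array([effect_scores[g] for g in guides])
        if len(guides) < cfg.min_group_size_for_z:
            for g in guides:
                flags[g], zs[g] = False, 0.0
            continue
        sd = float(np.std(vals, ddof=1))
        mean = float(np.mean(vals))
        for g, v in zip(guides, vals):
            z = (v - mean) / sd if sd > 0 else 0.0
            zs[g] = z
            flags[g] = sd > 0 and abs(z) > cfg.z_cut
    return flags, zs


# ---------------------------------------------------------------------------
# candidate ranking and de-novo design


def rank_candidates(
    gene: str,
    candidates: list[GuideSequence],
    activity: ActivityTable,
    contexts: dict[str, GuideContext],
    flags: dict[str, FilterFlags],
    cfg: SelectionConfig | None = None,
) -> list[GuideCandidate]:
    """Filter and order one gene's candidate guides.

    Candidates with any sequence flag or an off-target outlier flag are
    dropped. Empirically active guides (active fraction at or above the
    threshold) come first, ordered by activity; the remainder follow, ordered
    by annotation quality (many isoforms, near the TSS, few off-targets).
    Guide sequence is the final deterministic tie-break.
    """
    cfg = cfg or SelectionConfig()
    tbl = activity.table
    eligible = activity.eligible(cfg.min_active_fraction)
    surviving: list[GuideSequence] = []
    for cand in candidates:
        f = flags.get(cand.id)
        if f is not None and f.any_flag:
            continue
        if cand.id in tbl.index and bool(tbl.at[cand.id, "offtarget_outlier"]):
            continue
        ctx = contexts.get(cand.id)
        if cfg.max_offtargets is not None and ctx is not None:
            if ctx.offtarget_count > cfg.max_offtargets:
                continue
        surviving.append(cand)

    active_part = [c for c in surviving if c.id in eligible]
    rest = [c for c in surviving if c.id not in eligible]

    def activity_key(c: GuideSequence):
        return (
            -int(tbl.at[c.id, "n_active"]),
            -float(tbl.at[c.id, "active_fraction"]),
            c.seq,
        )

    def annotation_key(c: GuideSequence):
        ctx = contexts.get(c.id)
        n_tx = ctx.n_transcripts if ctx is not None else 0
        tss = ctx.tss_distance if ctx is not None else math.inf
        ot = ctx.offtarget_count if ctx is not None else math.inf
        return (-n_tx, tss, ot, c.seq)

    active_part.sort(key=activity_key)
    rest.sort(key=annotation_key)
    out = [
        GuideCandidate(id=c.id, seq=c.seq, gene=gene, category=EMPIRICAL_ESSENTIAL)
        for c in active_part
    ]
    out += [
        GuideCandidate(id=c.id, seq=c.seq, gene=gene, category=EMPIRICAL_NONESSENTIAL)
        for c in rest
    ]
    return out


def design_de_novo(
    gene: str, genome: Genome, cfg: SelectionConfig | None = None, max_mm: int = 3
) -> list[GuideCandidate]:
    """Enumerate flag-free NGG-adjacent 20-mers in a gene's coding exons.

    Candidates are ordered by (exon rank ascending, off-target count
    ascending, sequence ascending) and categorized ``de_novo``.
    """
    cfg = cfg or SelectionConfig()
    if gene not in genome.genes:
        raise KeyError(f"gene {gene!r} absent from annotation")
    g = genome.genes[gene]
    chrom_seq = genome.sequences[g.chrom]
    longest = g.longest_transcript()
    found: dict[str, tuple[int, int]] = {}  # seq -> (exon_rank, offtargets)
    for rank, (s, e) in enumerate(longest.exons_in_rank_order(), start=1):
        region = chrom_seq[s:e]
        # plus strand: 20-mer immediately 5' of NGG
        for i in range(len(region) - 22):
            if region[i + 21 : i + 23] == "GG":
                seq = region[i : i + 20]
                if seq not in found:
                    found[seq] = (rank, -1)
        # minus strand: CCN then 20-mer (protospacer on the reverse strand)
        for i in range(len(region) - 22):
            if region[i : i + 2] == "CC":
                seq = reverse_complement(region[i + 3 : i + 23])
                if seq not in found:
                    found[seq] = (rank, -1)
    out: list[tuple[int, int, str]] = []
    for seq, (rank, _) in found.items():
        gs = GuideSequence(id=f"{gene}_dn_{seq[:6]}", seq=seq)
        if sequence_flags(gs).any_flag:
            continue
        ot = count_offtargets(gs, genome, max_mm=max_mm)
        if cfg.max_offtargets is not None and ot > cfg.max_offtargets:
            continue
        out.append((rank, ot, seq))
    out.sort()
    return [
        GuideCandidate(id=f"{gene}_dn{i + 1}", seq=seq, gene=gene, category=DE_NOVO)
        for i, (rank, ot, seq) in enumerate(out)
    ]


# ---------------------------------------------------------------------------
# assembly


def assemble_library(
    ranked: dict[str, list[GuideCandidate]],
    nontargeting_pool: list[GuideCandidate],
    targeting_pool: list[GuideCandidate],
    cfg: SelectionConfig | None = None,
    de_novo_provider=None,
) -> LibraryDesign:
    """Split ranked candidates into sub-libraries A (ranks 1-4) and B (5-8).

    Shortfalls are backfilled from ``de_novo_provider(gene)`` (A before B);
    genes that cannot reach the per-sub-library count are recorded in the
    failed-genes report for that sub-library instead of crashing. The control
    pools must cover the configured counts; the same control guides are
    appended to both sub-libraries.
    """
    cfg = cfg or SelectionConfig()
    k = cfg.guides_per_sublibrary
    if len(nontargeting_pool) < cfg.n_nontargeting_controls:
        raise ValueError("non-targeting control pool too small")
    if len(targeting_pool) < cfg.n_targeting_controls:
        raise ValueError("targeting control pool too small")
    controls = (
        list(nontargeting_pool[: cfg.n_nontargeting_controls])
        + list(targeting_pool[: cfg.n_targeting_controls])
    )

    sub_a: dict[str, list[GuideCandidate]] = {}
    sub_b: dict[str, list[GuideCandidate]] = {}
    failed: dict[str, str] = {}
    for gene in sorted(ranked):
        pool = list(ranked[gene])
        need = 2 * k
        if len(pool) < need and de_novo_provider is not None:
            existing = {c.seq for c in pool}
            for dn in de_novo_provider(gene):
                if dn.seq not in existing:
                    pool.append(dn)
                    existing.add(dn.seq)
                if len(pool) >= need:
                    break
        if len(pool) == 0:
            failed[gene] = "no candidates after backfill"
            continue
        a = pool[:k]
        b = pool[k : 2 * k]
        if len(a) == k:
            sub_a[gene] = a
        else:
            failed[gene] = f"only {len(a)} candidates for sub-library A"
        if len(b) == k:
            sub_b[gene] = b
        elif gene not in failed:
            failed[gene] = f"only {len(b)} candidates for sub-library B"
    return LibraryDesign(
        sublibraries={"A": sub_a, "B": sub_b},
        controls=controls,
        guides_per_sublibrary=k,
        failed_genes=failed,
    )


def provenance_summary(design: LibraryDesign) -> dict[str, dict[str, float]]:
    """Fraction of gene-targeting guides per provenance category, per sub-library."""
    out: dict[str, dict[str, float]] = {}
    for lib, genes in design.sublibraries.items():
        cats: dict[str, int] = {}
        total = 0
        for gs in genes.values():
            for g in gs:
                cats[g.category] = cats.get(g.category, 0) + 1
                total += 1
        if total == 0:
            raise ValueError(f"sub-library {lib} holds no gene-targeting guides")
        out[lib] = {c: n / total for c, n in cats.items()}
    return out
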