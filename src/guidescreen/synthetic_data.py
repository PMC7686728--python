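"""Ground-truth synthetic screens and genomes for end-to-end testing.

The screen generator emulates a collection of genome-scale negative-selection
viability screens: ~12% of genes are essential, each guide carries a latent
efficacy in [0, 1], a small fraction of guides have a toxic gene-independent
(off-target-like) depletion, every cutting guide pays a small double-strand-
break cost, and sequencing counts are negative-binomial around lognormal
plasmid abundances. Essential genes deplete by a configurable log2 effect
(default -3) scaled by guide efficacy. Ground truth (per-gene essentiality,
per-guide efficacy and toxicity, per-screen active essentials) is returned
alongside the counts so downstream calls can be scored exactly.

The genome generator plants genes with exon/transcript structure in a random
sequence and duplicates selected guide sites with 0-4 mismatches to create
known off-target counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from guidescreen.guide_annotation import Gene, Genome, GuideSequence, Transcript
from guidescreen.screen_data import (
    GENE_TARGETING,
    NON_TARGETING_CONTROL,
    NON_TARGETING_LABEL,
    TARGETING_CONTROL,
    TARGETING_CTRL_LABEL,
    CountMatrix,
    ReferenceSets,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic screen collection."""

    n_genes: int = 1000
    guides_per_gene: int = 4
    essential_fraction: float = 0.12
    essential_effect: float = -3.0  # mean log2 depletion at full efficacy
    efficacy_dist: tuple = ("beta", 5.0, 1.5)  # per-guide efficacy in [0, 1]
    toxic_offtarget_rate: float = 0.01
    toxic_effect: float = -4.0
    nb_dispersion: float = 0.05
    sequencing_depth: float = 500.0  # mean reads per guide
    n_screens: int = 1
    n_replicates: int = 2
    n_nontargeting: int = 300
    n_targeting: int = 135
    targeting_dsb_effect: float = -0.3
    screen_essential_fraction: float = 1.0  # context: share of essentials active per screen
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("essential_fraction", "toxic_offtarget_rate", "screen_essential_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")


@dataclass
class TruthTables:
    """Ground truth emitted with each simulated collection."""

    essential_genes: set[str]
    guide_efficacy: dict[str, float]
    toxic_guides: set[str]
    screen_essentials: dict[str, set[str]]  # screen id -> essential genes there
    reference_sets: ReferenceSets | None = None
    guide_sequences: dict[str, str] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        rows = [
            (g, eff, g in self.toxic_guides) for g, eff in self.guide_efficacy.items()
        ]
        pd.DataFrame(rows, columns=["sgRNA", "efficacy", "toxic"]).to_csv(
            path, sep="\t", index=False
        )


def _sample_efficacy(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    kind = dist[0]
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size=size)
    if kind == "constant":
        return np.full(size, float(dist[1]))
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=size)
    raise ValueError(f"unknown efficacy distribution {kind!r}")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via Gamma-Poisson; dispersion 0 degenerates to Poisson."""
    mean = np.maximum(mean, 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_screen_collection(
    cfg: SimulationConfig,
) -> tuple[list[CountMatrix], TruthTables]:
    """Generate a seeded collection of screens with shared library and truth.

    Each screen has one plasmid sample plus ``n_replicates`` endpoint samples;
    endpoint expectation is ``plasmid * 2**(efficacy * gene_effect +
    toxic_effect + dsb_effect)`` for guides that cut. The number of essential
    genes is ``round(n_genes * essential_fraction)`` exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    n_ess = int(round(cfg.n_genes * cfg.essential_fraction))
    essential = set(rng.choice(genes, size=n_ess, replace=False).tolist())

    guide_ids: list[str] = []
    gene_of: dict[str, str] = {}
    cls_of: dict[str, str] = {}
    for gene in genes:
        for j in range(cfg.guides_per_gene):
            gid = f"{gene}_g{j + 1}"
            guide_ids.append(gid)
            gene_of[gid] = gene
            cls_of[gid] = GENE_TARGETING
    for i in range(cfg.n_targeting):
        gid = f"tc_{i + 1:04d}"
        guide_ids.append(gid)
        gene_of[gid] = TARGETING_CTRL_LABEL
        cls_of[gid] = TARGETING_CONTROL
    for i in range(cfg.n_nontargeting):
        gid = f"nt_{i + 1:04d}"
        guide_ids.append(gid)
        gene_of[gid] = NON_TARGETING_LABEL
        cls_of[gid] = NON_TARGETING_CONTROL

    n_guides = len(guide_ids)
    targeting_mask = np.array(
        [cls_of[g] in (GENE_TARGETING, TARGETING_CONTROL) for g in guide_ids]
    )
    gene_targeting_mask = np.array([cls_of[g] == GENE_TARGETING for g in guide_ids])

    efficacy = np.ones(n_guides)
    efficacy[gene_targeting_mask] = _sample_efficacy(
        rng, cfg.efficacy_dist, int(gene_targeting_mask.sum())
    )
    toxic = np.zeros(n_guides, dtype=bool)
    toxic[gene_targeting_mask] = (
        rng.random(int(gene_targeting_mask.sum())) < cfg.toxic_offtarget_rate
    )
    guide_efficacy = {g: float(e) for g, e in zip(guide_ids, efficacy)}
    toxic_guides = {g for g, t in zip(guide_ids, toxic) if t}

    # reference sets: a held-out half of truth essentials / sampled nonessentials
    ess_sorted = sorted(essential)
    non_sorted = sorted(set(genes) - essential)
    n_ref = max(10, min(len(ess_sorted) // 2, len(non_sorted) // 2, 100))
    refs = ReferenceSets(
        core_essential=set(ess_sorted[:n_ref]), nonessential=set(non_sorted[:n_ref])
    ) if len(ess_sorted) >= 10 and len(non_sorted) >= 10 else None

    screens: list[CountMatrix] = []
    screen_essentials: dict[str, set[str]] = {}
    for s in range(cfg.n_screens):
        screen_id = f"screen{s + 1:03d}"
        if cfg.screen_essential_fraction >= 1.0:
            active_ess = set(essential)
        else:
            k = int(round(len(essential) * cfg.screen_essential_fraction))
            active_ess = set(rng.choice(sorted(essential), size=k, replace=False).tolist())
        screen_essentials[screen_id] = active_ess

        abundance = rng.lognormal(mean=0.0, sigma=0.5, size=n_guides)
        abundance /= abundance.mean()
        plasmid_mean = abundance * cfg.sequencing_depth

        log2_effect = np.zeros(n_guides)
        ess_guide = np.array(
            [gene_of[g] in active_ess and cls_of[g] == GENE_TARGETING for g in guide_ids]
        )
        log2_effect[ess_guide] += efficacy[ess_guide] * cfg.essential_effect
        log2_effect[toxic] += cfg.toxic_effect
        log2_effect[targeting_mask] += cfg.targeting_dsb_effect
        endpoint_mean = plasmid_mean * 2.0**log2_effect

        data = {"plasmid": _nb_counts(rng, plasmid_mean, cfg.nb_dispersion)}
        for r in range(cfg.n_replicates):
            data[f"T14_rep{r + 1}"] = _nb_counts(rng, endpoint_mean, cfg.nb_dispersion)
        counts = pd.DataFrame(data, index=guide_ids)
        screens.append(
            CountMatrix(
                guide_ids=list(guide_ids),
                gene_of=dict(gene_of),
                control_class_of=dict(cls_of),
                samples=list(data.keys()),
                counts=counts,
                meta={"screen": screen_id},
            )
        )
    truth = TruthTables(
        essential_genes=essential,
        guide_efficacy=guide_efficacy,
        toxic_guides=toxic_guides,
        screen_essentials=screen_essentials,
        reference_sets=refs,
        guide_sequences=_unique_guide_sequences(rng, guide_ids),
    )
    return screens, truth


def _unique_guide_sequences(
    rng: np.random.Generator, guide_ids: list[str]
) -> dict[str, str]:
    """Unique flag-free 20-mers per guide (library guides passed pre-filters)."""
    from guidescreen.guide_annotation import sequence_flags

    seqs: dict[str, str] = {}
    used: set[str] = set()
    for gid in guide_ids:
        while True:
            s = _random_seq(rng, 20)
            if s in used:
                continue
            if sequence_flags(GuideSequence(id=gid, seq=s)).any_flag:
                continue
            used.add(s)
            seqs[gid] = s
            break
    return seqs


# ---------------------------------------------------------------------------
# genome simulation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate(rng: np.random.Generator, seq: str, n_mm: int) -> str:
    pos = rng.choice(len(seq), size=n_mm, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = str(rng.choice([b for b in "ACGT" if b != out[p]]))
    return "".join(out)


def simulate_genome(
    n_genes: int = 5,
    exons_per_gene: int = 3,
    exon_length: int = 120,
    genome_length: int = 20_000,
    planted_duplications: list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> tuple[Genome, dict[str, int], list[GuideSequence]]:
    """Random genome with planted genes and known off-target structure.

    ``planted_duplications`` lists (guide_index, n_mismatches) pairs: the
    NGG-adjacent site of that candidate guide is copied elsewhere in the
    genome with the requested number of substitutions. Returns the genome
    (with annotation), the truth off-target count per planted guide id (at a
    3-mismatch budget) and the candidate guides.
    """
    rng = np.random.default_rng(seed)
    intron = 60
    gene_span = exons_per_gene * exon_length + (exons_per_gene - 1) * intron
    spacing = 200
    needed = n_genes * (gene_span + spacing) + spacing
    if needed > genome_length:
        raise ValueError(
            f"cannot pack {n_genes} genes of span {gene_span} into {genome_length} bp"
        )
    seq = list(_random_seq(rng, genome_length))
    genes: dict[str, Gene] = {}
    candidates: list[GuideSequence] = []
    cursor = spacing
    for i in range(n_genes):
        gid = f"SG{i + 1:03d}"
        exons: list[tuple[int, int]] = []
        pos = cursor
        for _ in range(exons_per_gene):
            exons.append((pos, pos + exon_length))
            pos += exon_length + intron
        cursor = pos + spacing
        gene = Gene(id=gid, chrom="chrSim", strand="+")
        gene.transcripts[f"{gid}.t1"] = Transcript(id=f"{gid}.t1", strand="+", exons=exons)
        genes[gid] = gene
        # plant an NGG-adjacent candidate site inside exon 1
        s0 = exons[0][0] + 10
        protospacer = _random_seq(rng, 20)
        seq[s0 : s0 + 20] = list(protospacer)
        seq[s0 + 20 : s0 + 23] = list("AGG")
        candidates.append(GuideSequence(id=f"{gid}_cand", seq=protospacer))

    truth_ot: dict[str, int] = {g.id: 0 for g in candidates}
    if planted_duplications:
        free_start = cursor
        for guide_idx, n_mm in planted_duplications:
            guide = candidates[guide_idx]
            dup = _mutate(rng, guide.seq, n_mm) if n_mm > 0 else guide.seq
            if free_start + 25 > genome_length:
                raise ValueError("no room left for planted duplications")
            seq[free_start : free_start + 20] = list(dup)
            free_start += 40
            if n_mm <= 3:
                truth_ot[guide.id] += 1
    genome = Genome(sequences={"chrSim": "".join(seq)}, genes=genes)
    return genome, truth_ot, candidates
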