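"""Activity labeling, outlier flags, ranking, de-novo design and assembly."""

import numpy as np
import pandas as pd
import pytest

from guidescreen.empirical_selection import (
    CONTROL,
    DE_NOVO,
    EMPIRICAL_ESSENTIAL,
    EMPIRICAL_NONESSENTIAL,
    ActivityTable,
    GuideCandidate,
    LibraryDesign,
    SelectionConfig,
    aggregate_activity,
    aggregate_effect_scores,
    assemble_library,
    design_de_novo,
    flag_offtarget_outliers,
    label_active,
    provenance_summary,
    rank_candidates,
)
from guidescreen.guide_annotation import GuideContext, GuideSequence, sequence_flags
from guidescreen.screen_data import FoldChangeTable
from guidescreen.synthetic_data import simulate_genome


def _fc(values: dict[str, float], gene_of: dict[str, str]) -> FoldChangeTable:
    ids = list(values)
    return FoldChangeTable(
        guide_ids=ids,
        fc=pd.Series({g: float(v) for g, v in values.items()}),
        sample="trt",
        reference="ref",
        gene_of=dict(gene_of),
        control_class_of={g: "gene_targeting" for g in ids},
    )


class TestLabelActive:
    def test_quantile_and_gene_condition(self):
        # ten guides, fcs -9..0; 20% quantile of the ten = -7.2
        values = {f"g{i}": float(-9 + i) for i in range(10)}
        gene_of = {f"g{i}": ("E" if i < 5 else "N") for i in range(10)}
        flags = label_active(_fc(values, gene_of), {"E"})
        # active: essential gene AND fc <= -7.2 -> g0 (-9), g1 (-8)
        assert {g for g, a in flags.items() if a} == {"g0", "g1"}
        # without the essential call nothing is active
        none = label_active(_fc(values, gene_of), set())
        assert not any(none.values())

    def test_tie_at_threshold_is_inclusive(self):
        values = {"a": -2.0, "b": -2.0, "c": -2.0, "d": 0.0, "e": 1.0}
        gene_of = {g: "E" for g in values}
        # 20% quantile of (-2,-2,-2,0,1) = -2; all three tied guides are active
        flags = label_active(_fc(values, gene_of), {"E"})
        assert {g for g, a in flags.items() if a} == {"a", "b", "c"}

    def test_empty_table_is_error(self):
        empty = FoldChangeTable(
            guide_ids=[], fc=pd.Series(dtype=float), sample="t", reference="r"
        )
        with pytest.raises(ValueError, match="empty"):
            label_active(empty, {"E"})


class TestAggregateActivity:
    def test_counts_and_fractions(self):
        flags = [
            {"a": True, "b": False},
            {"a": True, "b": False},
            {"a": False},  # b unused in this screen
        ]
        tbl = aggregate_activity(flags).table
        assert tbl.at["a", "n_used"] == 3 and tbl.at["a", "n_active"] == 2
        assert tbl.at["a", "active_fraction"] == pytest.approx(2 / 3)
        assert tbl.at["b", "n_used"] == 2 and tbl.at["b", "active_fraction"] == 0.0

    def test_eligibility_boundary(self):
        flags = [{"a": i < 2, "b": i < 1, "c": False} for i in range(40)]
        act = aggregate_activity(flags)
        # a: 2/40 = 0.05 exactly -> eligible; b: 1/40 = 0.025 -> not
        assert act.eligible(0.05) == {"a"}
        assert act.eligible(0.02) == {"a", "b"}

    def test_min_active_fraction_monotonicity(self):
        rng = np.random.default_rng(4)
        flags = [
            {f"g{i}": bool(rng.random() < 0.3) for i in range(30)} for _ in range(12)
        ]
        act = aggregate_activity(flags)
        prev = None
        for thr in (0.0, 0.1, 0.3, 0.6, 1.0):
            cur = act.eligible(thr)
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestEffectScoresAndOutliers:
    def test_rank_normalized_bounds(self):
        fc = _fc({"a": -5, "b": 0, "c": 5}, {"a": "A", "b": "B", "c": "C"})
        scores = aggregate_effect_scores([fc])
        assert scores["a"] == pytest.approx(-1.0)
        assert scores["b"] == pytest.approx(0.0)
        assert scores["c"] == pytest.approx(1.0)

    def test_hand_computed_z_flags(self):
        # group {0,0,0,-10}: mean -2.5, sd 5 -> z(-10) = -1.5, flagged
        scores = {"g1": 0.0, "g2": 0.0, "g3": 0.0, "g4": -10.0}
        gene_of = {g: "G" for g in scores}
        flags, zs = flag_offtarget_outliers(scores, gene_of)
        assert zs["g4"] == pytest.approx(-1.5)
        assert flags["g4"] and not flags["g1"]

    def test_small_or_constant_groups_never_flagged(self):
        scores = {"a1": 0.0, "a2": -99.0, "b1": 1.0, "b2": 1.0, "b3": 1.0}
        gene_of = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"}
        flags, zs = flag_offtarget_outliers(scores, gene_of)
        assert not any(flags.values())  # A too small, B zero spread
        assert all(z == 0.0 for z in zs.values())

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        gene_of, scores = {}, {}
        for gi in range(20):
            for j in range(rng.integers(1, 7)):
                g = f"G{gi}_g{j}"
                gene_of[g] = f"G{gi}"
                scores[g] = float(rng.normal())
        cfg = SelectionConfig(z_cut=1.25)
        flags, zs = flag_offtarget_outliers(scores, gene_of, cfg)
        for g in scores:
            group = [x for x in scores if gene_of[x] == gene_of[g]]
            vals = np.array([scores[x] for x in group])
            if len(group) < cfg.min_group_size_for_z or np.std(vals, ddof=1) == 0:
                assert flags[g] is False and zs[g] == 0.0
            else:
                z = (scores[g] - vals.mean()) / np.std(vals, ddof=1)
                assert zs[g] == pytest.approx(z)
                assert flags[g] == (abs(z) > cfg.z_cut)


def _activity(rows: dict[str, dict]) -> ActivityTable:
    tbl = pd.DataFrame(rows).T
    for col, default in (
        ("n_used", 1), ("n_active", 0), ("active_fraction", 0.0),
        ("offtarget_outlier", False), ("effect_z", 0.0),
    ):
        if col not in tbl:
            tbl[col] = default
        else:
            tbl[col] = [default if pd.isna(v) else v for v in tbl[col]]
    return ActivityTable(table=tbl)


_CLEAN = [
    "ACGTGACGTACGTCAGCTGA",
    "TGCAGTACGATCGTACGGAT",
    "CAGTCGATCGATCAGCATGC",
    "GATCGTAGCTAGCATCGATC",
    "CGATCAGCTAGCTACGATCG",
    "TACGATCGATCGTACGATCA",
]


class TestRankCandidates:
    def _cands(self, n):
        return [GuideSequence(id=f"c{i}", seq=_CLEAN[i]) for i in range(n)]

    def test_active_first_by_activity(self):
        cands = self._cands(3)
        act = _activity({
            "c0": {"n_used": 10, "n_active": 2, "active_fraction": 0.2},
            "c1": {"n_used": 10, "n_active": 5, "active_fraction": 0.5},
            "c2": {"n_used": 10, "n_active": 0, "active_fraction": 0.0},
        })
        out = rank_candidates("G", cands, act, {}, {})
        assert [c.id for c in out] == ["c1", "c0", "c2"]
        assert out[0].category == EMPIRICAL_ESSENTIAL
        assert out[2].category == EMPIRICAL_NONESSENTIAL

    def test_inactive_ordered_by_annotation(self):
        cands = self._cands(3)
        act = _activity({c.id: {"n_used": 10} for c in cands})
        ctx = {
            "c0": GuideContext(gene="G", chrom="c", cut_pos=0, strand="+",
                               exon_rank=1, n_transcripts=2, tss_distance=100,
                               offtarget_count=0),
            "c1": GuideContext(gene="G", chrom="c", cut_pos=0, strand="+",
                               exon_rank=1, n_transcripts=3, tss_distance=500,
                               offtarget_count=0),
            "c2": GuideContext(gene="G", chrom="c", cut_pos=0, strand="+",
                               exon_rank=1, n_transcripts=2, tss_distance=100,
                               offtarget_count=5),
        }
        out = rank_candidates("G", cands, act, ctx, {})
        # most isoforms first, then nearest TSS, then fewest off-targets
        assert [c.id for c in out] == ["c1", "c0", "c2"]

    def test_flagged_and_outlier_candidates_dropped(self):
        cands = self._cands(3)
        flags = {"c0": sequence_flags(GuideSequence(id="x", seq="AAAAGACGTACGTCAGCTGA"))}
        act = _activity({
            "c1": {"n_used": 10, "offtarget_outlier": True},
            "c2": {"n_used": 10},
        })
        out = rank_candidates("G", cands, act, {}, flags)
        assert [c.id for c in out] == ["c2"]

    def test_max_offtargets_filter(self):
        cands = self._cands(2)
        ctx = {
            "c0": GuideContext(gene="G", chrom="c", cut_pos=0, strand="+",
                               exon_rank=1, n_transcripts=1, tss_distance=0,
                               offtarget_count=9),
            "c1": GuideContext(gene="G", chrom="c", cut_pos=0, strand="+",
                               exon_rank=1, n_transcripts=1, tss_distance=0,
                               offtarget_count=1),
        }
        act = _activity({c.id: {"n_used": 1} for c in cands})
        out = rank_candidates("G", cands, act, ctx, {}, SelectionConfig(max_offtargets=3))
        assert [c.id for c in out] == ["c1"]


class TestDesignDeNovo:
    def test_engineered_pam_sites_found(self):
        genome, _, cands = simulate_genome(n_genes=2, seed=31)
        for cand in cands:
            gene = cand.id.split("_")[0]
            dn = design_de_novo(gene, genome)
            assert len(dn) > 0
            # the planted exon-1 candidate is among the de-novo set unless flagged
            if not sequence_flags(cand).any_flag:
                assert cand.seq in {c.seq for c in dn}
            assert all(c.category == DE_NOVO for c in dn)

    def test_minus_strand_enumeration(self):
        genome, _, _ = simulate_genome(n_genes=1, seed=31)
        gene = next(iter(genome.genes))
        dn = design_de_novo(gene, genome)
        chrom = genome.sequences[genome.genes[gene].chrom]
        from guidescreen.guide_annotation import reverse_complement
        rc_hits = [c for c in dn if c.seq not in chrom and reverse_complement(c.seq) in chrom]
        assert rc_hits  # at least one CCN-strand candidate

    def test_unknown_gene_is_error(self):
        genome, _, _ = simulate_genome(n_genes=1, seed=31)
        with pytest.raises(KeyError, match="absent"):
            design_de_novo("NOPE", genome)


def _pool(prefix: str, n: int, gene: str) -> list[GuideCandidate]:
    rng = np.random.default_rng(abs(hash(prefix)) % 2**31)
    out = []
    seen = set()
    while len(out) < n:
        s = "".join(rng.choice(list("ACGT"), size=20))
        if s in seen:
            continue
        seen.add(s)
        out.append(GuideCandidate(id=f"{prefix}{len(out)}", seq=s, gene=gene, category=CONTROL))
    return out


class TestAssembleLibrary:
    def _ranked(self, genes: dict[str, int]) -> dict[str, list[GuideCandidate]]:
        rng = np.random.default_rng(77)
        out = {}
        seen = set()
        for gene, n in genes.items():
            pool = []
            while len(pool) < n:
                s = "".join(rng.choice(list("ACGT"), size=20))
                if s in seen:
                    continue
                seen.add(s)
                pool.append(GuideCandidate(
                    id=f"{gene}_c{len(pool)}", seq=s, gene=gene,
                    category=EMPIRICAL_ESSENTIAL,
                ))
            out[gene] = pool
        return out

    def test_split_and_size_arithmetic(self):
        ranked = self._ranked({f"G{i}": 8 for i in range(5)})
        nt = _pool("nt", 300, "NON_TARGETING")
        tc = _pool("tc", 135, "TARGETING_CTRL")
        design = assemble_library(ranked, nt, tc)
        # per sub-library: 5 genes x 4 guides + 300 + 135 controls
        assert design.size("A") == 5 * 4 + 300 + 435 - 300
        assert design.size("A") == design.size("B") == 455
        assert not design.failed_genes
        # ranks 1-4 go to A, 5-8 to B
        assert [g.id for g in design.sublibraries["A"]["G0"]] == [f"G0_c{i}" for i in range(4)]
        assert [g.id for g in design.sublibraries["B"]["G0"]] == [f"G0_c{i}" for i in range(4, 8)]

    def test_backfill_from_de_novo(self):
        ranked = self._ranked({"G0": 3})
        nt = _pool("nt", 300, "NON_TARGETING")
        tc = _pool("tc", 135, "TARGETING_CTRL")
        extra = self._ranked({"DN": 8})["DN"]
        provider = lambda gene: [
            GuideCandidate(id=f"{gene}_dn{i}", seq=c.seq, gene=gene, category=DE_NOVO)
            for i, c in enumerate(extra)
        ]
        design = assemble_library(ranked, nt, tc, de_novo_provider=provider)
        assert not design.failed_genes
        a = design.sublibraries["A"]["G0"]
        b = design.sublibraries["B"]["G0"]
        assert [c.category for c in a] == [EMPIRICAL_ESSENTIAL] * 3 + [DE_NOVO]
        assert all(c.category == DE_NOVO for c in b)

    def test_shortfall_reported_not_fatal(self):
        ranked = self._ranked({"G0": 8, "G1": 5})
        nt = _pool("nt", 300, "NON_TARGETING")
        tc = _pool("tc", 135, "TARGETING_CTRL")
        design = assemble_library(ranked, nt, tc)
        assert "G1" in design.failed_genes
        assert "G1" in design.sublibraries["A"]  # A got its full 4
        assert "G1" not in design.sublibraries["B"]
        # sub-library A therefore targets more genes than B
        assert len(design.sublibraries["A"]) > len(design.sublibraries["B"])

    def test_control_pools_shared_and_checked(self):
        ranked = self._ranked({"G0": 8})
        nt = _pool("nt", 300, "NON_TARGETING")
        tc = _pool("tc", 135, "TARGETING_CTRL")
        design = assemble_library(ranked, nt, tc)
        ids_a = {c.id for c in design.entries("A")}
        ids_b = {c.id for c in design.entries("B")}
        ctrl = {c.id for c in design.controls}
        assert ctrl <= ids_a and ctrl <= ids_b
        assert len(ctrl) == 435
        with pytest.raises(ValueError, match="non-targeting control pool"):
            assemble_library(ranked, nt[:299], tc)
        with pytest.raises(ValueError, match="targeting control pool"):
            assemble_library(ranked, nt, tc[:10])

    def test_duplicate_sequence_rejected(self):
        ranked = self._ranked({"G0": 8})
        ranked["G0"][1] = GuideCandidate(
            id="dup", seq=ranked["G0"][0].seq, gene="G0", category=EMPIRICAL_ESSENTIAL
        )
        nt = _pool("nt", 300, "NON_TARGETING")
        tc = _pool("tc", 135, "TARGETING_CTRL")
        with pytest.raises(ValueError, match="duplicate sequence"):
            assemble_library(ranked, nt, tc)

    def test_fuzzed_designs_mutually_exclusive(self):
        rng = np.random.default_rng(55)
        nt = _pool("nt", 300, "NON_TARGETING")
        tc = _pool("tc", 135, "TARGETING_CTRL")
        for trial in range(20):
            n_genes = int(rng.integers(1, 6))
            ranked = self._ranked(
                {f"T{trial}_G{i}": int(rng.integers(4, 12)) for i in range(n_genes)}
            )
            design = assemble_library(ranked, nt, tc)
            ids_a = {c.id for gs in design.sublibraries["A"].values() for c in gs}
            ids_b = {c.id for gs in design.sublibraries["B"].values() for c in gs}
            assert not ids_a & ids_b
            for lib in ("A", "B"):
                for gene, gs in design.sublibraries[lib].items():
                    assert len(gs) == 4

    def test_provenance_summary(self):
        ranked = self._ranked({"G0": 8})
        for i in (6, 7):
            ranked["G0"][i] = GuideCandidate(
                id=ranked["G0"][i].id, seq=ranked["G0"][i].seq, gene="G0",
                category=DE_NOVO,
            )
        nt = _pool("nt", 300, "NON_TARGETING")
        tc = _pool("tc", 135, "TARGETING_CTRL")
        design = assemble_library(ranked, nt, tc)
        prov = provenance_summary(design)
        assert prov["A"] == {EMPIRICAL_ESSENTIAL: 1.0}
        assert prov["B"] == {EMPIRICAL_ESSENTIAL: 0.5, DE_NOVO: 0.5}


class TestLibraryDesignIO:
    def test_frame_tsv_fasta(self, tmp_path):
        ranked = TestAssembleLibrary()._ranked({"G0": 8})
        nt = _pool("nt", 300, "NON_TARGETING")
        tc = _pool("tc", 135, "TARGETING_CTRL")
        design = assemble_library(ranked, nt, tc)
        frame = design.to_frame()
        assert len(frame) == design.size("A") + design.size("B")
        design.to_tsv(tmp_path / "lib.tsv")
        back = pd.read_csv(tmp_path / "lib.tsv", sep="\t")
        assert len(back) == len(frame)
        design.to_fasta(tmp_path / "lib.fa")
        text = (tmp_path / "lib.fa").read_text()
        assert text.count(">") == len(frame)
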