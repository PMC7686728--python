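"""Sequence-level guide filters, off-target counting and gene-context annotation.

Guides are 20-nt protospacers (PAM not included). Three sequence filters flag
guides that behave badly in oligo synthesis, cloning or transcription:
homopolymer runs (>= 4 consecutive A or T, >= 5 consecutive G or C), a BbsI
recognition site (GAAGAC or its reverse complement — the library cloning
enzyme), and extreme GC content (> 75% or < 20%, strict).

Off-target counting is an exhaustive full-length Hamming scan of both genome
strands with a mismatch budget (default 3 substitutions); one on-target site
is subtracted when the guide has an exact genomic match. No PAM requirement is
imposed by default, mirroring alignment-based off-target proxies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

_VALID = set("ACGT")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GuideSequence:
    """A 20-nt protospacer sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) != 20:
            raise ValueError(f"guide {self.id}: length must be 20, got {len(self.seq)}")
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"guide {self.id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class FilterFlags:
    homopolymer: bool
    bbsi_site: bool
    gc_out_of_range: bool
    gc_fraction: float

    @property
    def any_flag(self) -> bool:
        return self.homopolymer or self.bbsi_site or self.gc_out_of_range


@dataclass
class GuideContext:
    """Genomic context of a uniquely-mapping guide."""

    gene: str | None
    chrom: str
    cut_pos: int
    strand: str
    exon_rank: int
    n_transcripts: int
    tss_distance: int
    offtarget_count: int = 0


# ---------------------------------------------------------------------------
# genome + annotation model


@dataclass
class Transcript:
    id: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by start

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exons_in_rank_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def longest_transcript(self) -> Transcript:
        return max(self.transcripts.values(), key=lambda t: (t.length, t.id))


@dataclass
class Genome:
    """In-memory genome: chromosome sequences plus gene/transcript/exon model."""

    sequences: dict[str, str]
    genes: dict[str, Gene] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}

    @classmethod
    def from_files(cls, fasta_path, gff_path=None) -> "Genome":
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        genes = read_gff(gff_path) if gff_path is not None else {}
        return cls(sequences=sequences, genes=genes)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def read_gff(path) -> dict[str, Gene]:
    """Parse a GFF3 subset (gene/mRNA/exon) into the gene model.

    Coordinates are converted from 1-based closed to 0-based half-open.
    """
    genes: dict[str, Gene] = {}
    tx_gene: dict[str, str] = {}
    text = Path(path).read_text() if not hasattr(path, "read") else path.read()
    for line_no, line in enumerate(StringIO(text), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF line {line_no}: expected 9 fields")
        chrom, _, ftype, start, end, _, strand, _, attrs = fields
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
        )
        s, e = int(start) - 1, int(end)
        if ftype == "gene":
            gid = attr["ID"]
            genes[gid] = Gene(id=gid, chrom=chrom, strand=strand)
        elif ftype in ("mRNA", "transcript"):
            tid, parent = attr["ID"], attr["Parent"]
            tx_gene[tid] = parent
            genes[parent].transcripts[tid] = Transcript(id=tid, strand=strand, exons=[])
        elif ftype == "exon":
            parent = attr["Parent"]
            gid = tx_gene[parent]
            genes[gid].transcripts[parent].exons.append((s, e))
    for g in genes.values():
        for t in g.transcripts.values():
            t.exons.sort()
    return genes


def write_gff(genes: dict[str, Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes.values(), key=lambda x: x.id):
            gs = min(s for t in g.transcripts.values() for s, _ in t.exons)
            ge = max(e for t in g.transcripts.values() for _, e in t.exons)
            fh.write(f"{g.chrom}\tsim\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\tID={g.id}\n")
            for t in sorted(g.transcripts.values(), key=lambda x: x.id):
                ts = t.exons[0][0]
                te = t.exons[-1][1]
                fh.write(
                    f"{g.chrom}\tsim\tmRNA\t{ts + 1}\t{te}\t.\t{t.strand}\t.\t"
                    f"ID={t.id};Parent={g.id}\n"
                )
                for i, (s, e) in enumerate(t.exons, start=1):
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                        f"ID={t.id}.e{i};Parent={t.id}\n"
                    )


# ---------------------------------------------------------------------------
# sequence filters


def sequence_flags(g: GuideSequence, max_gc: float = 0.75, min_gc: float = 0.20) -> FilterFlags:
    """Apply the homopolymer / BbsI / GC filters to one guide (pure)."""
    seq = g.seq
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    homopolymer = False
    run_char, run_len = "", 0
    for ch in seq:
        if ch == run_char:
            run_len += 1
        else:
            run_char, run_len = ch, 1
        if ch in "AT" and run_len >= 4:
            homopolymer = True
        if ch in "GC" and run_len >= 5:
            homopolymer = True
    bbsi = "GAAGAC" in seq or "GTCTTC" in seq
    gc_out = gc > max_gc or gc < min_gc
    return FilterFlags(
        homopolymer=homopolymer, bbsi_site=bbsi, gc_out_of_range=gc_out, gc_fraction=gc
    )


# ---------------------------------------------------------------------------
# off-target scan


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_counts(chrom_arr: np.ndarray, guide_arr: np.ndarray) -> np.ndarray:
    """Hamming distance of the guide to every 20-mer window of a sequence."""
    k = len(guide_arr)
    if len(chrom_arr) < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(chrom_arr, k)
    return (windows != guide_arr).sum(axis=1)


def count_offtargets(g: GuideSequence, genome: Genome, max_mm: int = 3) -> int:
    """Number of genomic sites within ``max_mm`` substitutions, minus on-target.

    Both strands are scanned (the reverse-complement of the guide against the
    forward sequence covers the minus strand). When the guide matches exactly
    somewhere, one on-target occurrence is subtracted; a guide absent from the
    genome keeps all its near-matches counted.
    """
    if not genome.sequences:
        raise ValueError("empty genome")
    fwd = _encode(g.seq)
    rev = _encode(reverse_complement(g.seq))
    total = 0
    exact = 0
    for seq in genome.sequences.values():
        arr = _encode(seq)
        for probe in (fwd, rev):
            mm = _mismatch_counts(arr, probe)
            total += int((mm <= max_mm).sum())
            exact += int((mm == 0).sum())
    if exact > 0:
        total -= 1
    return total


def find_exact_matches(seq: str, genome: Genome) -> list[tuple[str, int, str]]:
    """All exact full-length matches as (chrom, 0-based start, strand)."""
    hits: list[tuple[str, int, str]] = []
    rc = reverse_complement(seq)
    for chrom, chrom_seq in genome.sequences.items():
        start = chrom_seq.find(seq)
        while start != -1:
            hits.append((chrom, start, "+"))
            start = chrom_seq.find(seq, start + 1)
        start = chrom_seq.find(rc)
        while start != -1:
            hits.append((chrom, start, "-"))
            start = chrom_seq.find(rc, start + 1)
    return hits


def cut_position(match_start: int, strand: str) -> int:
    """Cut coordinate between protospacer positions 17 and 18 (3 bp from PAM)."""
    return match_start + 17 if strand == "+" else match_start + 3


def annotate_guide(
    g: GuideSequence, genome: Genome, offtarget_max_mm: int = 3, count_ot: bool = True
) -> GuideContext:
    """Annotate a uniquely-mapping guide with exon/transcript/TSS context.

    ``exon_rank`` is the 1-based rank of the exon containing the cut site in
    the gene's longest transcript (transcription order); ``n_transcripts``
    counts transcripts with an exon overlapping the cut site;
    ``tss_distance`` is measured to the longest transcript's TSS.
    """
    hits = find_exact_matches(g.seq, genome)
    if not hits:
        raise ValueError(f"unmappable guide {g.id}")
    if len(hits) > 1:
        raise ValueError(f"ambiguous on-target for guide {g.id}: {len(hits)} exact matches")
    chrom, start, strand = hits[0]
    pos = cut_position(start, strand)

    containing_gene: Gene | None = None
    n_tx = 0
    for gene in genome.genes.values():
        if gene.chrom != chrom:
            continue
        overlapping = [
            t
            for t in gene.transcripts.values()
            if any(s <= pos < e for s, e in t.exons)
        ]
        if overlapping:
            containing_gene = gene
            n_tx = len(overlapping)
            break
    ot = count_offtargets(g, genome, max_mm=offtarget_max_mm) if count_ot else 0
    if containing_gene is None:
        return GuideContext(
            gene=None, chrom=chrom, cut_pos=pos, strand=strand,
            exon_rank=0, n_transcripts=0, tss_distance=0, offtarget_count=ot,
        )
    longest = containing_gene.longest_transcript()
    if not any(s <= pos < e for s, e in longest.exons):
        # gene's longest transcript skips this exon: rank on the longest
        # transcript that does contain the cut site
        longest = max(
            (
                t
                for t in containing_gene.transcripts.values()
                if any(s <= pos < e for s, e in t.exons)
            ),
            key=lambda t: (t.length, t.id),
        )
    exon_rank = 0
    for rank, (s, e) in enumerate(longest.exons_in_rank_order(), start=1):
        if s <= pos < e:
            exon_rank = rank
            break
    tss_distance = abs(pos - longest.tss)
    return GuideContext(
        gene=containing_gene.id,
        chrom=chrom,
        cut_pos=pos,
        strand=strand,
        exon_rank=exon_rank,
        n_transcripts=n_tx,
        tss_distance=tss_distance,
        offtarget_count=ot,
    )
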