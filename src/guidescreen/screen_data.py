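"""Count-table data model, normalization, fold changes and sub-library merging.

Screens are represented as sgRNA x sample count matrices. Normalization divides
each sample by the median count of the *targeting controls* (guides cutting a
neutral locus), after adding a pseudocount, so that depletion is measured
relative to the double-strand-break background rather than to the whole
library. Depletion phenotypes are log2 fold changes of an endpoint sample over
the plasmid/T0 reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

#: reserved gene labels in count tables mapping to control classes
NON_TARGETING_LABEL = "NON_TARGETING"
TARGETING_CTRL_LABEL = "TARGETING_CTRL"

GENE_TARGETING = "gene_targeting"
TARGETING_CONTROL = "targeting_control"
NON_TARGETING_CONTROL = "non_targeting_control"

_CONTROL_CLASSES = (GENE_TARGETING, TARGETING_CONTROL, NON_TARGETING_CONTROL)


def _class_from_gene(gene: str) -> str:
    if gene == NON_TARGETING_LABEL:
        return NON_TARGETING_CONTROL
    if gene == TARGETING_CTRL_LABEL:
        return TARGETING_CONTROL
    return GENE_TARGETING


@dataclass
class CountMatrix:
    """Raw sgRNA x sample read counts for one screen.

    Parameters
    ----------
    guide_ids : list of str
        Unique guide identifiers, row order preserved from input.
    gene_of : dict
        Guide id -> target gene symbol (reserved labels for controls).
    control_class_of : dict
        Guide id -> one of ``gene_targeting``, ``targeting_control``,
        ``non_targeting_control``.
    samples : list of str
        Ordered sample names.
    counts : pandas.DataFrame
        Integer counts, index = guide ids, columns = samples.
    meta : dict
        Free-form screen metadata (screen id, cell line, sub-library tag).
    """

    guide_ids: list[str]
    gene_of: dict[str, str]
    control_class_of: dict[str, str]
    samples: list[str]
    counts: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.guide_ids)) != len(self.guide_ids):
            seen: set[str] = set()
            for g in self.guide_ids:
                if g in seen:
                    raise ValueError(f"duplicate guide id {g}")
                seen.add(g)
        if len(self.samples) < 1:
            raise ValueError("CountMatrix requires at least one sample")
        for g in self.guide_ids:
            if g not in self.gene_of:
                raise ValueError(f"guide {g} missing gene assignment")
            if self.control_class_of.get(g) not in _CONTROL_CLASSES:
                raise ValueError(f"guide {g} missing/invalid control class")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_guides(self) -> int:
        return len(self.guide_ids)

    def guides_of_class(self, control_class: str) -> list[str]:
        return [g for g in self.guide_ids if self.control_class_of[g] == control_class]

    def subset(self, guides: Iterable[str]) -> "CountMatrix":
        """Row subset preserving original order."""
        keep = set(guides)
        ids = [g for g in self.guide_ids if g in keep]
        return CountMatrix(
            guide_ids=ids,
            gene_of={g: self.gene_of[g] for g in ids},
            control_class_of={g: self.control_class_of[g] for g in ids},
            samples=list(self.samples),
            counts=self.counts.loc[ids].copy(),
            meta=dict(self.meta),
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"sgRNA": self.guide_ids})
        df["gene"] = [self.gene_of[g] for g in self.guide_ids]
        for s in self.samples:
            df[s] = self.counts.loc[self.guide_ids, s].to_numpy()
        df.to_csv(path, sep="\t", index=False)


@dataclass
class NormalizedMatrix:
    """Targeting-control median-normalized counts (strictly positive reals)."""

    guide_ids: list[str]
    gene_of: dict[str, str]
    control_class_of: dict[str, str]
    samples: list[str]
    values: pd.DataFrame
    pseudocount_used: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("normalized values must be positive")


@dataclass
class FoldChangeTable:
    """Per-guide log2 fold changes of ``sample`` relative to ``reference``."""

    guide_ids: list[str]
    fc: pd.Series
    sample: str
    reference: str
    gene_of: dict[str, str] = field(default_factory=dict)
    control_class_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.fc.to_numpy()).all():
            raise ValueError("fold changes must be finite")
        if len(self.fc) != len(self.guide_ids):
            raise ValueError("one fold change per guide required")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "sgRNA": self.guide_ids,
                "gene": [self.gene_of.get(g, "") for g in self.guide_ids],
                "fc": self.fc.loc[self.guide_ids].to_numpy(),
            }
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class ReferenceSets:
    """Gold-standard core-essential and nonessential gene lists."""

    core_essential: set[str]
    nonessential: set[str]

    def __post_init__(self) -> None:
        self.core_essential = set(self.core_essential)
        self.nonessential = set(self.nonessential)
        if not self.core_essential or not self.nonessential:
            raise ValueError("reference sets must be non-empty")
        overlap = self.core_essential & self.nonessential
        if overlap:
            raise ValueError(f"reference sets overlap: {sorted(overlap)[:5]}")


def read_count_table(path) -> CountMatrix:
    """Read a tab-separated count table (``sgRNA<TAB>gene<TAB><sample...>``).

    Control classes are inferred from the reserved gene labels
    ``NON_TARGETING`` and ``TARGETING_CTRL``; all other genes are
    gene-targeting. Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "sgRNA" or cols[1] != "gene":
        raise ValueError(
            f"missing/invalid header in {path}: expected 'sgRNA<TAB>gene<TAB><sample...>'"
        )
    sample_cols = cols[2:]
    guide_ids: list[str] = []
    gene_of: dict[str, str] = {}
    seen: set[str] = set()
    counts = np.empty((len(df), len(sample_cols)), dtype=np.int64)
    for i, row in enumerate(df.itertuples(index=False)):
        gid = row[0]
        if gid in seen:
            raise ValueError(f"duplicate guide id {gid}")
        seen.add(gid)
        guide_ids.append(gid)
        gene_of[gid] = row[1]
        for j, raw in enumerate(row[2:]):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise ValueError(f"non-integer count {raw!r} in row {i + 2}") from None
            if val < 0:
                raise ValueError(f"negative count {val} in row {i + 2}")
            counts[i, j] = val
    control_class_of = {g: _class_from_gene(gene_of[g]) for g in guide_ids}
    return CountMatrix(
        guide_ids=guide_ids,
        gene_of=gene_of,
        control_class_of=control_class_of,
        samples=list(sample_cols),
        counts=pd.DataFrame(counts, index=guide_ids, columns=sample_cols),
    )


def normalize_counts(counts: CountMatrix, pseudocount: int = 1) -> NormalizedMatrix:
    """Pseudocount + targeting-control median normalization.

    ``value(g, s) = (count(g, s) + pseudocount) / median_{targeting controls}
    (count(., s) + pseudocount)`` — the per-sample targeting-control median of
    the output is 1 by construction.
    """
    if pseudocount < 1:
        raise ValueError("pseudocount must be >= 1")
    tctrl = counts.guides_of_class(TARGETING_CONTROL)
    if not tctrl:
        raise ValueError("no targeting controls present; cannot normalize")
    shifted = counts.counts.astype(float) + pseudocount
    medians = shifted.loc[tctrl].median(axis=0)
    values = shifted.div(medians, axis=1)
    return NormalizedMatrix(
        guide_ids=list(counts.guide_ids),
        gene_of=dict(counts.gene_of),
        control_class_of=dict(counts.control_class_of),
        samples=list(counts.samples),
        values=values,
        pseudocount_used=pseudocount,
        meta=dict(counts.meta),
    )


def log2_fold_change(norm: NormalizedMatrix, sample: str, reference: str) -> FoldChangeTable:
    """fc(g) = log2(value(g, sample) / value(g, reference))."""
    for name in (sample, reference):
        if name not in norm.samples:
            raise KeyError(f"unknown sample name {name!r}")
    fc = np.log2(norm.values[sample] / norm.values[reference])
    return FoldChangeTable(
        guide_ids=list(norm.guide_ids),
        fc=fc,
        sample=sample,
        reference=reference,
        gene_of=dict(norm.gene_of),
        control_class_of=dict(norm.control_class_of),
    )


def mean_fold_change(tables: list[FoldChangeTable]) -> FoldChangeTable:
    """Average fold changes across replicate tables (same guide sets)."""
    if not tables:
        raise ValueError("no fold-change tables given")
    base = tables[0]
    ids = set(base.guide_ids)
    for t in tables[1:]:
        if set(t.guide_ids) != ids:
            raise ValueError("replicate tables cover different guide sets")
    stacked = pd.concat([t.fc.loc[base.guide_ids] for t in tables], axis=1)
    return FoldChangeTable(
        guide_ids=list(base.guide_ids),
        fc=stacked.mean(axis=1),
        sample="+".join(t.sample for t in tables),
        reference=base.reference,
        gene_of=dict(base.gene_of),
        control_class_of=dict(base.control_class_of),
    )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def combine_sublibraries(a: CountMatrix, b: CountMatrix) -> CountMatrix:
    """Merge two sub-library screens into one depth-matched count matrix.

    Each input's counts are rescaled per sample to the median count across all
    samples of both inputs (division by the sample median, multiplication by
    the global median), rounded half-up. Gene-targeting guide sets must be
    disjoint; control guides present in both are kept as two rows with
    ``__A`` / ``__B`` suffixed ids.
    """
    if a.samples != b.samples:
        raise ValueError("sample sets must correspond pairwise (same labels, same order)")
    genes_a = {g for g in a.guide_ids if a.control_class_of[g] == GENE_TARGETING}
    genes_b = {g for g in b.guide_ids if b.control_class_of[g] == GENE_TARGETING}
    overlap = genes_a & genes_b
    if overlap:
        raise ValueError(
            f"overlapping gene-targeting guide ids: {sorted(overlap)[:5]}"
        )
    all_counts = np.concatenate([a.counts.to_numpy().ravel(), b.counts.to_numpy().ravel()])
    global_median = float(np.median(all_counts))

    def rescale(m: CountMatrix) -> np.ndarray:
        arr = m.counts.to_numpy().astype(float)
        med = np.median(arr, axis=0)
        return _round_half_up(arr / med * global_median)

    scaled_a = rescale(a)
    scaled_b = rescale(b)

    shared = set(a.guide_ids) & set(b.guide_ids)
    ids: list[str] = []
    gene_of: dict[str, str] = {}
    ccls: dict[str, str] = {}
    for src, suffix, gene_map, cls_map in ((a, "__A", a.gene_of, a.control_class_of),
                                           (b, "__B", b.gene_of, b.control_class_of)):
        for g in src.guide_ids:
            out = g + suffix if g in shared else g
            ids.append(out)
            gene_of[out] = gene_map[g]
            ccls[out] = cls_map[g]
    counts = pd.DataFrame(
        np.vstack([scaled_a, scaled_b]), index=ids, columns=a.samples
    )
    meta = {"combined_from": [a.meta.get("screen", "A"), b.meta.get("screen", "B")]}
    return CountMatrix(
        guide_ids=ids,
        gene_of=gene_of,
        control_class_of=ccls,
        samples=list(a.samples),
        counts=counts,
        meta=meta,
    )


def replicate_correlation(x: FoldChangeTable, y: FoldChangeTable) -> tuple[float, float]:
    """Pearson and Spearman correlation over matched guides."""
    shared = [g for g in x.guide_ids if g in set(y.guide_ids)]
    if set(x.guide_ids) != set(y.guide_ids):
        raise ValueError("fold-change tables cover different guide sets")
    if len(shared) < 3:
        raise ValueError("need at least 3 shared guides for correlation")
    xv = x.fc.loc[shared].to_numpy()
    yv = y.fc.loc[shared].to_numpy()
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    pearson = stats.pearsonr(xv, yv).statistic
    spearman = stats.spearmanr(xv, yv).statistic
    return float(pearson), float(spearman)
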