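"""Allocation of DmCs and DMRs to gene territories.

Eleven mutually exclusive labels are used: a three-tier promoter (<1 kb,
1-2 kb, 2-3 kb upstream of the TSS in transcription direction), 5' UTR,
first exon, other exons, first intron, other introns, 3' UTR, downstream
(0-1 kb past the gene end) and distal intergenic.  When several genes offer
candidate labels for the same position, the winner is chosen by label
precedence (UTRs beat exons beat introns beat promoter tiers beat
downstream), then by distance to the nearest TSS, then by gene id.  A DMR
interval is assigned by its midpoint so that territory fractions sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .formats_io import CONTEXTS, GeneModel, MethylomeTable

LABELS = (
    "promoter_0_1kb",
    "promoter_1_2kb",
    "promoter_2_3kb",
    "utr5",
    "exon_first",
    "exon_other",
    "intron_first",
    "intron_other",
    "utr3",
    "downstream",
    "distal_intergenic",
)

PROMOTER_LABELS = ("promoter_0_1kb", "promoter_1_2kb", "promoter_2_3kb")

#: lower rank wins when a position falls in several territories
PRECEDENCE = {
    "utr5": 0,
    "utr3": 1,
    "exon_first": 2,
    "exon_other": 3,
    "intron_first": 4,
    "intron_other": 5,
    "promoter_0_1kb": 6,
    "promoter_1_2kb": 7,
    "promoter_2_3kb": 8,
    "downstream": 9,
}

PROMOTER_TIERS = (1000, 2000, 3000)
DOWNSTREAM_SPAN = 1000


@dataclass(frozen=True)
class TerritoryAssignment:
    gene_id: str | None
    label: str
    distance_to_tss: int | None  # signed, transcription direction (+ downstream of TSS)


def _candidate_intervals(gene: GeneModel):
    """Yield (start, end, label) half-open candidate intervals for one gene."""
    tss = gene.tss
    if gene.strand == "+":
        for i, tier in enumerate(PROMOTER_TIERS):
            lo = tss - tier
            hi = tss - (PROMOTER_TIERS[i - 1] if i else 0)
            yield max(0, lo), max(0, hi), PROMOTER_LABELS[i]
        yield gene.end, gene.end + DOWNSTREAM_SPAN, "downstream"
    else:
        for i, tier in enumerate(PROMOTER_TIERS):
            lo = tss + 1 + (PROMOTER_TIERS[i - 1] if i else 0)
            hi = tss + 1 + tier
            yield lo, hi, PROMOTER_LABELS[i]
        yield max(0, gene.start - DOWNSTREAM_SPAN), gene.start, "downstream"
    for i, (s, e) in enumerate(gene.exons):
        yield s, e, "exon_first" if i == 0 else "exon_other"
    for i, (s, e) in enumerate(gene.introns):
        yield s, e, "intron_first" if i == 0 else "intron_other"
    for s, e in gene.utr5:
        yield s, e, "utr5"
    for s, e in gene.utr3:
        yield s, e, "utr3"


class TerritoryIndex:
    """Interval index over the candidate territories of a gene set."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for gene in self.genes:
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            for s, e, label in _candidate_intervals(gene):
                if e > s:
                    tree.addi(s, e, (PRECEDENCE[label], label, gene.gene_id, gene.tss, gene.strand))

    def assign(self, chrom: str, pos: int) -> TerritoryAssignment:
        tree = self._trees.get(chrom)
        hits = tree[pos] if tree is not None else ()
        if not hits:
            return TerritoryAssignment(None, "distal_intergenic", None)
        best = min(
            hits,
            key=lambda iv: (iv.data[0], abs(pos - iv.data[3]), iv.data[2]),
        )
        rank, label, gene_id, tss, strand = best.data
        dist = pos - tss if strand == "+" else tss - pos
        return TerritoryAssignment(gene_id, label, int(dist))


def assign_territory(
    feature: tuple, genes: Sequence[GeneModel] | TerritoryIndex
) -> TerritoryAssignment:
    """Assign one feature to a gene territory.

    ``feature`` is ``(chrom, pos)`` for a point (DmC) or
    ``(chrom, start, end)`` for an interval (DMR), which is assigned by its
    midpoint.
    """
    index = genes if isinstance(genes, TerritoryIndex) else TerritoryIndex(genes)
    if len(feature) == 2:
        chrom, pos = feature
    elif len(feature) == 3:
        chrom, start, end = feature
        pos = (start + end) // 2
    else:
        raise ValueError("feature must be (chrom,pos) or (chrom,start,end)")
    return index.assign(chrom, int(pos))


def assign_territories(
    features: pd.DataFrame, genes: Sequence[GeneModel] | TerritoryIndex
) -> pd.DataFrame:
    """Vector version: adds gene_id / label / distance_to_tss columns.

    ``features`` needs ``chrom`` plus either ``pos`` or ``start``/``end``.
    """
    index = genes if isinstance(genes, TerritoryIndex) else TerritoryIndex(genes)
    if "pos" in features.columns:
        points = features["pos"].to_numpy()
    else:
        points = ((features["start"] + features["end"]) // 2).to_numpy()
    out = features.copy()
    assigned = [index.assign(c, int(p)) for c, p in zip(features["chrom"], points)]
    out["gene_id"] = [a.gene_id for a in assigned]
    out["label"] = [a.label for a in assigned]
    out["distance_to_tss"] = [a.distance_to_tss for a in assigned]
    return out


def territory_distribution(assignments: pd.DataFrame | Iterable) -> pd.Series:
    """Fraction of features per territory label.

    The eleven exclusive labels sum to 1; an additional ``promoter`` entry
    merges the three promoter tiers (and is excluded from the sum-to-one
    set).
    """
    if isinstance(assignments, pd.DataFrame):
        labels = assignments["label"]
    else:
        labels = pd.Series([a.label for a in assignments], dtype=str)
    if len(labels) == 0:
        raise ValueError("territory_distribution needs at least one assignment")
    counts = labels.value_counts().reindex(LABELS, fill_value=0)
    frac = counts / counts.sum()
    frac.loc["promoter"] = frac[list(PROMOTER_LABELS)].sum()
    return frac


def territory_methylation_profile(
    methylome: MethylomeTable | pd.DataFrame,
    genes: Sequence[GeneModel] | TerritoryIndex,
    min_depth: int = 1,
) -> pd.DataFrame:
    """Pooled methylation level per (territory label, context).

    The level is the read-weighted mean sum(meth)/sum(total) over the sites
    assigned to each label; label/context combinations with no sites are
    absent from the result rather than reported as zero.
    """
    sites = methylome.sites if isinstance(methylome, MethylomeTable) else methylome
    sites = sites[sites["total_reads"] >= min_depth]
    annotated = assign_territories(sites, genes)
    grouped = annotated.groupby(["label", "context"], observed=True)
    prof = grouped.agg(
        n_sites=("pos", "size"),
        meth=("meth_reads", "sum"),
        total=("total_reads", "sum"),
    ).reset_index()
    prof["level"] = prof["meth"] / prof["total"]
    return prof
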