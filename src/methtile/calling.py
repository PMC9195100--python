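"""5-mC calling: non-conversion estimation, binomial methylation calls,
sequence-context classification and global methylation summaries.

The methylation caller follows the standard WGBS error model: after
bisulfite treatment an unmethylated cytosine is read as methylated only when
it escapes conversion, which happens at the non-conversion rate ``r``
estimated from a chromosome assumed devoid of methylation (the chloroplast
in plants).  A site with ``m`` methylated reads out of ``n`` is called
methylated when the upper-tail exact binomial probability
P(X >= m | n, r) falls below ``alpha`` (default 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import CONTEXTS, CytosineSite, MethylomeTable

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_ALPHA = 0.001
DEFAULT_MIN_DEPTH = 5


class NotACytosine(ValueError):
    """The queried (position, strand) does not carry a cytosine."""


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------


def classify_context(
    genome: dict[str, str], chrom: str, pos: int, strand: str
) -> str | None:
    """Classify a cytosine into CG / CHG / CHH (H = A, C or T).

    For a plus-strand cytosine the two downstream Watson bases are
    inspected; for a minus-strand cytosine the Crick-strand triplet (the
    reverse complement, read 3'->5' on Watson) is used.  Returns ``None``
    when the triplet runs off the contig end and the class cannot be
    resolved; raises :class:`NotACytosine` if the base on the given strand
    is not a cytosine.
    """
    seq = genome[chrom]
    base = seq[pos]
    if strand == "+":
        if base != "C":
            raise NotACytosine(f"{chrom}:{pos}:+ is {base}, not C")
        nxt = seq[pos + 1] if pos + 1 < len(seq) else None
        nxt2 = seq[pos + 2] if pos + 2 < len(seq) else None
    elif strand == "-":
        if base != "G":
            raise NotACytosine(f"{chrom}:{pos}:- is {base.translate(_COMPLEMENT)}, not C")
        nxt = seq[pos - 1].translate(_COMPLEMENT) if pos - 1 >= 0 else None
        nxt2 = seq[pos - 2].translate(_COMPLEMENT) if pos - 2 >= 0 else None
    else:
        raise ValueError(f"bad strand {strand!r}")
    if nxt is None:
        return None
    if nxt == "G":
        return "CG"
    if nxt2 is None:
        return None
    if nxt2 == "G":
        return "CHG"
    if nxt == "N" or nxt2 == "N":
        return None
    return "CHH"


def scan_cytosines(genome: dict[str, str]) -> pd.DataFrame:
    """Vectorised scan of every classifiable cytosine on both strands.

    Returns a DataFrame (chrom, pos, strand, context, dinuc) sorted by
    (chrom, pos, strand).  Cytosines whose context cannot be resolved at a
    contig end are skipped.
    """
    frames = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        C, G = ord("C"), ord("G")
        n = len(arr)

        # plus strand: need pos+1 (CG) or pos+2 (CHG vs CHH)
        pos = np.flatnonzero(arr == C)
        pos = pos[pos + 1 < n]
        nxt = arr[pos + 1]
        is_cg = nxt == G
        deep = pos + 2 < n
        nxt2 = np.where(deep, arr[np.minimum(pos + 2, n - 1)], 0)
        ctx = np.where(is_cg, "CG", np.where(nxt2 == G, "CHG", "CHH"))
        keep = is_cg | deep
        pos, ctx, nxt = pos[keep], ctx[keep], nxt[keep]
        dinuc = np.char.add("C", np.frombuffer(bytes(nxt), dtype="S1").astype("U1"))
        plus = pd.DataFrame(
            {"chrom": chrom, "pos": pos, "strand": "+", "context": ctx, "dinuc": dinuc}
        )

        # minus strand: cytosine where Watson has G; neighbours at pos-1, pos-2
        mpos = np.flatnonzero(arr == G)
        mpos = mpos[mpos - 1 >= 0]
        prv = arr[mpos - 1]
        is_cg = prv == C  # complement(prv) == G
        deep = mpos - 2 >= 0
        prv2 = np.where(deep, arr[np.maximum(mpos - 2, 0)], 0)
        ctx = np.where(is_cg, "CG", np.where(prv2 == C, "CHG", "CHH"))
        keep = is_cg | deep
        mpos, ctx, prv = mpos[keep], ctx[keep], prv[keep]
        comp = {A: B for A, B in zip(b"ACGT", "TGCA")}
        prv_c = np.array([comp[x] for x in prv], dtype="U1") if len(prv) else np.array([], dtype="U1")
        dinuc = np.char.add("C", prv_c)
        minus = pd.DataFrame(
            {"chrom": chrom, "pos": mpos, "strand": "-", "context": ctx, "dinuc": dinuc}
        )
        frames.append(pd.concat([plus, minus], ignore_index=True))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# non-conversion estimation
# ---------------------------------------------------------------------------


def estimate_nonconversion(organelle_methylome: MethylomeTable | pd.DataFrame) -> float:
    """Pooled methylated-read fraction on an unmethylated (organelle) genome.

    The returned value is the bisulfite non-conversion rate; the conversion
    rate is its complement.
    """
    sites = (
        organelle_methylome.sites
        if isinstance(organelle_methylome, MethylomeTable)
        else organelle_methylome
    )
    total = int(sites["total_reads"].sum())
    if total == 0:
        raise ValueError("no reads on the organelle chromosome")
    return float(sites["meth_reads"].sum()) / total


# ---------------------------------------------------------------------------
# binomial methylation calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McCall:
    site: CytosineSite
    p_value: float
    is_methylated: bool
    assayed: bool = True


def _check_rate(nonconversion: float) -> None:
    if not (0.0 < nonconversion < 1.0):
        raise ValueError(f"non-conversion rate must be in (0,1), got {nonconversion}")


def call_mc(
    site: CytosineSite,
    nonconversion: float,
    alpha: float = DEFAULT_ALPHA,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> McCall:
    """Exact one-sided binomial methylation call for a single site.

    p = P(X >= meth_reads | n = total_reads, rate = nonconversion). Sites
    below ``min_depth`` are marked unassayed (never 'unmethylated').
    """
    _check_rate(nonconversion)
    if site.total_reads < 1:
        raise ValueError("call_mc requires total_reads >= 1")
    p = float(stats.binom.sf(site.meth_reads - 1, site.total_reads, nonconversion))
    assayed = site.total_reads >= min_depth
    return McCall(site=site, p_value=p, is_methylated=assayed and p < alpha, assayed=assayed)


def call_mc_table(
    methylome: MethylomeTable | pd.DataFrame,
    nonconversion: float,
    alpha: float = DEFAULT_ALPHA,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Vectorised binomial calls; adds p_value / assayed / is_methylated."""
    _check_rate(nonconversion)
    sites = methylome.sites if isinstance(methylome, MethylomeTable) else methylome
    out = sites.copy()
    n = out["total_reads"].to_numpy()
    m = out["meth_reads"].to_numpy()
    out["p_value"] = stats.binom.sf(m - 1, n, nonconversion)
    out["assayed"] = n >= min_depth
    out["is_methylated"] = out["assayed"] & (out["p_value"] < alpha)
    return out


# ---------------------------------------------------------------------------
# global summaries
# ---------------------------------------------------------------------------


@dataclass
class GlobalMcSummary:
    """Per-context and overall counts of assayed and methylated cytosines."""

    n_assayed: dict[str, int]
    n_methylated: dict[str, int]

    @property
    def n_assayed_total(self) -> int:
        return sum(self.n_assayed.values())

    @property
    def n_methylated_total(self) -> int:
        return sum(self.n_methylated.values())

    @property
    def percent(self) -> dict[str, float]:
        return {
            ctx: 100.0 * self.n_methylated[ctx] / self.n_assayed[ctx]
            if self.n_assayed[ctx]
            else float("nan")
            for ctx in self.n_assayed
        }

    @property
    def percent_total(self) -> float:
        return 100.0 * self.n_methylated_total / self.n_assayed_total


def global_mc_content(calls: pd.DataFrame) -> GlobalMcSummary:
    """Summarise calls from :func:`call_mc_table` into 5-mC percentages.

    Unassayed sites are excluded from all denominators.
    """
    assayed = calls[calls["assayed"]]
    if len(assayed) == 0:
        raise ValueError("no assayed sites: cannot summarise 5-mC content")
    n_assayed = {ctx: 0 for ctx in CONTEXTS}
    n_meth = {ctx: 0 for ctx in CONTEXTS}
    grouped = assayed.groupby("context", observed=True)
    for ctx, grp in grouped:
        n_assayed[ctx] = int(len(grp))
        n_meth[ctx] = int(grp["is_methylated"].sum())
    return GlobalMcSummary(n_assayed=n_assayed, n_methylated=n_meth)
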