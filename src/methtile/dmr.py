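"""DmC and 100-bp-bin DMR detection between a treatment and a control
methylome, per sequence context.

Pipeline: :func:`tile_and_pool` pools read counts of sites assayed in both
samples into fixed, genome-tiling 100-bp bins; :func:`filter_bins` applies
the coverage (mean depth >= 5 in each sample) and cytosine-count (>= 3)
filters; each surviving bin is tested with a two-sided Fisher exact test on
the pooled 2x2 read-count table; :func:`call_dmrs` converts p-values into
Benjamini-Hochberg q-values within each context and applies the effect-size
thresholds (|level difference| >= 0.20, level fold >= 2, q < 0.05 and at
least 3 differentially methylated cytosines inside the bin).

The two-sided Fisher p-value is the sum of the probabilities of all tables
with the observed margins that are no more probable than the observed one.
For tables with total reads <= ``_EXACT_LIMIT`` the hypergeometric weights
are computed as exact integers, so ties are decided exactly; larger pooled
tables use log-gamma arithmetic with a 1+1e-7 relative tie tolerance.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .formats_io import CONTEXTS, MethylomeTable

DEFAULT_BIN_SIZE = 100
DEFAULT_MIN_DEPTH = 5.0
DEFAULT_MIN_CYTOSINES = 3
DEFAULT_MIN_DIFF = 0.20
DEFAULT_MIN_FOLD = 2.0
DEFAULT_ALPHA_Q = 0.05
DEFAULT_MIN_DMCS = 3
FOLD_EPSILON = 0.01

_EXACT_LIMIT = 500  # largest table total handled by exact integer weights


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided)
# ---------------------------------------------------------------------------


def _fisher_large_impl(a: int, b: int, c: int, d: int) -> float:
    """Log-gamma two-sided Fisher p for big pooled tables (tie tolerance 1e-7)."""
    from scipy.special import gammaln

    n1, n2 = a + b, c + d
    K = a + c
    kmin, kmax = max(0, K - n2), min(K, n1)
    k = np.arange(kmin, kmax + 1)
    logw = -(
        gammaln(k + 1)
        + gammaln(n1 - k + 1)
        + gammaln(K - k + 1)
        + gammaln(n2 - K + k + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w_obs = w[a - kmin]
    p = float(w[w <= w_obs * (1.0 + 1e-7)].sum() / w.sum())
    return min(1.0, p)


@lru_cache(maxsize=2_000_000)
def _fisher_canonical(a: int, b: int, c: int, d: int) -> float:
    n1, n2 = a + b, c + d
    K = a + c
    N = n1 + n2
    if min(n1, n2, K, N - K) == 0:
        return 1.0
    if N > _EXACT_LIMIT:
        return _fisher_large_impl(a, b, c, d)
    kmin, kmax = max(0, K - n2), min(K, n1)
    comb = math.comb
    M = N - K
    weights = [comb(K, k) * comb(M, n1 - k) for k in range(kmin, kmax + 1)]
    w_obs = weights[a - kmin]
    num = 0
    for w in weights:
        if w <= w_obs:
            num += w
    return min(1.0, num / comb(N, n1))


def fisher_exact_two_sided(meth_t: int, unmeth_t: int, meth_c: int, unmeth_c: int) -> float:
    """Two-sided Fisher exact p on [[meth_t, unmeth_t], [meth_c, unmeth_c]].

    Any zero margin returns p = 1 (a single admissible table).  The p-value
    is invariant under row swap, column swap and transposition; the table is
    canonicalised accordingly before the cached kernel is consulted.
    """
    a, b, c, d = int(meth_t), int(unmeth_t), int(meth_c), int(unmeth_c)
    if min(a, b, c, d) < 0:
        raise ValueError("negative count in 2x2 table")
    variants = (
        (a, b, c, d),
        (c, d, a, b),
        (b, a, d, c),
        (d, c, b, a),
        (a, c, b, d),
        (b, d, a, c),
        (c, a, d, b),
        (d, b, c, a),
    )
    return _fisher_canonical(*min(variants))


def fisher_bin_test(bin_row) -> float:
    """Fisher p for one pooled bin (row with meth_t/unmeth_t/meth_c/unmeth_c)."""
    return fisher_exact_two_sided(
        bin_row["meth_t"], bin_row["unmeth_t"], bin_row["meth_c"], bin_row["unmeth_c"]
    )


def _fisher_vector(meth_t, unmeth_t, meth_c, unmeth_c) -> np.ndarray:
    return np.array(
        [
            fisher_exact_two_sided(a, b, c, d)
            for a, b, c, d in zip(meth_t, unmeth_t, meth_c, unmeth_c)
        ]
    )


# ---------------------------------------------------------------------------
# tiling and pooling
# ---------------------------------------------------------------------------


def _paired_sites(
    treatment: MethylomeTable, control: MethylomeTable, min_depth: int | None = None
) -> pd.DataFrame:
    """Inner join of the two samples' sites on (chrom, pos, strand)."""
    t = treatment.sites
    c = control.sites
    if min_depth is not None:
        t = t[t["total_reads"] >= min_depth]
        c = c[c["total_reads"] >= min_depth]
    merged = t.merge(
        c[["chrom", "pos", "strand", "meth_reads", "total_reads"]],
        on=["chrom", "pos", "strand"],
        how="inner",
        suffixes=("_t", "_c"),
    )
    return merged


def tile_and_pool(
    treatment: MethylomeTable,
    control: MethylomeTable,
    context: str,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Pool per-site counts into genome-tiling ``bin_size`` windows.

    Only sites observed in both samples contribute.  Bin start is
    ``floor(pos / bin_size) * bin_size``.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    t_chr = set(treatment.sites["chrom"].unique())
    c_chr = set(control.sites["chrom"].unique())
    if t_chr != c_chr:
        import logging

        logging.getLogger("methtile").warning(
            "chromosome sets differ (%s vs %s); using intersection",
            sorted(t_chr - c_chr),
            sorted(c_chr - t_chr),
        )
    paired = _paired_sites(treatment, control)
    paired = paired[paired["context"] == context]
    if len(paired) == 0:
        return _empty_bins(context, bin_size)
    paired = paired.assign(start=(paired["pos"] // bin_size) * bin_size)
    grouped = paired.groupby(["chrom", "start"], observed=True)
    bins = grouped.agg(
        n_cytosines=("pos", "size"),
        meth_t=("meth_reads_t", "sum"),
        total_t=("total_reads_t", "sum"),
        meth_c=("meth_reads_c", "sum"),
        total_c=("total_reads_c", "sum"),
    ).reset_index()
    bins["end"] = bins["start"] + bin_size
    bins["context"] = context
    bins["unmeth_t"] = bins["total_t"] - bins["meth_t"]
    bins["unmeth_c"] = bins["total_c"] - bins["meth_c"]
    bins["level_t"] = bins["meth_t"] / bins["total_t"]
    bins["level_c"] = bins["meth_c"] / bins["total_c"]
    bins["mean_depth_t"] = bins["total_t"] / bins["n_cytosines"]
    bins["mean_depth_c"] = bins["total_c"] / bins["n_cytosines"]
    cols = [
        "chrom",
        "start",
        "end",
        "context",
        "n_cytosines",
        "meth_t",
        "unmeth_t",
        "meth_c",
        "unmeth_c",
        "level_t",
        "level_c",
        "mean_depth_t",
        "mean_depth_c",
    ]
    return bins[cols].sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def _empty_bins(context: str, bin_size: int) -> pd.DataFrame:
    cols = {
        "chrom": pd.Series(dtype=str),
        "start": pd.Series(dtype=int),
        "end": pd.Series(dtype=int),
        "context": pd.Series(dtype=str),
        "n_cytosines": pd.Series(dtype=int),
        "meth_t": pd.Series(dtype=int),
        "unmeth_t": pd.Series(dtype=int),
        "meth_c": pd.Series(dtype=int),
        "unmeth_c": pd.Series(dtype=int),
        "level_t": pd.Series(dtype=float),
        "level_c": pd.Series(dtype=float),
        "mean_depth_t": pd.Series(dtype=float),
        "mean_depth_c": pd.Series(dtype=float),
    }
    return pd.DataFrame(cols)


def filter_bins(
    bins: pd.DataFrame,
    min_depth: float = DEFAULT_MIN_DEPTH,
    min_cytosines: int = DEFAULT_MIN_CYTOSINES,
) -> pd.DataFrame:
    """Keep bins with mean per-cytosine depth >= min_depth in BOTH samples
    and at least ``min_cytosines`` shared cytosines."""
    keep = (
        (bins["mean_depth_t"] >= min_depth)
        & (bins["mean_depth_c"] >= min_depth)
        & (bins["n_cytosines"] >= min_cytosines)
    )
    return bins[keep].reset_index(drop=True)


def add_bin_pvalues(bins: pd.DataFrame) -> pd.DataFrame:
    """Fisher p-value per bin (column ``p_value``)."""
    out = bins.copy()
    out["p_value"] = _fisher_vector(
        out["meth_t"].to_numpy(),
        out["unmeth_t"].to_numpy(),
        out["meth_c"].to_numpy(),
        out["unmeth_c"].to_numpy(),
    ) if len(out) else np.array([])
    return out


# ---------------------------------------------------------------------------
# DmC calling
# ---------------------------------------------------------------------------


_SITE_COLS = [
    "chrom", "pos", "strand", "context",
    "level_t", "level_c", "p_value", "q_value", "direction",
]


def site_tests(
    treatment: MethylomeTable,
    control: MethylomeTable,
    min_depth: int = 5,
) -> pd.DataFrame:
    """Per-site two-sided Fisher exact tests for all sites assayed
    (>= ``min_depth`` reads) in both samples, with BH q-values within each
    context.  No significance thresholds are applied."""
    paired = _paired_sites(treatment, control, min_depth=min_depth)
    if len(paired) == 0:
        return pd.DataFrame(columns=_SITE_COLS)
    paired = paired.assign(
        level_t=paired["meth_reads_t"] / paired["total_reads_t"],
        level_c=paired["meth_reads_c"] / paired["total_reads_c"],
    )
    paired["p_value"] = _fisher_vector(
        paired["meth_reads_t"].to_numpy(),
        (paired["total_reads_t"] - paired["meth_reads_t"]).to_numpy(),
        paired["meth_reads_c"].to_numpy(),
        (paired["total_reads_c"] - paired["meth_reads_c"]).to_numpy(),
    )
    paired["q_value"] = np.nan
    for ctx, idx in paired.groupby("context", observed=True).groups.items():
        paired.loc[idx, "q_value"] = bh_qvalues(paired.loc[idx, "p_value"].to_numpy())
    paired["direction"] = np.where(paired["level_t"] > paired["level_c"], "hyper", "hypo")
    return (
        paired[_SITE_COLS]
        .sort_values(["chrom", "pos", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )


def call_dmcs(
    treatment: MethylomeTable,
    control: MethylomeTable,
    min_depth: int = 5,
    alpha_q: float = DEFAULT_ALPHA_Q,
    min_diff: float = DEFAULT_MIN_DIFF,
    tests: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Differentially methylated cytosines by per-site Fisher exact test.

    A site is a DmC when its within-context BH q-value is below ``alpha_q``
    and the level difference is at least ``min_diff``.  Returns only the
    DmCs, with direction (hyper: treatment > control).  Precomputed
    :func:`site_tests` output may be passed via ``tests``.
    """
    paired = site_tests(treatment, control, min_depth) if tests is None else tests
    if len(paired) == 0:
        return pd.DataFrame(columns=_SITE_COLS)
    diff = paired["level_t"] - paired["level_c"]
    keep = (paired["q_value"] < alpha_q) & (diff.abs() >= min_diff)
    return paired[keep].reset_index(drop=True)


def supporting_dmcs(
    tests: pd.DataFrame,
    support_alpha: float = 0.05,
    min_diff: float = DEFAULT_MIN_DIFF,
) -> pd.DataFrame:
    """Differential cytosines at raw per-site significance.

    Used by the DMR caller's >=3-cytosine redundancy rule: the supporting
    evidence is counted at raw p < ``support_alpha`` with a level difference
    of at least ``min_diff``; the multiple-testing control of the DMR call
    itself lives at the bin level (bin Fisher q-value), where the region
    test is actually powered.
    """
    diff = tests["level_t"] - tests["level_c"]
    keep = (tests["p_value"] < support_alpha) & (diff.abs() >= min_diff)
    return tests[keep].reset_index(drop=True)


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    if len(pvalues) == 0:
        return np.array([])
    return multipletests(pvalues, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------


def call_dmrs(
    bins: pd.DataFrame,
    dmcs: pd.DataFrame,
    alpha_q: float = DEFAULT_ALPHA_Q,
    min_diff: float = DEFAULT_MIN_DIFF,
    min_fold: float = DEFAULT_MIN_FOLD,
    min_dmcs: int = DEFAULT_MIN_DMCS,
    bin_size: int = DEFAULT_BIN_SIZE,
    fold_epsilon: float = FOLD_EPSILON,
) -> pd.DataFrame:
    """Apply FDR control and effect-size thresholds to tested bins.

    ``bins`` must carry ``p_value`` (from :func:`add_bin_pvalues`) and may
    mix contexts; q-values are computed within each context.  The fold is
    the ratio of the larger to the smaller pooled level, with the smaller
    level floored at ``fold_epsilon``.  A bin is a DMR iff q < ``alpha_q``,
    |level_t - level_c| >= ``min_diff``, fold >= ``min_fold`` and it
    contains at least ``min_dmcs`` DmCs of its context.
    """
    if len(bins) == 0:
        return bins.assign(
            q_value=pd.Series(dtype=float),
            level_diff=pd.Series(dtype=float),
            fold=pd.Series(dtype=float),
            n_dmcs=pd.Series(dtype=int),
            direction=pd.Series(dtype=str),
        )
    if "p_value" not in bins.columns:
        raise ValueError("bins lack p_value; run add_bin_pvalues first")
    out = bins.copy()
    out["q_value"] = np.nan
    for ctx, idx in out.groupby("context", observed=True).groups.items():
        out.loc[idx, "q_value"] = bh_qvalues(out.loc[idx, "p_value"].to_numpy())
    out["level_diff"] = out["level_t"] - out["level_c"]
    lo = np.maximum(np.minimum(out["level_t"], out["level_c"]), fold_epsilon)
    hi = np.maximum(out["level_t"], out["level_c"])
    out["fold"] = hi / lo
    out["n_dmcs"] = _count_dmcs_per_bin(out, dmcs, bin_size)
    keep = (
        (out["q_value"] < alpha_q)
        & (out["level_diff"].abs() >= min_diff)
        & (out["fold"] >= min_fold)
        & (out["n_dmcs"] >= min_dmcs)
    )
    dmrs = out[keep].copy()
    dmrs["direction"] = np.where(dmrs["level_diff"] > 0, "hyper", "hypo")
    return dmrs.sort_values(["chrom", "start", "context"], kind="mergesort").reset_index(drop=True)


def _count_dmcs_per_bin(bins: pd.DataFrame, dmcs: pd.DataFrame, bin_size: int) -> np.ndarray:
    if dmcs is None or len(dmcs) == 0:
        return np.zeros(len(bins), dtype=int)
    d = dmcs.assign(start=(dmcs["pos"] // bin_size) * bin_size)
    counts = (
        d.groupby(["chrom", "start", "context"], observed=True)
        .size()
        .rename("n_dmcs")
        .reset_index()
    )
    merged = bins[["chrom", "start", "context"]].merge(
        counts, on=["chrom", "start", "context"], how="left"
    )
    return merged["n_dmcs"].fillna(0).astype(int).to_numpy()


def detect_dmrs(
    treatment: MethylomeTable,
    control: MethylomeTable,
    contexts: tuple[str, ...] = CONTEXTS,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_depth: float = DEFAULT_MIN_DEPTH,
    min_cytosines: int = DEFAULT_MIN_CYTOSINES,
    min_diff: float = DEFAULT_MIN_DIFF,
    min_fold: float = DEFAULT_MIN_FOLD,
    alpha_q: float = DEFAULT_ALPHA_Q,
    min_dmcs: int = DEFAULT_MIN_DMCS,
    site_min_depth: int = 5,
    support_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full treatment-vs-control DMR scan over the requested contexts.

    The >=``min_dmcs`` redundancy rule is applied against supporting
    differential cytosines at raw per-site p < ``support_alpha`` (see
    :func:`supporting_dmcs`).  Returns ``(dmrs, tested_bins, dmcs)`` where
    ``tested_bins`` is every filtered bin with its p/q values (useful for
    diagnostics and false-discovery accounting) and ``dmcs`` is the
    FDR-controlled per-site DmC set from :func:`call_dmcs`.
    """
    tests = site_tests(treatment, control, min_depth=site_min_depth)
    dmcs = call_dmcs(
        treatment, control, min_depth=site_min_depth, alpha_q=alpha_q,
        min_diff=min_diff, tests=tests,
    )
    support = supporting_dmcs(tests, support_alpha=support_alpha, min_diff=min_diff)
    all_bins = []
    for ctx in contexts:
        bins = tile_and_pool(treatment, control, ctx, bin_size=bin_size)
        bins = filter_bins(bins, min_depth=min_depth, min_cytosines=min_cytosines)
        bins = add_bin_pvalues(bins)
        all_bins.append(bins)
    tested = pd.concat(all_bins, ignore_index=True) if all_bins else _empty_bins("CG", bin_size)
    dmrs = call_dmrs(
        tested,
        support,
        alpha_q=alpha_q,
        min_diff=min_diff,
        min_fold=min_fold,
        min_dmcs=min_dmcs,
        bin_size=bin_size,
    )
    # propagate q/effect columns onto tested bins for reporting
    tested = call_dmr_stats(tested, support, bin_size=bin_size)
    return dmrs, tested, dmcs


def call_dmr_stats(bins: pd.DataFrame, dmcs: pd.DataFrame, bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Annotate tested bins with q-values, effect sizes and DmC counts
    without applying DMR thresholds."""
    if len(bins) == 0:
        return bins
    out = bins.copy()
    out["q_value"] = np.nan
    for ctx, idx in out.groupby("context", observed=True).groups.items():
        out.loc[idx, "q_value"] = bh_qvalues(out.loc[idx, "p_value"].to_numpy())
    out["level_diff"] = out["level_t"] - out["level_c"]
    lo = np.maximum(np.minimum(out["level_t"], out["level_c"]), FOLD_EPSILON)
    out["fold"] = np.maximum(out["level_t"], out["level_c"]) / lo
    out["n_dmcs"] = _count_dmcs_per_bin(out, dmcs, bin_size)
    return out


# ---------------------------------------------------------------------------
# four-way set comparison
# ---------------------------------------------------------------------------


def fourway_partition(dmr_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Membership-class counts for up to four labelled DMR sets.

    Each DMR is keyed e.g. by (chrom, start, end, context).  Returns a dict
    mapping the sorted tuple of set labels containing an element (all 15
    non-empty classes for four sets; empty classes reported as 0) to the
    number of elements with exactly that membership.  Exclusive plus shared
    class counts sum to the union size.
    """
    if not 1 <= len(dmr_sets) <= 4:
        raise ValueError("fourway_partition takes 1-4 labelled sets")
    from itertools import combinations

    labels = sorted(dmr_sets)
    union = set().union(*dmr_sets.values())
    classes: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            classes[combo] = 0
    for item in union:
        member = tuple(lbl for lbl in labels if item in dmr_sets[lbl])
        classes[member] += 1
    return classes
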