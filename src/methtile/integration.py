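"""Methylome-transcriptome integration.

Joins DMR calls (annotated to gene territories) with differential gene
expression, profiles methylation density across gene bodies and flanks by
expression stratum, and computes relative expression from qPCR cycle
thresholds by the 2^-ddCt method.

The differential-expression call is a deliberately simple surrogate for an
upstream RNA-seq pipeline: a Welch two-sample t-test on log2(FPKM + 1)
replicate values, combined with a two-fold change threshold on the
(pseudocounted) condition means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import LABELS, PROMOTER_LABELS
from .formats_io import CONTEXTS, GeneModel, MethylomeTable

FPKM_PSEUDOCOUNT = 1.0

CATEGORIES = ("hypo_up", "hypo_down", "hyper_up", "hyper_down", "uncorrelated")

#: order in which a gene's DMRs decide its methylation direction
#: (promoter territories first, then 5' UTR, gene body, 3' UTR, downstream)
INTEGRATION_PRECEDENCE = (
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


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def classify_deg(
    fpkm_treatment: np.ndarray,
    fpkm_control: np.ndarray,
    min_fold: float = 2.0,
    alpha: float = 0.05,
) -> tuple[str, float, float]:
    """DEG call for one gene: returns (deg_class, log2fc, p_value).

    log2fc = log2((mean_t + 1) / (mean_c + 1)); p from a Welch t-test on
    log2(FPKM + 1) replicates.  'up' iff log2fc >= log2(min_fold) and
    p < alpha; 'down' symmetric; otherwise 'ns'.
    """
    t = np.asarray(fpkm_treatment, dtype=float)
    c = np.asarray(fpkm_control, dtype=float)
    if len(t) < 2 or len(c) < 2:
        raise ValueError("classify_deg needs >= 2 replicates per condition")
    log2fc = float(np.log2((t.mean() + FPKM_PSEUDOCOUNT) / (c.mean() + FPKM_PSEUDOCOUNT)))
    if t.max() == 0 and c.max() == 0:
        return "ns", 0.0, 1.0
    lt, lc = np.log2(t + 1.0), np.log2(c + 1.0)
    if np.allclose(lt.var(), 0) and np.allclose(lc.var(), 0) and np.isclose(lt.mean(), lc.mean()):
        p = 1.0
    else:
        p = float(stats.ttest_ind(lt, lc, equal_var=False).pvalue)
        if np.isnan(p):
            p = 1.0
    thr = np.log2(min_fold)
    if p < alpha and log2fc >= thr:
        return "up", log2fc, p
    if p < alpha and log2fc <= -thr:
        return "down", log2fc, p
    return "ns", log2fc, p


def classify_deg_table(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    min_fold: float = 2.0,
    alpha: float = 0.05,
    treatment: str = "stress",
    control: str = "control",
) -> pd.DataFrame:
    """Per-gene DEG classification of an FPKM matrix.

    ``expr`` is genes x samples; ``design`` maps sample -> condition.
    """
    t_samples = design.loc[design["condition"] == treatment, "sample"].tolist()
    c_samples = design.loc[design["condition"] == control, "sample"].tolist()
    missing = [s for s in t_samples + c_samples if s not in expr.columns]
    if missing:
        raise ValueError(f"samples missing from expression matrix: {missing}")
    rows = []
    for gene_id, row in expr.iterrows():
        cls, lfc, p = classify_deg(
            row[t_samples].to_numpy(), row[c_samples].to_numpy(), min_fold, alpha
        )
        rows.append((gene_id, lfc, p, cls))
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_value", "deg_class"])


# ---------------------------------------------------------------------------
# methylation density by expression stratum
# ---------------------------------------------------------------------------


def methylation_by_expression_strata(
    methylome: MethylomeTable | pd.DataFrame,
    genes: Sequence[GeneModel],
    expression: pd.Series,
    n_strata: int = 4,
    body_bins: int = 40,
    flank: int = 2000,
    flank_bins: int = 20,
) -> pd.DataFrame:
    """Metagene methylation profile per expression stratum and context.

    Genes are partitioned into ``n_strata`` quantile strata of
    ``expression`` (stratum 0 = lowest).  For every gene the upstream
    flank, the positionally scaled gene body and the downstream flank are
    divided into ``flank_bins`` + ``body_bins`` + ``flank_bins`` windows
    oriented 5'->3', and site read counts are pooled per
    (stratum, context, window).  Values are pooled levels in [0, 1]; empty
    windows are NaN.
    """
    sites = methylome.sites if isinstance(methylome, MethylomeTable) else methylome
    gene_ids = [g.gene_id for g in genes if g.gene_id in expression.index]
    if not gene_ids:
        raise ValueError("no gene has an expression value")
    expr = expression.loc[gene_ids]
    # quantile strata on ranks (ties broken by order for determinism)
    ranks = expr.rank(method="first")
    strata = pd.qcut(ranks, n_strata, labels=False)

    n_windows = 2 * flank_bins + body_bins
    flank_w = flank / flank_bins
    meth = np.zeros((n_strata, len(CONTEXTS), n_windows))
    total = np.zeros_like(meth)
    ctx_idx = {c: i for i, c in enumerate(CONTEXTS)}

    by_chrom = {c: g.sort_values("pos") for c, g in sites.groupby("chrom", observed=True)}
    for gene in genes:
        if gene.gene_id not in strata.index:
            continue
        stratum = int(strata.loc[gene.gene_id])
        chrom_sites = by_chrom.get(gene.chrom)
        if chrom_sites is None:
            continue
        lo, hi = gene.start - flank, gene.end + flank
        pos = chrom_sites["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, [lo, hi])
        if i1 <= i0:
            continue
        sub = chrom_sites.iloc[i0:i1]
        p = sub["pos"].to_numpy()
        # orient 5'->3'
        rel = (p - lo) if gene.strand == "+" else (hi - 1 - p)
        glen = gene.length
        win = np.empty(len(rel), dtype=int)
        up = rel < flank
        body = (rel >= flank) & (rel < flank + glen)
        down = rel >= flank + glen
        win[up] = (rel[up] / flank_w).astype(int)
        win[body] = flank_bins + ((rel[body] - flank) * body_bins // glen).astype(int)
        win[down] = (
            flank_bins + body_bins + ((rel[down] - flank - glen) / flank_w).astype(int)
        )
        win = np.clip(win, 0, n_windows - 1)
        for ctx in CONTEXTS:
            m = (sub["context"] == ctx).to_numpy()
            if not m.any():
                continue
            np.add.at(meth[stratum, ctx_idx[ctx]], win[m], sub["meth_reads"].to_numpy()[m])
            np.add.at(total[stratum, ctx_idx[ctx]], win[m], sub["total_reads"].to_numpy()[m])

    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    index = pd.MultiIndex.from_product(
        [range(n_strata), CONTEXTS], names=["stratum", "context"]
    )
    return pd.DataFrame(level.reshape(n_strata * len(CONTEXTS), n_windows), index=index)


# ---------------------------------------------------------------------------
# DMR x DEG correlation
# ---------------------------------------------------------------------------


def correlate_dmr_deg(
    dmr_territories: pd.DataFrame,
    degs: pd.DataFrame,
    n_background_genes: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join annotated DMRs with DEG calls into direction categories.

    ``dmr_territories`` needs gene_id / context / label / direction columns
    (distal-intergenic DMRs, having no gene, are ignored); ``degs`` needs
    gene_id / deg_class.  One record is produced per (gene, context) pair
    with at least one DMR; when a gene carries both hyper and hypo DMRs in
    a context, the DMR in the highest-precedence territory (promoter tiers
    first) decides the methylation direction.  Returns (records, summary)
    where the summary holds counts and percentages per category; the
    percentage denominator is ``n_background_genes`` (default: the number
    of genes in ``degs``).
    """
    deg_map = degs.set_index("gene_id")["deg_class"]
    usable = dmr_territories.dropna(subset=["gene_id"])
    usable = usable[usable["label"] != "distal_intergenic"]
    records = []
    prec = {lbl: i for i, lbl in enumerate(INTEGRATION_PRECEDENCE)}
    for (gene_id, context), grp in usable.groupby(["gene_id", "context"], observed=True):
        grp = grp.assign(_rank=grp["label"].map(prec))
        top = grp.sort_values(["_rank", "chrom", "start"]).iloc[0]
        meth_dir = top["direction"]
        deg_class = deg_map.get(gene_id, "ns")
        if deg_class == "up":
            category = f"{meth_dir}_up"
        elif deg_class == "down":
            category = f"{meth_dir}_down"
        else:
            category = "uncorrelated"
        records.append(
            (gene_id, context, top["label"], meth_dir, deg_class, category)
        )
    rec = pd.DataFrame(
        records,
        columns=["gene_id", "context", "label", "meth_direction", "deg_class", "category"],
    )
    denom = n_background_genes if n_background_genes is not None else len(degs)
    counts = (
        rec["category"].value_counts().reindex(CATEGORIES, fill_value=0)
        if len(rec)
        else pd.Series(0, index=list(CATEGORIES))
    )
    summary = pd.DataFrame(
        {
            "category": counts.index,
            "n": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / denom if denom else np.nan,
        }
    )
    return rec, summary


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DdCtMeasurement:
    """Replicate Ct values for target and reference genes in two conditions."""

    ct_target_treated: tuple[float, ...]
    ct_reference_treated: tuple[float, ...]
    ct_target_control: tuple[float, ...]
    ct_reference_control: tuple[float, ...]

    def __post_init__(self):
        for name in (
            "ct_target_treated",
            "ct_reference_treated",
            "ct_target_control",
            "ct_reference_control",
        ):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size == 0:
                raise ValueError(f"{name} is empty")
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                raise ValueError(f"{name} must be positive and finite")


def relative_expression_ddct(m: DdCtMeasurement) -> float:
    """Fold change by the 2^-ddCt method.

    dCt = mean(Ct_target) - mean(Ct_reference) per condition;
    ddCt = dCt_treated - dCt_control; result = 2^(-ddCt).
    """
    dct_treated = float(np.mean(m.ct_target_treated)) - float(np.mean(m.ct_reference_treated))
    dct_control = float(np.mean(m.ct_target_control)) - float(np.mean(m.ct_reference_control))
    return float(2.0 ** (-(dct_treated - dct_control)))
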