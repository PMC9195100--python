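"""Synthetic WGBS study generator with known ground truth.

Generates a small reference genome (nuclear chromosomes plus an
unmethylated organelle surrogate), gene models, a paired control/stress
methylome with spiked differentially methylated regions, and an expression
matrix in which a chosen fraction of genes responds to promoter methylation
changes.  The generator emulates the statistical structure of a
high-coverage (~25x) plant bisulfite experiment: negative-binomial
per-site coverage, beta-mixture baseline methylation levels with
CG > CHG > CHH, a small bisulfite non-conversion rate acting on
unmethylated cytosines, and localized treatment-vs-control shifts.

Read-count model per site: with true level ``L`` and non-conversion rate
``r`` (methylated cytosines assumed fully protected from conversion), each
of the ``n`` reads covering the site reports methylation with probability
``L + (1 - L) * r``.

Within a spiked region the baseline level is redrawn uniformly on the
window for which both the baseline and the shifted level stay inside
[0.05, 0.95], so the realized per-site shift equals the requested delta
instead of being eroded by clipping (a hypomethylation spike on a
near-zero CHH baseline would otherwise be unobservable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import scan_cytosines
from .formats_io import (
    CONTEXTS,
    GeneModel,
    MethylomeTable,
    write_cgmap,
    write_expression,
    write_fasta,
    write_gff3,
    write_tsv,
)

log = logging.getLogger("methtile")

ORGANELLE_CHROM = "chrC"

# candidate spike bins must be testable in every context
_MIN_SPIKE_CYTOSINES = {"CG": 3, "CHG": 3, "CHH": 6}


@dataclass(frozen=True)
class BetaMixture:
    """Mixture of beta distributions for baseline methylation levels."""

    components: tuple[tuple[float, float, float], ...]  # (weight, a, b)

    def __post_init__(self):
        w = sum(c[0] for c in self.components)
        if not np.isclose(w, 1.0):
            raise ValueError(f"mixture weights sum to {w}, not 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        weights = np.array([c[0] for c in self.components])
        comp = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n)
        for i, (_, a, b) in enumerate(self.components):
            m = comp == i
            out[m] = rng.beta(a, b, m.sum())
        return out


#: default per-context baselines: CG bimodal (mass near 0 and near 0.9),
#: CHG mostly low with an intermediate component, CHH low.  Calibrated so
#: the binomial caller reports a genome-wide 5-mC fraction in the 13-17%
#: range observed for rice.
DEFAULT_CONTEXT_LEVELS: dict[str, BetaMixture] = {
    "CG": BetaMixture(((0.70, 0.3, 15.0), (0.30, 8.0, 1.5))),
    "CHG": BetaMixture(((0.88, 0.3, 15.0), (0.12, 5.0, 4.0))),
    "CHH": BetaMixture(((1.0, 0.5, 22.0),)),
}


@dataclass(frozen=True)
class SpikedRegion:
    """A localized treatment-vs-control methylation shift."""

    chrom: str
    start: int
    end: int
    context: str  # CG / CHG / CHH / 'all'
    delta: float  # signed level shift applied to treatment

    def __post_init__(self):
        if self.context not in CONTEXTS and self.context != "all":
            raise ValueError(f"bad spike context {self.context!r}")
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError("|delta| must be <= 1")


@dataclass
class SimulationParams:
    """Study conditions for the synthetic WGBS experiment."""

    genome_length: int = 1_000_000  # total nuclear bases
    gc_fraction: float = 0.44
    n_chroms: int = 3  # includes one organelle surrogate
    organelle_length: int = 30_000
    n_genes: int = 100
    gene_span: tuple[int, int] = (1_000, 4_000)
    coverage_mean: float = 25.0
    coverage_dispersion: float = 5.0  # negative-binomial size parameter
    context_level_params: dict[str, BetaMixture] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_LEVELS)
    )
    nonconversion_rate: float = 0.005
    spiked_dmrs: list[SpikedRegion] | None = None  # None -> planned automatically
    n_background_spikes: int = 60
    spike_delta: float = 0.4
    promoter_spike_delta: float = -0.6
    linked_gene_fraction: float = 0.3
    expression_effect_slope: float = 2.0
    expression_noise_sd: float = 0.25  # log2 scale
    expression_base_mean: float = 4.0  # log2 FPKM
    expression_base_sd: float = 1.5
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("gc_fraction", "nonconversion_rate", "linked_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10,000")
        if self.n_chroms < 2:
            raise ValueError("need at least one nuclear and one organelle chromosome")
        if self.gene_span[0] > self.gene_span[1] or self.gene_span[0] < 300:
            raise ValueError("bad gene_span")


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream scoring."""

    true_site_levels: pd.DataFrame  # chrom,pos,strand,context,level_control,level_treatment
    true_dmr_regions: pd.DataFrame  # chrom,start,end,context,delta,direction
    linked_genes: pd.DataFrame  # gene_id,promoter_delta,expected_log2fc


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

_GENE_MARGIN = 3_200  # keeps promoters/downstream of neighbours apart
_MIN_EXON, _MIN_INTRON = 80, 60


def simulate_genome(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus non-overlapping gene models.

    Nuclear chromosomes are named chr1..chrN; the organelle surrogate
    (:data:`ORGANELLE_CHROM`) carries no genes and is simulated fully
    unmethylated downstream.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n_nuclear = params.n_chroms - 1
    chrom_len = params.genome_length // n_nuclear
    gc, at = params.gc_fraction / 2, (1 - params.gc_fraction) / 2
    bases = np.array(["A", "C", "G", "T"])
    probs = [at, gc, gc, at]

    genome: dict[str, str] = {}
    for i in range(n_nuclear):
        seq = rng.choice(bases, size=chrom_len, p=probs)
        genome[f"chr{i + 1}"] = "".join(seq)
    genome[ORGANELLE_CHROM] = "".join(
        rng.choice(bases, size=params.organelle_length, p=probs)
    )

    # distribute genes round-robin over nuclear chromosomes
    per_chrom = [params.n_genes // n_nuclear] * n_nuclear
    for i in range(params.n_genes % n_nuclear):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gi = 0
    for ci, k in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        lo, hi = params.gene_span
        lengths = rng.integers(lo, hi + 1, size=k)
        needed = int(lengths.sum()) + (k + 1) * _GENE_MARGIN
        if needed > chrom_len:
            raise ValueError(
                f"cannot pack {k} genes of span {params.gene_span} into "
                f"{chrom_len} bases of {chrom}"
            )
        slack = chrom_len - needed
        cuts = np.sort(rng.uniform(0, slack, size=k)).astype(int)
        cursor = np.concatenate([[0], np.cumsum(lengths[:-1])]) + (
            np.arange(k) + 1
        ) * _GENE_MARGIN
        starts = cuts + cursor
        for j in range(k):
            start, length = int(starts[j]), int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                _make_gene(f"gene{gi:04d}", chrom, strand, start, start + length, rng)
            )
            gi += 1
    return genome, genes


def _make_gene(
    gene_id: str, chrom: str, strand: str, start: int, end: int, rng: np.random.Generator
) -> GeneModel:
    length = end - start
    max_exons = max(1, min(4, (length - _MIN_EXON) // (_MIN_EXON + _MIN_INTRON) + 1))
    n_exons = int(rng.integers(1, max_exons + 1))
    n_seg = 2 * n_exons - 1
    mins = np.array([_MIN_EXON if i % 2 == 0 else _MIN_INTRON for i in range(n_seg)])
    extra = length - mins.sum()
    w = rng.dirichlet(np.ones(n_seg))
    sizes = mins + np.floor(w * extra).astype(int)
    sizes[-1] += length - sizes.sum()
    edges = start + np.concatenate([[0], np.cumsum(sizes)])
    exons = [(int(edges[i]), int(edges[i + 1])) for i in range(0, n_seg, 2)]

    # short UTRs inside the terminal exons (transcription direction)
    first = exons[0] if strand == "+" else exons[-1]
    last = exons[-1] if strand == "+" else exons[0]
    utr5: list[tuple[int, int]] = []
    utr3: list[tuple[int, int]] = []
    if first[1] - first[0] >= 3 * 120:
        utr5 = [(first[0], first[0] + 120)] if strand == "+" else [(first[1] - 120, first[1])]
    if last[1] - last[0] >= 3 * 120:
        utr3 = [(last[1] - 120, last[1])] if strand == "+" else [(last[0], last[0] + 120)]
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        exons=exons,
        utr5=utr5,
        utr3=utr3,
    )


# ---------------------------------------------------------------------------
# spike planning
# ---------------------------------------------------------------------------


def plan_spikes(
    genome: dict[str, str],
    genes: list[GeneModel],
    params: SimulationParams,
    rng: np.random.Generator,
    cytosines: pd.DataFrame | None = None,
    bin_size: int = 100,
) -> tuple[list[SpikedRegion], pd.DataFrame]:
    """Choose spiked regions: promoter spikes for expression-linked genes
    plus background spikes in bins well away from any gene.

    All spikes are 100-bp bin-aligned and restricted to bins containing
    enough cytosines of every context to be testable downstream.  Returns
    (spikes, linked_genes table).
    """
    scan = scan_cytosines(genome) if cytosines is None else cytosines
    nuc = scan[scan["chrom"] != ORGANELLE_CHROM]
    counts = (
        nuc.assign(bin=(nuc["pos"] // bin_size) * bin_size)
        .groupby(["chrom", "bin", "context"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(CONTEXTS), fill_value=0)
    )
    ok = counts.index[
        (counts["CG"] >= _MIN_SPIKE_CYTOSINES["CG"])
        & (counts["CHG"] >= _MIN_SPIKE_CYTOSINES["CHG"])
        & (counts["CHH"] >= _MIN_SPIKE_CYTOSINES["CHH"])
    ]
    candidates = set(ok)

    spikes: list[SpikedRegion] = []
    used: set[tuple[str, int]] = set()

    # promoter spikes for linked genes
    n_linked = int(round(params.linked_gene_fraction * len(genes)))
    order = rng.permutation(len(genes))
    linked_rows = []
    for idx in order:
        if len(linked_rows) >= n_linked:
            break
        gene = genes[idx]
        tss = gene.tss
        # a bin fully inside the proximal (<1 kb) promoter window
        if gene.strand == "+":
            trial_bins = [((tss - off) // bin_size) * bin_size for off in (300, 500, 700)]
            window = range(max(0, tss - 1000), tss - bin_size + 1)
        else:
            trial_bins = [((tss + off) // bin_size) * bin_size for off in (300, 500, 700)]
            window = range(tss + 1, tss + 1000 - bin_size + 1)
        chosen = None
        for b in trial_bins:
            if b in window and (gene.chrom, b) in candidates and (gene.chrom, b) not in used:
                chosen = b
                break
        if chosen is None:
            continue
        used.add((gene.chrom, chosen))
        spikes.append(
            SpikedRegion(gene.chrom, chosen, chosen + bin_size, "all", params.promoter_spike_delta)
        )
        linked_rows.append(
            (
                gene.gene_id,
                params.promoter_spike_delta,
                -params.expression_effect_slope * params.promoter_spike_delta,
            )
        )
    if len(linked_rows) < n_linked:
        log.warning(
            "only %d/%d linked genes received a promoter spike", len(linked_rows), n_linked
        )

    # background spikes away from genes (no expression linkage)
    blocked: set[tuple[str, int]] = set(used)
    for gene in genes:
        lo = (max(0, gene.start - _GENE_MARGIN) // bin_size) * bin_size
        hi = gene.end + _GENE_MARGIN
        for b in range(lo, hi, bin_size):
            blocked.add((gene.chrom, b))
    free = sorted(b for b in candidates if b not in blocked)
    if len(free) < params.n_background_spikes:
        raise ValueError(
            f"only {len(free)} intergenic candidate bins for "
            f"{params.n_background_spikes} background spikes"
        )
    pick = rng.choice(len(free), size=params.n_background_spikes, replace=False)
    for j, i in enumerate(sorted(pick)):
        chrom, b = free[i]
        delta = params.spike_delta if j % 2 == 0 else -params.spike_delta
        spikes.append(SpikedRegion(chrom, b, b + bin_size, "all", delta))

    linked = pd.DataFrame(
        linked_rows, columns=["gene_id", "promoter_delta", "expected_log2fc"]
    )
    return spikes, linked


# ---------------------------------------------------------------------------
# methylome pair
# ---------------------------------------------------------------------------


def simulate_methylome_pair(
    genome: dict[str, str],
    genes: list[GeneModel],
    params: SimulationParams,
    spikes: list[SpikedRegion] | None = None,
    linked_genes: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    cytosines: pd.DataFrame | None = None,
) -> tuple[MethylomeTable, MethylomeTable, GroundTruth]:
    """Paired control/stress methylomes with spiked DMRs and ground truth.

    Every classifiable reference cytosine on both strands receives a true
    level from its context's beta mixture (CpG sites strand-symmetric),
    negative-binomial coverage and binomial methylated-read counts under the
    non-conversion error model.  The organelle chromosome is fully
    unmethylated.  Sites drawing zero coverage in a sample are absent from
    that sample's table.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    if spikes is None:
        spikes = params.spiked_dmrs or []
    scan = scan_cytosines(genome) if cytosines is None else cytosines
    n = len(scan)
    chrom_arr = scan["chrom"].to_numpy()
    pos_arr = scan["pos"].to_numpy()
    ctx_arr = scan["context"].to_numpy()

    # baseline levels (CG strand-symmetric: minus-strand CpG copies its partner)
    level = np.empty(n)
    for ctx in CONTEXTS:
        m = ctx_arr == ctx
        level[m] = params.context_level_params[ctx].sample(rng, int(m.sum()))
    is_cg_minus = (ctx_arr == "CG") & (scan["strand"].to_numpy() == "-")
    if is_cg_minus.any():
        key = pd.MultiIndex.from_arrays([chrom_arr, pos_arr])
        plus_cg = (ctx_arr == "CG") & (scan["strand"].to_numpy() == "+")
        partner = pd.Series(level[plus_cg], index=key[plus_cg])
        want = pd.MultiIndex.from_arrays(
            [chrom_arr[is_cg_minus], pos_arr[is_cg_minus] - 1]
        )
        mapped = partner.reindex(want).to_numpy()
        found = ~np.isnan(mapped)
        idx = np.flatnonzero(is_cg_minus)[found]
        level[idx] = mapped[found]

    organelle = chrom_arr == ORGANELLE_CHROM
    level[organelle] = 0.0

    control_level = level.copy()
    treat_level = level.copy()
    for s in spikes:
        if s.chrom not in genome:
            raise ValueError(f"spiked region on unknown chromosome {s.chrom}")
        if s.start < 0 or s.end > len(genome[s.chrom]):
            raise ValueError(f"spiked region {s.chrom}:{s.start}-{s.end} outside genome")
        mask = (chrom_arr == s.chrom) & (pos_arr >= s.start) & (pos_arr < s.end) & ~organelle
        if s.context != "all":
            mask &= ctx_arr == s.context
        k = int(mask.sum())
        if k == 0:
            raise ValueError(
                f"spiked region {s.chrom}:{s.start}-{s.end} contains no "
                f"{s.context} cytosine"
            )
        lo = max(0.05, 0.05 - s.delta)
        hi = min(0.95, 0.95 - s.delta)
        # one draw per CpG dyad (keyed by the plus-strand partner position)
        # keeps CG strand symmetry inside the spiked region
        idx = np.flatnonzero(mask)
        strand_arr = scan["strand"].to_numpy()
        key = pos_arr[idx].copy()
        key[(ctx_arr[idx] == "CG") & (strand_arr[idx] == "-")] -= 1
        uniq, inv = np.unique(key, return_inverse=True)
        base = rng.uniform(lo, hi, size=len(uniq))[inv]
        control_level[mask] = base
        treat_level[mask] = base + s.delta
    control_level = np.clip(control_level, 0.0, 1.0)
    treat_level = np.clip(treat_level, 0.0, 1.0)

    r = params.nonconversion_rate
    size = params.coverage_dispersion
    p_nb = size / (size + params.coverage_mean)

    def draw(true_level: np.ndarray, sample_id: str, condition: str) -> MethylomeTable:
        cov = rng.negative_binomial(size, p_nb, size=n)
        p_obs = true_level + (1.0 - true_level) * r
        meth = rng.binomial(cov, p_obs)
        keep = cov > 0
        sites = pd.DataFrame(
            {
                "chrom": chrom_arr[keep],
                "pos": pos_arr[keep],
                "strand": scan["strand"].to_numpy()[keep],
                "context": ctx_arr[keep],
                "dinuc": scan["dinuc"].to_numpy()[keep],
                "meth_reads": meth[keep],
                "total_reads": cov[keep],
            }
        )
        sites["level"] = sites["meth_reads"] / sites["total_reads"]
        return MethylomeTable(
            sample_id=sample_id,
            sites=sites,
            condition=condition,
            nonconversion_rate=r,
        )

    control = draw(control_level, "control", "control")
    treatment = draw(treat_level, "treatment", "stress")

    truth_sites = scan[["chrom", "pos", "strand", "context"]].copy()
    truth_sites["level_control"] = control_level
    truth_sites["level_treatment"] = treat_level
    regions = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "context": s.context,
                "delta": s.delta,
                "direction": "hyper" if s.delta > 0 else "hypo",
            }
            for s in spikes
        ],
        columns=["chrom", "start", "end", "context", "delta", "direction"],
    )
    truth = GroundTruth(
        true_site_levels=truth_sites,
        true_dmr_regions=regions,
        linked_genes=linked_genes
        if linked_genes is not None
        else pd.DataFrame(columns=["gene_id", "promoter_delta", "expected_log2fc"]),
    )
    return control, treatment, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: list[GeneModel],
    ground_truth: GroundTruth,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM matrix (genes x replicates x conditions) plus design table.

    Log2 abundances carry log-normal replicate noise; a linked gene's
    stress-condition mean is shifted by
    ``-expression_effect_slope * promoter_delta`` on the log2 scale, so
    promoter hypomethylation (negative delta) raises expression.
    """
    if params.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 for downstream tests")
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    gene_ids = [g.gene_id for g in genes]
    base = rng.normal(params.expression_base_mean, params.expression_base_sd, len(gene_ids))
    delta = (
        pd.to_numeric(
            ground_truth.linked_genes.set_index("gene_id")["promoter_delta"],
            errors="coerce",
        )
        .reindex(gene_ids)
        .fillna(0.0)
        .to_numpy()
    )
    shift = -params.expression_effect_slope * delta
    cols = {}
    for i in range(params.n_replicates):
        cols[f"control_{i + 1}"] = 2.0 ** (
            base + rng.normal(0, params.expression_noise_sd, len(gene_ids))
        )
    for i in range(params.n_replicates):
        cols[f"stress_{i + 1}"] = 2.0 ** (
            base + shift + rng.normal(0, params.expression_noise_sd, len(gene_ids))
        )
    expr = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    design = pd.DataFrame(
        {
            "sample": list(cols),
            "condition": ["control"] * params.n_replicates + ["stress"] * params.n_replicates,
            "replicate": list(range(1, params.n_replicates + 1)) * 2,
        }
    )
    return expr, design


# ---------------------------------------------------------------------------
# one-call orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    params: SimulationParams
    genome: dict[str, str]
    genes: list[GeneModel]
    control: MethylomeTable
    treatment: MethylomeTable
    truth: GroundTruth
    expression: pd.DataFrame
    design: pd.DataFrame


def simulate_dataset(
    params: SimulationParams, outdir: str | Path | None = None
) -> SimulatedDataset:
    """Run the full generator; optionally write all artefacts to ``outdir``.

    Identical parameters (including seed) produce byte-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    genome, genes = simulate_genome(params, rng)
    scan = scan_cytosines(genome)
    if params.spiked_dmrs is None:
        spikes, linked = plan_spikes(genome, genes, params, rng, cytosines=scan)
    else:
        spikes, linked = params.spiked_dmrs, pd.DataFrame(
            columns=["gene_id", "promoter_delta", "expected_log2fc"]
        )
    control, treatment, truth = simulate_methylome_pair(
        genome, genes, params, spikes=spikes, linked_genes=linked, rng=rng, cytosines=scan
    )
    expr, design = simulate_expression(genes, truth, params, rng)
    ds = SimulatedDataset(params, genome, genes, control, treatment, truth, expr, design)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fa")
        write_gff3(genes, out / "genes.gff3")
        write_cgmap(control, out / "control.cgmap.tsv")
        write_cgmap(treatment, out / "treatment.cgmap.tsv")
        write_expression(expr, out / "expression.tsv")
        design.to_csv(out / "design.tsv", sep="\t", index=False)
        _write_truth_bed(truth.true_dmr_regions, out / "true_dmrs.bed")
        write_tsv(truth.true_dmr_regions, out / "true_dmrs.tsv")
        write_tsv(truth.linked_genes, out / "linked_genes.tsv")
    return ds


def _write_truth_bed(regions: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# ground-truth spiked regions (0-based half-open)\n")
        for row in regions.itertuples():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.context}:{row.direction}"
                f"\t0\t.\n"
            )


# ---------------------------------------------------------------------------
# scoring against ground truth
# ---------------------------------------------------------------------------


def evaluate_dmr_calls(
    dmrs: pd.DataFrame,
    truth_regions: pd.DataFrame,
    tested_bins: pd.DataFrame,
    bin_size: int = 100,
) -> dict[str, float]:
    """Recall and empirical false-discovery proportion of a DMR call set.

    A spiked bin counts as recovered when any context yields a DMR on that
    bin with the spiked direction; recall is computed over spiked bins that
    passed the coverage/cytosine filters in at least one context.  The
    false-discovery proportion is the fraction of DMR calls on bins that
    were never spiked.
    """
    truth_bins: dict[tuple[str, int], str] = {}
    for row in truth_regions.itertuples():
        for b in range(int(row.start) // bin_size * bin_size, int(row.end), bin_size):
            truth_bins[(row.chrom, b)] = row.direction

    tested_keys = set(zip(tested_bins["chrom"], tested_bins["start"]))
    passing = [k for k in truth_bins if k in tested_keys]

    call_keys = list(zip(dmrs["chrom"], dmrs["start"], dmrs["direction"]))
    recovered = {
        (c, s)
        for c, s, d in call_keys
        if (c, s) in truth_bins and truth_bins[(c, s)] == d
    }
    n_calls = len(dmrs)
    false_calls = sum(1 for c, s, _ in call_keys if (c, s) not in truth_bins)
    return {
        "n_spiked_bins": len(truth_bins),
        "n_spiked_bins_passing_filters": len(passing),
        "n_recovered": len(recovered & set(passing)),
        "recall": len(recovered & set(passing)) / len(passing) if passing else float("nan"),
        "n_calls": n_calls,
        "n_false_calls": false_calls,
        "false_discovery_proportion": false_calls / n_calls if n_calls else 0.0,
    }


# ---------------------------------------------------------------------------
# canonical study conditions
# ---------------------------------------------------------------------------


def dmr_benchmark_params(seed: int = 0) -> SimulationParams:
    """1 Mb genome, ~25x coverage, non-conversion 0.005, 100 spiked
    100-bp regions at |delta| = 0.4 and no expression linkage."""
    return SimulationParams(
        genome_length=1_000_000,
        n_background_spikes=100,
        spike_delta=0.4,
        linked_gene_fraction=0.0,
        seed=seed,
    )


def integration_benchmark_params(seed: int = 0) -> SimulationParams:
    """Smaller genome with 30% of genes expression-linked to promoter
    methylation (slope 2), used for the methylome-transcriptome join."""
    return SimulationParams(
        genome_length=600_000,
        n_genes=60,
        n_background_spikes=20,
        linked_gene_fraction=0.3,
        expression_effect_slope=2.0,
        seed=seed,
    )
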