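import numpy as np
import pandas as pd
import pytest

import methtile as mt
from methtile.synthetic import ORGANELLE_CHROM

from oracles import scan_contexts_oracle


def _params(**kw):
    base = dict(genome_length=60_000, n_genes=4, n_background_spikes=5, seed=3)
    base.update(kw)
    return mt.SimulationParams(**base)


class TestSimulateGenome:
    def test_gene_models_within_bounds(self):
        params = _params()
        genome, genes = mt.simulate_genome(params)
        assert len(genes) == params.n_genes
        for g in genes:
            assert 0 <= g.start < g.end <= len(genome[g.chrom])
            assert params.gene_span[0] <= g.length <= params.gene_span[1]
            exons = sorted(g.exons)
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                assert e1 <= s2  # non-overlapping, intron between
            if len(g.exons) > 1:
                assert len(g.introns) == len(g.exons) - 1

    def test_organelle_has_no_genes(self):
        _, genes = mt.simulate_genome(_params())
        assert all(g.chrom != ORGANELLE_CHROM for g in genes)

    def test_same_seed_identical_outputs(self, tmp_path):
        for run in ("a", "b"):
            mt.simulate_dataset(_params(), outdir=tmp_path / run)
        for name in ("genome.fa", "genes.gff3", "control.cgmap.tsv",
                     "treatment.cgmap.tsv", "expression.tsv", "true_dmrs.bed"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes(), name

    def test_pure_gc_composition(self):
        genome, _ = mt.simulate_genome(_params(gc_fraction=1.0, n_genes=2))
        assert set("".join(genome.values())) <= {"G", "C"}

    def test_impossible_packing_raises(self):
        with pytest.raises(ValueError):
            mt.simulate_genome(_params(genome_length=12_000, n_genes=30))

    def test_context_composition_matches_oracle(self):
        genome, _ = mt.simulate_genome(_params())
        scanned = mt.scan_cytosines(genome)
        got = set(zip(scanned["chrom"], scanned["pos"], scanned["strand"], scanned["context"]))
        assert got == scan_contexts_oracle(genome)


@pytest.fixture(scope="module")
def pair():
    params = _params(genome_length=120_000, n_genes=6, n_background_spikes=10, seed=9)
    genome, genes = mt.simulate_genome(params)
    rng = np.random.default_rng(params.seed)
    spikes, linked = mt.plan_spikes(genome, genes, params, rng)
    control, treatment, truth = mt.simulate_methylome_pair(
        genome, genes, params, spikes=spikes, linked_genes=linked, rng=rng
    )
    return params, control, treatment, truth


class TestMethylomePair:
    def test_organelle_methylated_fraction_near_nonconversion(self, pair):
        params, control, _, _ = pair
        org = control.restrict(ORGANELLE_CHROM).sites
        assert len(org) > 5000
        total = org["total_reads"].sum()
        rate = org["meth_reads"].sum() / total
        se = np.sqrt(params.nonconversion_rate * (1 - params.nonconversion_rate) / total)
        assert abs(rate - params.nonconversion_rate) <= 3 * se

    def test_mean_coverage_close_to_target(self, pair):
        params, control, _, _ = pair
        # zero-coverage sites are absent; compare against the truncated mean
        p_zero = (params.coverage_dispersion / (params.coverage_dispersion + params.coverage_mean)) ** params.coverage_dispersion
        expected = params.coverage_mean / (1 - p_zero)
        obs = control.sites["total_reads"].mean()
        assert len(control) > 10_000
        assert abs(obs - expected) / expected < 0.05

    def test_spiked_regions_show_requested_shift(self, pair):
        params, control, treatment, truth = pair
        t = treatment.sites.set_index(["chrom", "pos", "strand"])
        c = control.sites.set_index(["chrom", "pos", "strand"])
        for row in truth.true_dmr_regions.itertuples():
            tt = treatment.sites.query(
                "chrom == @row.chrom and @row.start <= pos < @row.end"
            )
            cc = control.sites.query(
                "chrom == @row.chrom and @row.start <= pos < @row.end"
            )
            diff = (
                tt["meth_reads"].sum() / tt["total_reads"].sum()
                - cc["meth_reads"].sum() / cc["total_reads"].sum()
            )
            assert diff == pytest.approx(row.delta, abs=0.12)

    def test_cpg_levels_strand_symmetric(self, pair):
        _, _, _, truth = pair
        lv = truth.true_site_levels

        def in_spike(chrom, pos):
            for r in truth.true_dmr_regions.itertuples():
                if r.chrom == chrom and r.start <= pos < r.end:
                    return True
            return False

        cg = lv[lv["context"] == "CG"]
        plus = cg[cg["strand"] == "+"].set_index(["chrom", "pos"])["level_control"]
        minus = cg[cg["strand"] == "-"]
        # dyads straddling a spike boundary are redrawn on one side only
        same_side = np.array(
            [
                in_spike(c, p) == in_spike(c, p - 1)
                for c, p in zip(minus["chrom"], minus["pos"])
            ]
        )
        minus = minus[same_side]
        partner = pd.MultiIndex.from_arrays([minus["chrom"], minus["pos"] - 1])
        matched = plus.reindex(partner).to_numpy()
        have = ~np.isnan(matched)
        assert have.sum() > 1000
        np.testing.assert_allclose(matched[have], minus["level_control"].to_numpy()[have])

    def test_observed_levels_unbiased_after_error_model(self, pair):
        params, control, _, truth = pair
        merged = control.sites.merge(
            truth.true_site_levels, on=["chrom", "pos", "strand"], how="inner"
        )
        merged = merged[merged["total_reads"] >= 5]
        assert len(merged) > 10_000
        x = (
            merged["level_control"]
            + (1 - merged["level_control"]) * params.nonconversion_rate
        ).to_numpy()
        y = (merged["meth_reads"] / merged["total_reads"]).to_numpy()
        slope = float(np.sum(x * y) / np.sum(x * x))
        assert slope == pytest.approx(1.0, abs=0.01)

    def test_null_bins_centered_at_zero(self, pair):
        params, control, treatment, truth = pair
        bins = mt.tile_and_pool(treatment, control, "CG")
        bins = mt.filter_bins(bins)
        spiked = set()
        for row in truth.true_dmr_regions.itertuples():
            for b in range(row.start // 100 * 100, row.end, 100):
                spiked.add((row.chrom, b))
        keys = list(zip(bins["chrom"], bins["start"]))
        null = bins[[k not in spiked for k in keys]]
        diffs = (null["level_t"] - null["level_c"]).to_numpy()
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs))

    def test_spike_outside_genome_rejected(self):
        params = _params()
        genome, genes = mt.simulate_genome(params)
        bad = [mt.SpikedRegion("chr1", 10**7, 10**7 + 100, "all", 0.4)]
        with pytest.raises(ValueError):
            mt.simulate_methylome_pair(genome, genes, params, spikes=bad)

    def test_every_spiked_region_contains_its_context(self, pair):
        _, _, _, truth = pair
        lv = truth.true_site_levels
        for row in truth.true_dmr_regions.itertuples():
            inside = lv.query("chrom == @row.chrom and @row.start <= pos < @row.end")
            if row.context != "all":
                inside = inside[inside["context"] == row.context]
            assert len(inside) >= 1


class TestExpression:
    def _truth_with_link(self, genes, delta):
        linked = pd.DataFrame(
            {"gene_id": [genes[0].gene_id], "promoter_delta": [delta],
             "expected_log2fc": [-2.0 * delta]}
        )
        return mt.GroundTruth(
            true_site_levels=pd.DataFrame(),
            true_dmr_regions=pd.DataFrame(),
            linked_genes=linked,
        )

    def test_linked_gene_expected_log2fc(self):
        params = _params(n_replicates=400, expression_effect_slope=2.0)
        _, genes = mt.simulate_genome(params)
        truth = self._truth_with_link(genes, delta=-0.5)
        expr, design = mt.simulate_expression(genes, truth, params)
        t_cols = design.loc[design["condition"] == "stress", "sample"]
        c_cols = design.loc[design["condition"] == "control", "sample"]
        lfc = np.log2(expr[t_cols].mean(axis=1)) - np.log2(expr[c_cols].mean(axis=1))
        assert lfc[genes[0].gene_id] == pytest.approx(1.0, abs=0.1)
        assert lfc[genes[1].gene_id] == pytest.approx(0.0, abs=0.1)

    def test_determinism(self):
        params = _params()
        _, genes = mt.simulate_genome(params)
        truth = self._truth_with_link(genes, -0.5)
        e1, _ = mt.simulate_expression(genes, truth, params)
        e2, _ = mt.simulate_expression(genes, truth, params)
        pd.testing.assert_frame_equal(e1, e2)

    def test_single_replicate_rejected(self):
        params = _params(n_replicates=1)
        _, genes = mt.simulate_genome(_params())
        truth = self._truth_with_link(genes, -0.5)
        with pytest.raises(ValueError):
            mt.simulate_expression(genes, truth, params)
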