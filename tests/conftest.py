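import numpy as np
import pandas as pd
import pytest

import methtile as mt


def make_methylome(rows, sample_id="s", condition="control", **meta):
    """Build a MethylomeTable from (chrom,pos,strand,context,meth,total) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]
    )
    df["dinuc"] = "CG"
    df["level"] = df["meth_reads"] / df["total_reads"]
    return mt.MethylomeTable(sample_id=sample_id, sites=df, condition=condition, **meta)


@pytest.fixture(scope="session")
def small_dataset():
    """200 kb synthetic study shared by unit tests (fast)."""
    params = mt.SimulationParams(
        genome_length=200_000, n_genes=12, n_background_spikes=20, seed=11
    )
    return mt.simulate_dataset(params)


@pytest.fixture(scope="session")
def toy_genes():
    """A handful of hand-placed genes on both strands for territory tests."""
    return [
        mt.GeneModel(
            gene_id="gPlus",
            chrom="chr1",
            strand="+",
            start=5000,
            end=8000,
            exons=[(5000, 5600), (6200, 7100), (7600, 8000)],
            utr5=[(5000, 5150)],
            utr3=[(7800, 8000)],
        ),
        mt.GeneModel(
            gene_id="gMinus",
            chrom="chr1",
            strand="-",
            start=15000,
            end=17000,
            exons=[(15000, 15800), (16300, 17000)],
            utr5=[(16850, 17000)],
            utr3=[(15000, 15120)],
        ),
        mt.GeneModel(
            gene_id="gSingle",
            chrom="chr2",
            strand="+",
            start=1000,
            end=2200,
        ),
    ]
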