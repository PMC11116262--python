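import numpy as np
import pandas as pd
import pytest

import methdiffscan as mds
from methdiffscan.io import ANNOTATION_COLUMNS


@pytest.fixture(scope="session")
def tiny_annotation():
    """Three transcripts on two chromosomes, both strands, multi-exon."""
    rows = [
        dict(transcript_id="txA", gene_id="gA", chrom="chr1", strand="+",
             tx_start=5000, tx_end=8000,
             exons=((5000, 5999), (7000, 8000)), tss=5000),
        dict(transcript_id="txB", gene_id="gB", chrom="chr1", strand="-",
             tx_start=20000, tx_end=26000,
             exons=((20000, 21000), (25000, 26000)), tss=26000),
        dict(transcript_id="txC", gene_id="gC", chrom="chr2", strand="+",
             tx_start=1000, tx_end=3000, exons=((1000, 3000),), tss=1000),
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


@pytest.fixture(scope="session")
def sim_dataset():
    """Small simulated dataset with planted single-site effects."""
    cfg = mds.SimConfig(
        seed=11, n_chroms=2, chrom_length_bp=400_000, n_transcripts=40,
        mean_coverage=30,
        planted_dmc=(
            [mds.PlantedSite(40.0, "hyper") for _ in range(15)]
            + [mds.PlantedSite(40.0, "hypo") for _ in range(15)]
        ),
    )
    annotation = mds.simulate_annotation(cfg)
    samples, truth = mds.simulate_counts(cfg, annotation)
    return cfg, annotation, samples, truth


@pytest.fixture(scope="session")
def united(sim_dataset):
    cfg, annotation, samples, truth = sim_dataset
    design = mds.GroupDesign(
        {n: ("control" if n.startswith("control") else "case") for n in samples},
        reference="control",
    )
    return mds.unite(samples, design, min_coverage=10)


def make_design(n_per_group=2):
    groups = {f"ctrl_{i}": "control" for i in range(n_per_group)}
    groups.update({f"case_{i}": "case" for i in range(n_per_group)})
    return mds.GroupDesign(groups, reference="control")


def matrix_from_counts(meth, cov, design, chrom="chr1"):
    """Build a UnitedMatrix from raw (n_loci, n_samples) count arrays."""
    meth = np.asarray(meth)
    cov = np.asarray(cov)
    loci = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(1, len(meth) + 1) * 100,
        "end": np.arange(1, len(meth) + 1) * 100,
    })
    return mds.UnitedMatrix(loci=loci, meth=meth, cov=cov,
                            samples=design.samples, design=design)
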