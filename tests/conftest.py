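"""Shared fixtures: tiny hand-written inputs and the heavy simulation batteries."""
from __future__ import annotations

import numpy as np
import pytest

from enhburden.io_formats import GenotypeMatrix, SampleTable, VariantRecord
from enhburden.simulate import (
    PlantedSet,
    SimConfig,
    null_pvalue_battery,
    power_battery,
)

SEED = 20260903


@pytest.fixture
def tiny_vcf(tmp_path):
    """3 samples; 2 biallelic autosomal sites, 1 multi-allelic, 1 chrX site."""
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=chr1>",
            "##contig=<ID=chrX>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3",
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1",
            "chr1\t200\t.\tC\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0",
            "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t./.\t0/0\t0/1",
            "chrX\t400\t.\tT\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0",
        ]
    )
    path = tmp_path / "tiny.vcf"
    path.write_text(text + "\n")
    return path


def make_matrix(dosages, status=None, chrom="chr1", start_pos=1000):
    """Build a GenotypeMatrix (+ SampleTable when status given) from a 2-D list."""
    dos = np.asarray(dosages, dtype=float)
    n, m = dos.shape
    variants = [
        VariantRecord(chrom=chrom, pos=start_pos + 10 * j, ref="A", alt="G")
        for j in range(m)
    ]
    gm = GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n)], variants=variants, dosages=dos
    )
    if status is None:
        return gm
    st = SampleTable(sample_ids=list(gm.sample_ids), status=np.asarray(status, float))
    return gm, st


@pytest.fixture(scope="session")
def null_skato_battery():
    """2,000 null replicates (500+500 samples, 20 variants/set).

    Shared by the calibration acceptance criterion, the uniformity K-S
    property and the lambda-GC check; computed once per session.
    """
    cfg = SimConfig(
        seed=SEED, n_case=500, n_ctrl=500, variants_per_set=20, weight_a2=25.0
    )
    return null_pvalue_battery(cfg, 2000)


@pytest.fixture(scope="session")
def planted_skato_battery():
    """500 replicates with carrier risk ratio 5 at 1% case carrier frequency."""
    cfg = SimConfig(
        seed=SEED + 1,
        n_case=2000,
        n_ctrl=2000,
        variants_per_set=20,
        weight_a2=25.0,
        planted_sets=[PlantedSet("SET0000", 5.0, 0.01)],
    )
    return power_battery(cfg, 500, alpha=1e-3)
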