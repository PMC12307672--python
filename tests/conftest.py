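"""Shared fixtures: small planted-signal panels generated at test time."""

import numpy as np
import pytest

from forestscan.forest import ForestConfig, run_ensemble
from forestscan.matrix import impute_for_model
from forestscan.sim import SimGenotypeSpec, simulate_genotypes

CRAFTED_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=sc1,length=10000>
##contig=<ID=sc2,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
sc1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
sc1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t./.\t1|0\t0/0
sc1\t300\t.\tG\tA,C\t.\tPASS\t.\tGT\t1/2\t0/2\t2/2
sc2\t50\t.\tT\tC\t.\tPASS\t.\tGT\t1/1\t0/.\t0/0
"""

#: dosage matrix the crafted VCF encodes to with biallelic_only=True
#: (columns sorted by coordinate: sc1:100, sc1:200, sc2:50)
CRAFTED_EXPECTED_BIALLELIC = np.array(
    [
        [0, -1, 2],
        [1, 1, -1],
        [2, 0, 0],
    ],
    dtype=np.int8,
)


@pytest.fixture
def crafted_vcf(tmp_path):
    path = tmp_path / "crafted.vcf"
    path.write_text(CRAFTED_VCF)
    return path


@pytest.fixture(scope="session")
def planted():
    """Small two-group panel with 3 planted causal blocks."""
    spec = SimGenotypeSpec(
        n_samples_per_group={"wild": 30, "cultivated": 30},
        n_variants=2000,
        scaffolds=[("sc1", 500_000), ("sc2", 500_000)],
        n_causal_loci=3,
        causal_block_size=5,
        causal_freq_pair=(0.05, 0.9),
        ld_copy_prob=0.5,
        missing_rate=0.02,
        seed=7,
    )
    matrix, labels, truth = simulate_genotypes(spec)
    return spec, matrix, labels, truth


@pytest.fixture(scope="session")
def small_ensemble(planted):
    """A cheap ensemble over the planted panel, shared across tests."""
    spec, matrix, labels, truth = planted
    config = ForestConfig(n_models=4, n_trees=50, feature_fraction=0.05, base_seed=11)
    ensemble = run_ensemble(impute_for_model(matrix), labels, config)
    return config, ensemble
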