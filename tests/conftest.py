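"""Shared fixtures: the published nine-region catalogue and small synthetic builds."""

import pytest

from pandmr import PlantedDMR, build_manifest_with_runs, generate_beta_cohorts

# Published pan-cancer DMR catalogue used as the golden surface:
# (chrom, n_dms, printed density per bp at 5 decimals, start, end, length)
GOLDEN_REGIONS = [
    ("chr1", 12, 0.01875, 25130211, 25130851, 640),
    ("chr2", 13, 0.00386, 53940358, 53943729, 3371),
    ("chr5", 10, 0.00388, 140777418, 140779995, 2577),
    ("chr5", 10, 0.00965, 140733599, 140734635, 1036),
    ("chr6", 15, 0.02717, 31804202, 31804754, 552),
    ("chr6", 19, 0.03442, 29629141, 29629693, 552),
    ("chr6", 21, 0.03443, 30202939, 30203549, 610),
    ("chr7", 13, 0.01207, 27150841, 27151918, 1077),
    ("chr7", 10, 0.04717, 27150584, 27150796, 212),
]

# the two coordinately close chr7 regions and their published merge
CHR7_PAIR = [GOLDEN_REGIONS[8], GOLDEN_REGIONS[7]]
CHR7_MERGED = ("chr7", 23, 27150584, 27151918, 1334)

GOLDEN_CHROMS = ("chr1", "chr2", "chr5", "chr6", "chr7")


def golden_planted(delta_beta=0.3):
    return [
        PlantedDMR(chrom, start, end, n, delta_beta)
        for chrom, n, _dens, start, end, _len in GOLDEN_REGIONS
    ]


@pytest.fixture(scope="session")
def planted_build():
    """One hypermethylated 12-probe run on a small manifest, 3 cohorts of 40/40."""
    run = PlantedDMR("chr1", 100_000, 100_640, 12, 0.3)
    manifest = build_manifest_with_runs([run], 400, ["chr1", "chr2"], 500, seed=11)
    cohorts = generate_beta_cohorts(
        manifest, n_cohorts=3, n_normal=40, n_tumor=40, planted=[run], seed=12
    )
    return run, manifest, cohorts
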