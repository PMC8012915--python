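"""Generator contracts: determinism, value ranges, planted effects, PSD validation."""

import numpy as np
import pandas as pd
import pytest

from pandmr import (
    PlantedDMR,
    ValidationError,
    build_manifest_with_runs,
    generate_beta_cohorts,
    generate_expression_cohorts,
    generate_manifest,
)
from pandmr.simulate import DEFAULT_BLOCKS, HOXA_GENES


class TestGenerateManifest:
    def test_single_probe(self):
        manifest = generate_manifest(1, ["chr1"], 500, seed=0)
        assert len(manifest) == 1

    def test_same_seed_identical(self):
        a = generate_manifest(200, ["chr1", "chr2"], 300, seed=42)
        b = generate_manifest(200, ["chr1", "chr2"], 300, seed=42)
        assert a.to_frame().equals(b.to_frame())

    def test_positions_strictly_increasing_per_chromosome(self):
        manifest = generate_manifest(1000, ["chr1", "chr2"], 200, seed=3)
        frame = manifest.to_frame()
        for _, sub in frame.groupby("chrom"):
            pos = sub["pos"].to_numpy()
            assert (np.diff(pos) > 0).all()

    def test_mean_spacing_close_to_requested(self):
        manifest = generate_manifest(5000, ["chr1"], 400, seed=4)
        gaps = np.diff(manifest.to_frame()["pos"].to_numpy())
        assert gaps.mean() == pytest.approx(400, rel=0.1)

    @pytest.mark.parametrize("kwargs", [
        {"n_probes": 0, "chroms": ["chr1"], "mean_spacing_bp": 10},
        {"n_probes": 5, "chroms": ["chr1"], "mean_spacing_bp": 0},
        {"n_probes": 5, "chroms": [], "mean_spacing_bp": 10},
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValidationError):
            generate_manifest(**kwargs)


class TestPlantedDMR:
    @pytest.mark.parametrize("kwargs", [
        {"start": 100, "end": 100},            # empty span
        {"n_probes": 1},                        # too few probes
        {"n_probes": 300},                      # probes do not fit
        {"delta_beta": 1.0},                    # shift at domain boundary
        {"affected_cohort_fraction": 0.0},      # no affected cohort
    ])
    def test_invariants_rejected(self, kwargs):
        base = dict(chrom="chr1", start=100, end=200, n_probes=5, delta_beta=0.3)
        base.update(kwargs)
        with pytest.raises(ValidationError):
            PlantedDMR(**base)


class TestBuildManifestWithRuns:
    def test_runs_are_contiguous_with_exact_endpoints(self):
        runs = [
            PlantedDMR("chr1", 50_000, 50_600, 12, 0.3),
            PlantedDMR("chr1", 80_000, 80_300, 10, 0.3),
        ]
        manifest = build_manifest_with_runs(runs, 300, ["chr1"], 500, seed=5)
        for run in runs:
            probes = manifest.probes_in_span(run.chrom, run.start, run.end)
            assert len(probes) == run.n_probes
            assert probes["pos"].iloc[0] == run.start
            assert probes["pos"].iloc[-1] == run.end

    def test_runs_separated_by_background(self):
        # without intervening probes two same-chromosome runs would fuse
        runs = [
            PlantedDMR("chr1", 50_000, 50_600, 12, 0.3),
            PlantedDMR("chr1", 90_000, 90_300, 10, 0.3),
        ]
        manifest = build_manifest_with_runs(runs, 0, ["chr1"], 500, seed=6)
        between = manifest.probes_in_span("chr1", 50_601, 89_999)
        assert len(between) > 0


class TestGenerateBetaCohorts:
    def test_values_in_unit_interval_and_deterministic(self, planted_build):
        run, manifest, cohorts = planted_build
        again = generate_beta_cohorts(
            manifest, n_cohorts=3, n_normal=40, n_tumor=40, planted=[run], seed=12
        )
        for name, (normal, tumor) in cohorts.cohorts.items():
            for matrix in (normal, tumor):
                values = matrix.to_numpy()
                assert (values > 0).all() and (values < 1).all()
            assert normal.equals(again.cohorts[name][0])
            assert tumor.equals(again.cohorts[name][1])

    def test_null_groups_share_distribution(self):
        from scipy import stats

        from pandmr.sitestats import adjust_fdr

        manifest = generate_manifest(500, ["chr1"], 500, seed=21)
        cohorts = generate_beta_cohorts(manifest, 1, 60, 60, [], seed=22)
        normal, tumor = cohorts.cohorts["cohort01"]
        p = stats.ttest_ind(
            tumor.to_numpy(), normal.to_numpy(), axis=1, equal_var=False
        ).pvalue
        q = adjust_fdr(p)
        assert (q >= 0.01).mean() >= 0.99

    def test_planted_delta_recovered(self, planted_build):
        run, manifest, cohorts = planted_build
        probes = manifest.probes_in_span(run.chrom, run.start, run.end)["probe_id"]
        deltas = [
            (tumor.loc[probes].mean(axis=1) - normal.loc[probes].mean(axis=1)).mean()
            for normal, tumor in cohorts.cohorts.values()
        ]
        assert np.mean(deltas) == pytest.approx(0.3, abs=0.03)

    def test_partial_cohort_fraction(self):
        run = PlantedDMR("chr1", 100_000, 100_640, 12, 0.3, affected_cohort_fraction=0.5)
        manifest = build_manifest_with_runs([run], 100, ["chr1"], 500, seed=31)
        cohorts = generate_beta_cohorts(manifest, 4, 30, 30, [run], seed=32)
        probes = manifest.probes_in_span(run.chrom, run.start, run.end)["probe_id"]
        shifted = sum(
            (tumor.loc[probes].mean(axis=1) - normal.loc[probes].mean(axis=1)).mean() > 0.15
            for normal, tumor in cohorts.cohorts.values()
        )
        assert shifted == 2  # ceil(0.5 * 4)

    def test_planted_region_off_manifest_rejected(self):
        manifest = generate_manifest(50, ["chr1"], 500, seed=41)
        orphan = PlantedDMR("chrX", 1000, 2000, 5, 0.3)
        with pytest.raises(ValidationError, match="planted run"):
            generate_beta_cohorts(manifest, 1, 5, 5, [orphan], seed=42)


class TestGenerateExpressionCohorts:
    def test_independence_null(self):
        expr = generate_expression_cohorts(
            n_normal=200, n_tumor=200, r_within_normal=0.0,
            r_within_tumor=0.0, r_between=0.0, seed=51,
        )
        matrix = expr.cohorts["cohort01"]["normal"]
        corr = np.corrcoef(matrix.to_numpy())
        off = corr[~np.eye(len(corr), dtype=bool)]
        # per-entry sampling sd is 1/sqrt(n); 4 sd bounds the family
        # maximum over the 110 off-diagonal entries
        assert np.abs(off).max() < 4 / np.sqrt(200)
        assert np.abs(off).mean() < 2 / np.sqrt(200)

    def test_near_degenerate_correlation(self):
        expr = generate_expression_cohorts(
            genes=["g1", "g2"], block_assignment={"g1": "A", "g2": "A"},
            n_normal=200, n_tumor=200, r_within_normal=0.99,
            r_within_tumor=0.99, r_between=0.0, seed=52,
        )
        matrix = expr.cohorts["cohort01"]["normal"].to_numpy()
        assert np.corrcoef(matrix)[0, 1] > 0.9

    def test_block_contrast_parameter_recovery(self):
        from pandmr import block_contrast, correlation_matrix

        expr = generate_expression_cohorts(
            n_normal=200, n_tumor=200, r_within_normal=0.8,
            r_within_tumor=0.2, r_between=0.1, seed=53,
        )
        corr = correlation_matrix(expr.cohorts["cohort01"]["normal"])
        contrast = block_contrast(corr, expr.block_assignment)
        assert contrast.contrast == pytest.approx(0.7, abs=0.1)

    def test_non_psd_target_rejected(self):
        with pytest.raises(ValidationError, match="positive semi-definite"):
            generate_expression_cohorts(
                genes=["g1", "g2", "g3"],
                block_assignment={g: "A" for g in ["g1", "g2", "g3"]},
                n_normal=10, n_tumor=10,
                r_within_normal=-0.9, r_within_tumor=0.0, r_between=0.0,
                seed=54,
            )

    def test_distal_gene_coupled_in_tumor_only(self):
        expr = generate_expression_cohorts(
            n_normal=300, n_tumor=300, distal_gene="TAX1BP1",
            distal_gene_r_tumor=0.3, seed=55,
        )
        assert expr.distal_genes == ["TAX1BP1"]
        for group, expected in (("normal", 0.0), ("tumor", 0.3)):
            matrix = expr.cohorts["cohort01"][group]
            x = matrix.loc["TAX1BP1"].to_numpy()
            rs = [
                np.corrcoef(x, matrix.loc[g].to_numpy())[0, 1] for g in HOXA_GENES
            ]
            assert np.mean(rs) == pytest.approx(expected, abs=0.1)

    def test_default_gene_list_matches_block_split(self):
        assert len(HOXA_GENES) == 11
        assert sum(v == "block1" for v in DEFAULT_BLOCKS.values()) == 6
        assert sum(v == "block2" for v in DEFAULT_BLOCKS.values()) == 5
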