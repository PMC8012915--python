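"""Site-level statistics: Welch test, BH adjustment, AUROC, DMS aggregation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pandmr import (
    ValidationError,
    adjust_fdr,
    auroc,
    pan_cancer_dms,
    per_cohort_stats,
    site_test,
)
from pandmr.core import ProbeManifest
from pandmr.normalize import normalize_cohorts
from pandmr.sitestats import cohort_stats_tables


def welch_oracle(x, y):
    """Independently coded Welch t-test (textbook formulas)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (y.mean() - x.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    from scipy.stats import t as tdist

    return 2 * tdist.sf(abs(t), df)


def bh_oracle(p):
    """Hand-coded step-up rule: q_(i) = min over j>=i of p_(j) * n / j."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


def pairwise_auc_oracle(normal, tumor):
    """Exhaustive comparison over all normal x tumor pairs."""
    wins = sum(
        1.0 if t > n else (0.5 if t == n else 0.0)
        for n, t in itertools.product(normal, tumor)
    )
    return wins / (len(normal) * len(tumor))


class TestSiteTest:
    def test_identical_groups_give_p_one(self):
        assert site_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == pytest.approx(1.0)

    def test_extreme_separation(self):
        rng = np.random.default_rng(0)
        normal = rng.normal(0.1, 0.01, 30)
        tumor = rng.normal(0.6, 0.01, 30)
        assert site_test(normal, tumor) < 1e-6

    def test_matches_independent_welch_formula(self):
        normal, tumor = [0.1, 0.2, 0.3], [0.2, 0.3, 0.4]
        assert site_test(normal, tumor) == pytest.approx(
            welch_oracle(normal, tumor), abs=1e-10
        )

    def test_constant_groups(self):
        assert site_test([0.5, 0.5, 0.5], [0.5, 0.5]) == 1.0
        assert site_test([0.2, 0.2], [0.8, 0.8]) == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            site_test([0.1], [0.2, 0.3])


class TestAdjustFdr:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(adjust_fdr([0.04]), [0.04])

    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.005, 0.5], [0.01, 0.5]),
    ])
    def test_hand_applied_step_up(self, p, expected):
        np.testing.assert_allclose(adjust_fdr(p), expected)

    def test_all_permutations_of_four_match_oracle(self):
        base = [0.001, 0.02, 0.3, 0.9]
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(adjust_fdr(list(perm)), bh_oracle(perm))

    def test_q_never_below_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = adjust_fdr(p)
        assert (q >= p).all()
        assert (q <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="index 1"):
            adjust_fdr([0.5, 1.5])


class TestAuroc:
    @pytest.mark.parametrize("normal,tumor,expected", [
        ([0.1, 0.2], [0.3, 0.4], 1.0),
        ([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], 0.5),
        ([0.1, 0.2, 0.3], [0.25, 0.35], 5 / 6),
    ])
    def test_known_values(self, normal, tumor, expected):
        assert auroc(normal, tumor) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(0, 10), min_size=1, max_size=20),
        st.lists(st.integers(0, 10), min_size=1, max_size=20),
    )
    def test_matches_exhaustive_pair_oracle(self, normal, tumor):
        # integer scores force ties, exercising the half-credit rule
        normal = [v / 10 for v in normal]
        tumor = [v / 10 for v in tumor]
        assert auroc(normal, tumor) == pytest.approx(
            pairwise_auc_oracle(normal, tumor), abs=1e-12
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=15),
        st.lists(st.integers(0, 5), min_size=1, max_size=15),
    )
    def test_antisymmetry(self, a, b):
        assert auroc(a, b) == pytest.approx(1 - auroc(b, a), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            auroc([], [0.1])


class TestPerCohortStats:
    def test_planted_probes_pass_both_gates(self, planted_build):
        run, manifest, cohorts = planted_build
        normalized = normalize_cohorts(cohorts)
        normal, tumor = normalized.cohorts["cohort01"]
        table = per_cohort_stats(normal, tumor, manifest)
        probes = manifest.probes_in_span(run.chrom, run.start, run.end)["probe_id"]
        sub = table.set_index("probe_id").loc[probes]
        assert (sub["q_value"] < 0.01).all()
        assert (sub["auc"] > 0.9).all()

    def test_null_cohort_fdr_controlled(self):
        from pandmr import generate_beta_cohorts, generate_manifest

        hits = []
        for seed in range(20):
            manifest = generate_manifest(200, ["chr1"], 500, seed=seed)
            cohorts = generate_beta_cohorts(manifest, 1, 30, 30, [], seed=500 + seed)
            normal, tumor = cohorts.cohorts["cohort01"]
            table = per_cohort_stats(normal, tumor, manifest)
            hits.append((table["q_value"] < 0.01).mean())
        assert np.mean(hits) <= 0.02

    def test_single_probe_bh_equals_raw_p(self):
        manifest = ProbeManifest.from_records([("cg0", "chr1", 100)])
        rng = np.random.default_rng(3)
        normal = pd.DataFrame(rng.uniform(size=(1, 10)), index=["cg0"],
                              columns=[f"n{i}" for i in range(10)])
        tumor = pd.DataFrame(rng.uniform(size=(1, 10)), index=["cg0"],
                             columns=[f"t{i}" for i in range(10)])
        table = per_cohort_stats(normal, tumor, manifest)
        assert table["q_value"].iloc[0] == pytest.approx(table["p_value"].iloc[0])


def _table(probe_qs_aucs):
    rows = [
        {"probe_id": pid, "chrom": "chr1", "pos": i + 1,
         "p_value": q / 2, "q_value": q, "auc": auc, "delta_beta": auc - 0.5}
        for i, (pid, q, auc) in enumerate(probe_qs_aucs)
    ]
    return pd.DataFrame(rows)


class TestPanCancerDms:
    def test_clear_pass_is_hyper(self):
        tables = [_table([("cg0", 0.001, 0.8)]) for _ in range(3)]
        dms = pan_cancer_dms(tables)
        assert list(dms["probe_id"]) == ["cg0"]
        assert dms["direction"].iloc[0] == "hyper"

    def test_mean_auc_boundary_inclusive(self):
        tables = [_table([("cg0", 0.001, a)]) for a in (0.7, 0.8, 0.75)]
        dms = pan_cancer_dms(tables)
        assert list(dms["probe_id"]) == ["cg0"]  # mean is exactly 0.75

    def test_low_auc_excluded_in_hyper_mode(self):
        tables = [_table([("cg0", 0.001, 0.6)]) for _ in range(3)]
        assert len(pan_cancer_dms(tables)) == 0

    def test_symmetric_mode_admits_hypomethylation(self):
        tables = [_table([("cg0", 0.001, 0.2)]) for _ in range(3)]
        assert len(pan_cancer_dms(tables, direction_mode="hyper")) == 0
        dms = pan_cancer_dms(tables, direction_mode="symmetric")
        assert dms["direction"].iloc[0] == "hypo"

    def test_q_gate_requires_required_fraction(self):
        tables = [
            _table([("cg0", 0.001, 0.9)]),
            _table([("cg0", 0.5, 0.9)]),
        ]
        assert len(pan_cancer_dms(tables, min_significant_fraction=1.0)) == 0
        assert len(pan_cancer_dms(tables, min_significant_fraction=0.5)) == 1

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(7)
        tables = [
            _table([
                (f"cg{i}", float(rng.uniform(0, 0.05)), float(rng.uniform(0.5, 1)))
                for i in range(50)
            ])
            for _ in range(3)
        ]
        loose = set(pan_cancer_dms(tables, q_threshold=0.05, mean_auc_threshold=0.6)["probe_id"])
        tight_q = set(pan_cancer_dms(tables, q_threshold=0.01, mean_auc_threshold=0.6)["probe_id"])
        tight_auc = set(pan_cancer_dms(tables, q_threshold=0.05, mean_auc_threshold=0.8)["probe_id"])
        assert tight_q <= loose and tight_auc <= loose

    def test_empty_tables_rejected(self):
        with pytest.raises(ValidationError):
            pan_cancer_dms([])


def test_type_one_error_under_global_null():
    """No planted effect: the pan-cancer DMS set is empty in >= 95% of replicates."""
    from pandmr import generate_beta_cohorts, generate_manifest

    empty = 0
    n_reps = 20
    for seed in range(n_reps):
        manifest = generate_manifest(200, ["chr1"], 500, seed=seed)
        cohorts = generate_beta_cohorts(manifest, 3, 40, 40, [], seed=900 + seed)
        tables = cohort_stats_tables(normalize_cohorts(cohorts))
        if len(pan_cancer_dms(tables)) == 0:
            empty += 1
    assert empty >= 0.95 * n_reps
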