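"""Confound handling, Spearman/permutation inference and FDR control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from traitnet.association import (
    AnalysisConfig,
    fdr_bh,
    mean_framewise_displacement,
    permutation_p,
    residualize,
    run_full_analysis,
    spearman,
    zscore,
)
from traitnet.graph import compute_metric_table
from traitnet.pipeline import cohort_functional_connectomes


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        assert mean_framewise_displacement(np.zeros((10, 6))) == 0.0

    def test_single_translation_step(self):
        motion = np.zeros((2, 6))
        motion[1, 0] = 1.0
        assert mean_framewise_displacement(motion) == pytest.approx(1.0)

    def test_rotation_arc_length(self):
        motion = np.zeros((2, 6))
        motion[1, 3] = 0.01
        assert mean_framewise_displacement(motion, sphere_radius=50.0) == pytest.approx(0.5)

    def test_wrong_column_count(self):
        with pytest.raises(ValueError, match="6"):
            mean_framewise_displacement(np.zeros((5, 4)))


class TestZscore:
    def test_basic_moments(self):
        z = zscore(np.array([1.0, 2.0, 3.0]))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_and_affine_invariant(self, rng):
        v = rng.standard_normal(40)
        z = zscore(v)
        assert np.allclose(zscore(z), z, atol=1e-10)
        assert np.allclose(zscore(3.2 * v - 7.0), z, atol=1e-10)

    def test_zero_variance_names_measure(self):
        with pytest.raises(ValueError, match="SRS"):
            zscore(np.full(10, 2.0), name="SRS")


class TestResidualize:
    def _confounds(self, rng, n=30):
        return pd.DataFrame(
            rng.standard_normal((n, 5)),
            columns=["age", "sex", "fsiq", "mean_fd", "brain_volume"],
        )

    def test_exact_fit_gives_zero(self, rng):
        conf = self._confounds(rng)
        metric = 2.0 * conf["age"].to_numpy() + 3.0
        assert np.max(np.abs(residualize(metric, conf))) < 1e-10

    def test_orthogonal_centred_vector_unchanged(self, rng):
        conf = self._confounds(rng)
        v = rng.standard_normal(30)
        design = np.column_stack([np.ones(30), conf.to_numpy()])
        v -= design @ np.linalg.lstsq(design, v, rcond=None)[0]  # make orthogonal
        assert np.max(np.abs(residualize(v, conf) - v)) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        conf = self._confounds(rng)
        y = rng.standard_normal(30)
        X = np.column_stack([np.ones(30), conf.to_numpy()])
        expected = y - X @ np.linalg.solve(X.T @ X, X.T @ y)
        assert np.max(np.abs(residualize(y, conf) - expected)) < 1e-10

    def test_rank_deficiency_rejected(self, rng):
        conf = self._confounds(rng)
        conf["brain_volume"] = 2.0 * conf["age"]
        with pytest.raises(ValueError, match="rank"):
            residualize(rng.standard_normal(30), conf)

    def test_subject_mismatch_rejected(self, rng):
        conf = self._confounds(rng)
        metric = pd.Series(rng.standard_normal(30), index=[f"x{i}" for i in range(30)])
        with pytest.raises(ValueError, match="subjects"):
            residualize(metric, conf)


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, -x**3) == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self, rng):
        x = rng.integers(0, 4, 25).astype(float)
        y = rng.integers(0, 4, 25).astype(float)

        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
                i = j + 1
            return ranks

        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_missing_values_dropped_pairwise(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, np.nan])
        assert spearman(x, y) == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            spearman(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


class TestPermutationP:
    def test_extreme_observation_floor(self, rng):
        # a perfect monotone pair at n=12: essentially no permutation beats it
        x = np.arange(12.0)
        y = x + rng.normal(0, 1e-6, 12)
        result = permutation_p(x, y, n_perm=1000, seed=5)
        assert result.p == pytest.approx(1.0 / 1000)

    def test_same_seed_bit_identical(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        a = permutation_p(x, y, n_perm=500, seed=42)
        b = permutation_p(x, y, n_perm=500, seed=42)
        assert a.p == b.p and a.rho_obs == b.rho_obs and a.null_mean == b.null_mean

    def test_invariant_to_zscoring_inputs(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        a = permutation_p(x, y, n_perm=300, seed=1)
        b = permutation_p(zscore(x), zscore(y), n_perm=300, seed=1)
        assert a.p == b.p and a.rho_obs == pytest.approx(b.rho_obs, abs=1e-12)

    def test_nearest_tail_null_law(self, rng):
        """Under the null the nearest-tail p doubles: P(p <= a) ~ 2a on its
        support {1/N .. (N/2+1)/N}; rejection at 0.05 runs near 10%."""
        n_perm, reps = 500, 400
        ps = np.array(
            [
                permutation_p(
                    rng.standard_normal(30), rng.standard_normal(30), n_perm, seed=int(k)
                ).p
                for k in range(reps)
            ]
        )
        assert 0.06 <= np.mean(ps <= 0.05) <= 0.15
        ks = stats.kstest(ps, lambda v: np.clip(2.0 * v - 1.0 / n_perm, 0.0, 1.0))
        assert ks.pvalue > 0.01

    def test_constant_vector_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            permutation_p(np.ones(30), rng.standard_normal(30), 500, seed=0)


class TestFdrBH:
    def test_all_small_pass(self):
        assert fdr_bh(np.full(90, 0.001), q=0.05).all()

    def test_single_above_threshold_fails(self):
        assert not fdr_bh(np.array([0.06]), q=0.05)[0]

    def test_matches_exhaustive_stepup_oracle(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 120))
            p = rng.uniform(1e-6, 1.0, m)
            q = float(rng.uniform(0.01, 0.2))
            assert np.array_equal(fdr_bh(p, q), oracles.bh_stepup(p, q))

    def test_flags_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 90)
        flags = fdr_bh(p, 0.05)
        if flags.any():
            assert p[flags].max() <= p[~flags].min() or not (~flags).any()

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fdr_bh(np.array([]))


@pytest.fixture(scope="module")
def metric_table(small_cohort):
    graphs = cohort_functional_connectomes(small_cohort)
    return compute_metric_table(graphs, scopes=("global", "nodal"))


class TestRunFullAnalysis:

    def test_deterministic_given_seed(self, small_cohort, metric_table):
        cfg = AnalysisConfig(n_perm=200, seed=9)
        beh = small_cohort.behaviour[["SRS", "EQ"]]
        a = run_full_analysis(metric_table, beh, small_cohort.confounds, cfg)
        b = run_full_analysis(metric_table, beh, small_cohort.confounds, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_behaviour_uses_pairwise_subjects(self, small_cohort, metric_table):
        beh = small_cohort.behaviour[["SRS", "EQ"]].copy()
        beh.iloc[0, beh.columns.get_loc("SRS")] = np.nan
        res = run_full_analysis(
            metric_table, beh, small_cohort.confounds, AnalysisConfig(n_perm=200, seed=0)
        )
        n = small_cohort.config.n_subjects
        assert (res[res.behaviour == "SRS"].n_subjects == n - 1).all()
        assert (res[res.behaviour == "EQ"].n_subjects == n).all()

    def test_exempt_pair_uncorrected_and_outside_family(self, small_cohort, metric_table):
        region = metric_table[metric_table.scope == "nodal"].region.iloc[0]
        cfg = AnalysisConfig(n_perm=200, seed=2, exempt=(("SRS", region),))
        res = run_full_analysis(
            metric_table, small_cohort.behaviour[["SRS"]], small_cohort.confounds, cfg
        )
        ex = res[res.exempt]
        assert set(ex.region) == {region}
        assert ex.fdr_pass.isna().all()
        family = res[(res.scope == "nodal") & ~res.exempt & (res.metric == "strength")]
        assert family.fdr_pass.notna().all()

    def test_global_rows_have_no_family(self, small_cohort, metric_table):
        res = run_full_analysis(
            metric_table, small_cohort.behaviour[["SRS"]], small_cohort.confounds,
            AnalysisConfig(n_perm=200, seed=3),
        )
        glob = res[res.scope == "global"]
        assert glob.family_id.isna().all() and glob.fdr_pass.isna().all()

    def test_planted_null_rarely_flagged(self, small_cohort, metric_table):
        """Null behaviours: the flagged fraction of nodal results stays tiny."""
        beh = small_cohort.behaviour[["EQ", "SQ", "RMET"]]  # no planted effect
        res = run_full_analysis(
            metric_table, beh, small_cohort.confounds, AnalysisConfig(n_perm=400, seed=4)
        )
        nodal = res[res.scope == "nodal"]
        assert nodal.fdr_pass.fillna(False).mean() <= 0.02


def test_shipped_a_priori_exemptions_reference_real_names():
    from traitnet.association import A_PRIORI_TPJ_EXEMPTIONS
    from traitnet.atlas import AAL90_LABELS, RIGHT_TPJ_LABEL
    from traitnet.simulate import MEASURE_SCALES

    for beh, region in A_PRIORI_TPJ_EXEMPTIONS:
        assert region == RIGHT_TPJ_LABEL and region in AAL90_LABELS
        assert beh in MEASURE_SCALES
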