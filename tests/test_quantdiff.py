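"""Quantification, NB differential-expression stand-in, BH adjustment and
correspondence analysis, each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from srna_seeker import quantdiff as qd
from srna_seeker import synthdata
from srna_seeker.core import CoverageTrack, SrnaInterval


def track(depths):
    return CoverageTrack("chr", np.asarray(depths, dtype=float), normalized=True)


class TestQuantify:
    def test_constant_depth_returns_that_depth(self):
        t = track([50.0] * 100)
        assert qd.quantify(SrnaInterval("nc1", "chr", 10, 60), t) == 50.0

    def test_mean_of_varying_depths(self):
        t = track([0, 10, 20, 30, 0])
        assert qd.quantify(SrnaInterval("nc1", "chr", 2, 4), t) == 20.0

    def test_zero_coverage_gives_zero(self):
        t = track(np.zeros(100))
        assert qd.quantify(SrnaInterval("nc1", "chr", 1, 100), t) == 0.0

    def test_merged_interval_is_length_weighted_mean_of_parts(self):
        rng = np.random.default_rng(0)
        t = track(rng.uniform(0, 100, size=500))
        a = qd.quantify(SrnaInterval("a", "chr", 10, 109), t)  # 100 nt
        b = qd.quantify(SrnaInterval("b", "chr", 110, 159), t)  # 50 nt
        merged = qd.quantify(SrnaInterval("m", "chr", 10, 159), t)
        assert merged == pytest.approx((100 * a + 50 * b) / 150)


class TestSizeFactors:
    def test_identical_samples_have_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert np.allclose(qd.size_factors(counts), 1.0)

    def test_doubled_sample_has_double_factor(self):
        rng = np.random.default_rng(1)
        base = rng.integers(5, 100, size=50)
        counts = pd.DataFrame({"s1": base, "s2": base, "s3": 2 * base})
        f = qd.size_factors(counts)
        assert f["s3"] / f["s1"] == pytest.approx(2.0)

    def test_invariant_to_srna_reordering(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 200, size=(40, 5)),
                              columns=[f"s{i}" for i in range(5)])
        shuffled = counts.sample(frac=1, random_state=3)
        assert np.allclose(qd.size_factors(counts), qd.size_factors(shuffled))

    def test_no_all_positive_row_rejected(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError):
            qd.size_factors(counts)


class TestNbTest:
    def test_identical_vectors_are_null(self):
        fc, p = qd.nb_test(np.array([10, 12, 11]), np.array([10, 12, 11]), 0.1)
        assert fc == pytest.approx(1.0)
        assert p == 1.0

    def test_all_zero_both_conditions(self):
        fc, p = qd.nb_test(np.zeros(3), np.zeros(3), 0.1)
        assert (fc, p) == (1.0, 1.0)

    def test_label_swap_inverts_fold_change_and_preserves_p(self):
        a = np.array([100, 120, 110])
        b = np.array([310, 290, 305])
        fc1, p1 = qd.nb_test(a, b, 0.05)
        fc2, p2 = qd.nb_test(b, a, 0.05)
        assert fc2 == pytest.approx(1 / fc1)
        assert p2 == pytest.approx(p1)

    def test_strong_difference_is_significant(self):
        fc, p = qd.nb_test(np.array([100, 110, 105]), np.array([400, 420, 390]), 0.02)
        assert fc > 3 and p < 0.01

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            qd.nb_test(np.array([-1, 2, 3]), np.array([1, 2, 3]), 0.1)


class TestBhAdjust:
    @staticmethod
    def oracle(p):
        """Hand-written BH step-up: p_(i) * n/i, cumulative min from the top."""
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        prev = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * n / rank)
            adj[i] = prev
        return adj

    def test_single_p_unchanged(self):
        assert qd.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_textbook_example(self):
        # p_(i) * n / i = (.04, .04, .04, .04) after the cumulative min
        assert qd.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                    min_size=1, max_size=60))
    def test_matches_step_up_oracle(self, ps):
        got = qd.bh_adjust(ps)
        assert np.allclose(got, self.oracle(ps), atol=1e-12)
        assert np.all(got >= np.asarray(ps) - 1e-15)  # adjusted >= raw
        assert np.all(got <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qd.bh_adjust([0.5, 1.5])


class TestDeFilter:
    def frame(self, fc, p_adj):
        return pd.DataFrame({"srna_id": ["x"], "fold_change": [fc],
                             "p": [p_adj], "p_adj": [p_adj]})

    def test_fold_change_threshold_is_strict(self):
        out = qd.de_filter(self.frame(1.5, 0.01))
        assert not out["significant"].iloc[0]

    def test_alpha_is_strict(self):
        out = qd.de_filter(self.frame(2.0, 0.05))
        assert not out["significant"].iloc[0]

    def test_both_pass(self):
        out = qd.de_filter(self.frame(2.0, 0.049))
        assert out["significant"].iloc[0]
        assert out["direction"].iloc[0] == "up"

    def test_down_regulation_direction(self):
        out = qd.de_filter(self.frame(0.4, 0.01))
        assert out["significant"].iloc[0]
        assert out["direction"].iloc[0] == "down"


class TestCorrespondenceAnalysis:
    def test_rank_one_matrix_has_zero_inertia(self):
        r = np.array([1.0, 2.0, 3.0])
        c = np.array([4.0, 1.0, 2.0, 3.0])
        m = pd.DataFrame(np.outer(r, c))
        res = qd.correspondence_analysis(m)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_2x2_total_inertia_equals_chisq_over_total(self):
        m = pd.DataFrame([[30.0, 10.0], [5.0, 25.0]])
        res = qd.correspondence_analysis(m)
        chi2 = stats.chi2_contingency(m.to_numpy(), correction=False)[0]
        assert res.total_inertia == pytest.approx(chi2 / m.to_numpy().sum(), rel=1e-12)

    def test_coordinates_match_direct_svd_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0.5, 10, size=(10, 10))
        m = pd.DataFrame(X)
        res = qd.correspondence_analysis(m)
        # independent direct computation
        total = X.sum()
        P = X / total
        r, c = P.sum(axis=1), P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sv, Vt = np.linalg.svd(S)
        k = res.row_coords.shape[1]
        F = (U[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
        G = (Vt[:k].T * sv[:k]) / np.sqrt(c)[:, None]
        for j in range(k):  # align per-dimension sign freedom
            s = np.sign(np.dot(F[:, j], res.row_coords.iloc[:, j]))
            assert np.allclose(res.row_coords.iloc[:, j], s * F[:, j], atol=1e-8)
            assert np.allclose(res.col_coords.iloc[:, j], s * G[:, j], atol=1e-8)
        assert np.all(np.diff(res.inertia) <= 1e-12)  # nonincreasing

    def test_row_permutation_permutes_coordinates_only(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.uniform(1, 5, size=(6, 4)),
                         index=[f"r{i}" for i in range(6)])
        perm = ["r3", "r0", "r5", "r1", "r4", "r2"]
        a = qd.correspondence_analysis(m)
        b = qd.correspondence_analysis(m.loc[perm])
        assert b.total_inertia == pytest.approx(a.total_inertia)
        assert np.allclose(np.abs(a.row_coords.loc[perm]), np.abs(b.row_coords), atol=1e-10)

    def test_all_zero_row_names_offender(self):
        m = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["good", "bad"])
        with pytest.raises(ValueError, match="bad"):
            qd.correspondence_analysis(m)

    def test_condition_specific_srna_sits_with_its_condition(self, study,
                                                            mapped_study, called_srnas):
        """A salt-only sRNA's CA coordinates are closest (cosine) to salt samples."""
        expr = qd.expression_matrix(called_srnas, mapped_study["norm"])
        cs = study.truth[study.truth.feature_id.str.startswith("planted_nc_cs")]
        assert len(cs) == 1
        f = cs.iloc[0]
        match = [s for s in called_srnas
                 if s.replicon == f.replicon and s.overlap(f.start, f.end) > 0]
        assert match, "condition-specific feature was not recovered"
        ca = qd.correspondence_analysis(expr)
        row = ca.row_coords.loc[match[0].id].to_numpy()[:2]
        sims = {
            smp: np.dot(row, ca.col_coords.loc[smp].to_numpy()[:2])
            / (np.linalg.norm(row) * np.linalg.norm(ca.col_coords.loc[smp].to_numpy()[:2]))
            for smp in expr.columns
        }
        best = max(sims, key=sims.get)
        assert best.startswith("salt"), f"nearest sample was {best}"


class TestDeConditions:
    def test_null_study_yields_few_calls(self):
        counts = synthdata.simulate_counts(120, dispersion=0.1, base_mean=150.0, seed=41)
        res = qd.de_conditions(counts)
        frac_sig = res["significant"].mean()
        assert frac_sig < 0.05

    def test_planted_condition_effect_detected_in_that_condition_only(self):
        n = 200
        eff = np.ones(n)
        eff[:20] = 5.0
        counts = synthdata.simulate_counts(n, effects={"salt": eff}, dispersion=0.05,
                                           base_mean=300.0, seed=42)
        res = qd.de_conditions(counts)
        sig = res[res["significant"]]
        salt_hits = set(sig[sig["comparison"] == "salt"]["srna_id"])
        assert len(salt_hits & {f"sRNA{i+1}" for i in range(20)}) >= 16
        other = sig[sig["comparison"] != "salt"]
        assert len(other) <= 0.02 * len(res)

    def test_timepoint_mode_produces_per_time_comparisons(self):
        counts = synthdata.simulate_counts(30, dispersion=0.1, base_mean=100.0, seed=43)
        res = qd.de_conditions(counts, mode="timepoint")
        assert {"ethanol_24h", "salt_72h"} <= set(res["comparison"])
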