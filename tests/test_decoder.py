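"""Reverse-inference decoding: activation mapping, the Bayes formulas,
chi-square association, FDR and term selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sysdecode as sd
from sysdecode.decoder import _chi2_from_table

GRID = sd.VolumeGrid.isotropic((10, 10, 10), 2.0)


def _roi(voxels, name="roi"):
    m = np.zeros(GRID.shape, bool)
    for v in voxels:
        m[v] = True
    return sd.RegionMask(GRID, m, name)


def _db(foci, freq):
    return sd.CoordinateDatabase(foci, freq)


def _act(active, roi="roi"):
    active = np.asarray(active, bool)
    return sd.ActivationVector(active, [f"s{i}" for i in range(len(active))],
                               roi, 0.0)


def _labeling(cols: dict):
    n = len(next(iter(cols.values())))
    idx = [f"s{i}" for i in range(n)]
    return sd.TermLabeling(pd.DataFrame(cols, index=idx).astype(np.int8), 0.001)


class TestActivationVector:
    def test_focus_at_voxel_center_radius_zero(self):
        roi = _roi([(4, 4, 4)])
        center = GRID.voxel_centers(np.array([[4, 4, 4]]))[0]
        freq = pd.DataFrame({"t": [0.1, 0.1]}, index=["a", "b"])
        db = _db({"a": center[None, :], "b": np.empty((0, 3))}, freq)
        av = sd.activation_vector(db, roi, radius_mm=0.0)
        assert av.active.tolist() == [True, False]

    def test_study_without_foci_inactive(self):
        freq = pd.DataFrame({"t": [0.1]}, index=["a"])
        db = _db({}, freq)
        av = sd.activation_vector(db, _roi([(0, 0, 0)]), radius_mm=6.0)
        assert av.active.tolist() == [False]

    def test_radius_matches_brute_force_distance_scan(self, rng):
        roi = _roi([(2, 3, 4), (7, 7, 7), (5, 1, 8)])
        centers = roi.voxel_centers_mm()
        studies = {}
        for i in range(40):
            studies[f"s{i}"] = rng.uniform(-12, 12, size=(rng.integers(1, 5), 3))
        freq = pd.DataFrame({"t": np.full(40, 0.1)}, index=list(studies))
        db = _db(studies, freq)
        av = sd.activation_vector(db, roi, radius_mm=6.0)
        for i, s in enumerate(db.studies):
            d = np.sqrt((((studies[s][:, None, :] - centers[None]) ** 2).sum(-1)))
            assert av.active[i] == bool((d <= 6.0).any())

    def test_empty_roi_rejected(self):
        freq = pd.DataFrame({"t": [0.1]}, index=["a"])
        with pytest.raises(ValueError, match="empty"):
            sd.activation_vector(_db({}, freq), _roi([]))


class TestConditionProbs:
    def test_all_term_studies_active(self):
        act = _act([1] * 10 + [0] * 5)
        lab = _labeling({"t": [1] * 10 + [0] * 5})
        pat, patn = sd.condition_probs(act, lab, "t")
        assert pat == 1.0 and patn == 0.0

    def test_counting_example(self):
        # act&term=30, ~act&term=10, act&~term=10, ~act&~term=30
        act = _act([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30)
        lab = _labeling({"t": [1] * 40 + [0] * 40})
        assert sd.condition_probs(act, lab, "t") == (0.75, 0.25)

    def test_independent_db_likelihoods_near_base_rate(self, rng):
        n = 2000
        act = _act(rng.random(n) < 0.3)
        lab = _labeling({"t": (rng.random(n) < 0.5).astype(int)})
        pat, patn = sd.condition_probs(act, lab, "t")
        assert pat == pytest.approx(0.3, abs=0.05)
        assert patn == pytest.approx(0.3, abs=0.05)

    def test_degenerate_stratum_rejected(self):
        act = _act([1, 0, 1])
        lab = _labeling({"t": [1, 1, 1]})
        with pytest.raises(ValueError, match="degenerate"):
            sd.condition_probs(act, lab, "t")


class TestInferenceFormulas:
    def test_forward_printed_example(self):
        assert sd.forward_inference(0.8, 0.2, 0.5) == pytest.approx(0.5)

    def test_forward_mixture_of_equal_values(self, rng):
        for _ in range(20):
            x, p = rng.random(), rng.random()
            assert sd.forward_inference(x, x, p) == pytest.approx(x)

    def test_forward_extremes(self):
        assert sd.forward_inference(1.0, 0.0, 0.5) == pytest.approx(0.5)

    def test_reverse_printed_example(self):
        assert sd.reverse_inference(0.8, 0.2, 0.5) == pytest.approx(0.8)

    def test_reverse_equal_likelihoods_return_prior(self, rng):
        for _ in range(20):
            x = rng.uniform(0.05, 1.0)
            p = rng.uniform(0.01, 0.99)
            assert sd.reverse_inference(x, x, p) == pytest.approx(p)

    def test_reverse_perfect_discrimination(self):
        assert sd.reverse_inference(1.0, 0.0, 0.5) == 1.0

    def test_posterior_monotone_in_likelihoods(self, rng):
        pat = np.sort(rng.uniform(0.01, 1.0, 10))
        post = [sd.reverse_inference(p, 0.3, 0.5) for p in pat]
        assert np.all(np.diff(post) >= 0)
        patn = np.sort(rng.uniform(0.01, 1.0, 10))
        post = [sd.reverse_inference(0.3, p, 0.5) for p in patn]
        assert np.all(np.diff(post) <= 0)

    def test_zero_forward_rejected(self):
        with pytest.raises(ValueError, match="forward"):
            sd.reverse_inference(0.0, 0.0, 0.5)

    def test_agrees_with_joint_count_bayes_oracle(self, rng):
        # enumerate a weighted joint distribution over (term, activation)
        # and read the posterior off the joint table directly
        for _ in range(200):
            pat, patn = rng.random(2)
            prior = rng.uniform(0.01, 0.99)
            joint = {
                ("term", "act"): prior * pat,
                ("term", "no"): prior * (1 - pat),
                ("not", "act"): (1 - prior) * patn,
                ("not", "no"): (1 - prior) * (1 - patn),
            }
            p_act = joint[("term", "act")] + joint[("not", "act")]
            if p_act == 0:
                continue
            want = joint[("term", "act")] / p_act
            assert sd.reverse_inference(pat, patn, prior) == pytest.approx(
                want, abs=1e-12)


class TestChiSquare:
    def test_printed_toy_table_gives_twenty(self):
        act = _act([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30)
        lab = _labeling({"t": [1] * 40 + [0] * 40})
        stat, p = sd.chi_square_association(act, lab, "t")
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(stats.chi2.sf(20.0, 1))

    def test_identical_rows_give_zero(self):
        act = _act([1, 0, 1, 0])
        lab = _labeling({"t": [1, 1, 0, 0]})
        stat, p = sd.chi_square_association(act, lab, "t")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_uninformative(self):
        stat, p = _chi2_from_table(np.array([[3.0, 5.0], [0.0, 0.0]]))
        assert (stat, p) == (0.0, 1.0)

    def test_random_tables_match_scipy_oracle(self, rng):
        for _ in range(100):
            table = rng.integers(1, 60, size=(2, 2)).astype(float)
            stat, p = _chi2_from_table(table)
            want = stats.chi2_contingency(table, correction=False)
            assert stat == pytest.approx(want.statistic)
            assert p == pytest.approx(want.pvalue)


class TestFdr:
    def test_hand_stepped_example(self):
        q, rej = sd.fdr_correct([0.001, 0.01, 0.02, 0.04, 0.2], alpha=0.05)
        assert rej.tolist() == [True, True, True, True, False]

    def test_all_ones_reject_nothing(self):
        _, rej = sd.fdr_correct([1.0] * 10)
        assert not rej.any()

    def test_single_p(self):
        _, rej = sd.fdr_correct([0.04], alpha=0.05)
        assert rej.tolist() == [True]

    def test_empty_input(self):
        q, rej = sd.fdr_correct([])
        assert len(q) == 0 and len(rej) == 0


class TestDecodeRoi:
    def test_planted_term_has_max_posterior_and_significance(self, rng):
        # term t0 co-occurs with activation (odds ratio >> 1); the other
        # terms are independent of it
        n = 1200
        active = rng.random(n) < 0.25
        cols = {"t0": np.where(active, rng.random(n) < 0.8,
                               rng.random(n) < 0.05).astype(float) * 0.1}
        for j in range(1, 15):
            cols[f"t{j}"] = (rng.random(n) < 0.3).astype(float) * 0.1
        freq = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
        db = _db({}, freq)
        act = sd.ActivationVector(active, db.studies, "roi", 0.0)
        res = sd.decode_roi(db, act)
        best = res.rows.sort_values("posterior", ascending=False).iloc[0]
        assert best["term"] == "t0"
        assert bool(best["significant"])

    def test_independent_null_db_controls_fdr(self, rng):
        n, m = 1500, 60
        active = rng.random(n) < 0.3
        freq = pd.DataFrame((rng.random((n, m)) < 0.4) * 0.1,
                            columns=[f"t{j}" for j in range(m)],
                            index=[f"s{i}" for i in range(n)])
        db = _db({}, freq)
        res = sd.decode_roi(db, sd.ActivationVector(active, db.studies, "r", 0.0))
        assert res.rows["significant"].mean() <= 0.05 + 0.05

    def test_equal_likelihood_term_decodes_to_prior(self):
        # proportional rows: P(act|term) = P(act|~term) = 0.5
        active = np.array([1, 0] * 20, bool)
        freq = pd.DataFrame({"t": [0.1] * 20 + [0.0] * 20,
                             "u": [0.1, 0.1, 0.0, 0.0] * 10},
                            index=[f"s{i}" for i in range(40)])
        db = _db({}, freq)
        res = sd.decode_roi(db, sd.ActivationVector(active, db.studies, "r", 0.0))
        row = res.rows.set_index("term").loc["u"]
        assert row["posterior"] == pytest.approx(0.5)

    def test_invariant_to_study_and_vocab_order(self, rng):
        n = 300
        active = rng.random(n) < 0.4
        freq = pd.DataFrame((rng.random((n, 6)) < 0.4) * 0.2,
                            columns=list("fedcba"),
                            index=[f"s{i}" for i in range(n)])
        db1 = _db({}, freq)
        perm = rng.permutation(n)
        db2 = _db({}, freq.iloc[perm, ::-1])
        r1 = sd.decode_roi(db1, sd.ActivationVector(active, db1.studies, "r", 0.0))
        r2 = sd.decode_roi(db2, sd.ActivationVector(active[perm], db2.studies, "r", 0.0))
        a = r1.rows.sort_values("term").reset_index(drop=True)
        b = r2.rows.sort_values("term").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_terms_are_excluded(self):
        active = np.array([1, 0, 1, 0], bool)
        freq = pd.DataFrame({"all": [0.1] * 4, "none": [0.0] * 4,
                             "ok": [0.1, 0.0, 0.1, 0.0]},
                            index=list("abcd"))
        db = _db({}, freq)
        res = sd.decode_roi(db, sd.ActivationVector(active, db.studies, "r", 0.0))
        assert set(res.rows["term"]) == {"ok"}
        assert set(res.excluded_terms) == {"all", "none"}


def _result_with(n_terms, significant=True, posterior=0.8):
    rows = pd.DataFrame({
        "term": [f"t{j:03d}" for j in range(n_terms)],
        "p_act_given_term": 0.5, "p_act_given_notterm": 0.3,
        "forward": 0.4, "posterior": posterior,
        "chi2": 10.0, "p_value": 0.001, "q_value": 0.01,
        "significant": significant,
    })
    return sd.DecodingResult("roi", 0.5, rows, 10, 100)


class TestSelectTerms:
    def test_exactly_thirty_from_surplus(self):
        res = _result_with(100)
        allow = {f"t{j:03d}" for j in range(100)}
        assert len(sd.select_terms(res, 30, allow)) == 30

    def test_supply_below_k_returns_all(self):
        res = _result_with(5)
        assert len(sd.select_terms(res, 30)) == 5

    def test_equal_posteriors_break_ties_lexicographically(self):
        res = _result_with(50, posterior=0.7)
        out = sd.select_terms(res, 10)
        assert out == sorted(res.rows["term"])[:10]

    def test_rank_then_filter_drops_nonsignificant_after_ranking(self):
        rows = _result_with(40).rows
        rows.loc[rows.index < 20, "significant"] = False
        rows["posterior"] = np.linspace(1.0, 0.5, 40)  # top ranks not significant
        res = sd.DecodingResult("roi", 0.5, rows, 10, 100)
        out = sd.select_terms(res, 30, order="rank_then_filter")
        assert len(out) == 10  # 30 ranked, first 20 dropped post-hoc
        out2 = sd.select_terms(res, 30, order="filter_then_rank")
        assert len(out2) == 20

    def test_empty_allowlist_warns_and_skips_filter(self):
        res = _result_with(10)
        with pytest.warns(UserWarning, match="allowlist"):
            out = sd.select_terms(res, 5, construct_allowlist=[])
        assert len(out) == 5
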