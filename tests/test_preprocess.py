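"""Background correction, geNorm ranking, normalization and control QC."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lymphcll as L
from lymphcll.containers import ConfigurationError, ValidationError
from lymphcll.preprocess import (
    background_correct,
    genorm_rank,
    geometric_mean,
    normalize,
    preprocess_pipeline,
    qc_positive_controls,
)


def matrix_from(values: dict, classes: dict, stage="raw"):
    data = pd.DataFrame(values).T
    data.columns = [f"s{i + 1}" for i in range(data.shape[1])]
    return L.CountMatrix(data, pd.Series(classes), stage=stage)


class TestBackgroundCorrect:
    def test_arithmetic_oracle(self):
        # neg counts {4,6,8,10,12}: mean 8, sample SD sqrt(10), threshold
        # 8 + 2*sqrt(10) ~= 14.3246
        m = matrix_from(
            {"NEG_A": [4], "NEG_B": [6], "NEG_C": [8], "NEG_D": [10], "NEG_E": [12],
             "g_hi": [20], "g_lo": [10]},
            {**{f"NEG_{c}": "negative" for c in "ABCDE"},
             "g_hi": "endogenous", "g_lo": "endogenous"},
        )
        corrected, model = background_correct(m)
        thr = 8 + 2 * math.sqrt(10)
        assert model.loc["s1", "threshold"] == pytest.approx(thr)
        assert corrected.data.loc["g_hi", "s1"] == pytest.approx(20 - thr)  # ~5.6754
        assert corrected.data.loc["g_lo", "s1"] == 0.0  # clamped
        # negative-control rows kept for audit
        assert corrected.data.loc["NEG_C", "s1"] == 8

    def test_zero_background_leaves_counts(self):
        m = matrix_from(
            {"NEG_A": [0], "NEG_B": [0], "g": [7]},
            {"NEG_A": "negative", "NEG_B": "negative", "g": "endogenous"},
        )
        corrected, model = background_correct(m)
        assert model.loc["s1", "threshold"] == 0.0
        assert corrected.data.loc["g", "s1"] == 7.0

    def test_requires_two_negative_probes(self):
        m = matrix_from({"NEG_A": [5], "g": [7]},
                        {"NEG_A": "negative", "g": "endogenous"})
        with pytest.raises(ConfigurationError, match="negative"):
            background_correct(m)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_never_increases_and_stays_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(8)] + ["NEG_A", "NEG_B", "NEG_C"]
        classes = {g: ("negative" if g.startswith("NEG") else "endogenous") for g in genes}
        data = pd.DataFrame(rng.integers(0, 500, (11, 4)).astype(float),
                            index=genes, columns=list("abcd"))
        m = L.CountMatrix(data, pd.Series(classes))
        corrected, _ = background_correct(m)
        endo = [g for g in genes if not g.startswith("NEG")]
        assert (corrected.data.loc[endo] <= data.loc[endo]).all().all()
        assert (corrected.data >= 0).all().all()


def brute_force_m_values(counts: pd.DataFrame) -> dict:
    """Independent geNorm oracle: mean over partner genes of the SD of
    pairwise log2 ratios, enumerated explicitly."""
    out = {}
    for j in counts.index:
        sds = []
        for k in counts.index:
            if k == j:
                continue
            ratios = [
                math.log2(counts.loc[j, s] / counts.loc[k, s]) for s in counts.columns
            ]
            mean = sum(ratios) / len(ratios)
            sds.append(math.sqrt(sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)))
        out[j] = sum(sds) / len(sds)
    return out


class TestGeNorm:
    def _matrix(self, frame):
        classes = {g: "housekeeping" for g in frame.index}
        return L.CountMatrix(frame, pd.Series(classes), stage="background_corrected")

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        frame = pd.DataFrame(
            rng.integers(50, 5000, (4, 4)).astype(float),
            index=list("wxyz"), columns=[f"s{i}" for i in range(4)],
        )
        ranking = genorm_rank(self._matrix(frame), list("wxyz"), n_select=2)
        oracle = brute_force_m_values(frame)
        for g, m_val in ranking.m_values[0].items():
            assert m_val == pytest.approx(oracle[g], abs=1e-9)

    def test_proportional_pair_contributes_zero(self):
        frame = pd.DataFrame(
            {"s1": [100.0, 200.0, 130.0], "s2": [50.0, 100.0, 260.0],
             "s3": [400.0, 800.0, 70.0]},
            index=["a", "b", "c"],
        )  # b = 2*a exactly
        oracle = brute_force_m_values(frame)
        # a's only nonzero contribution comes from c; the a-b pair SD is 0
        pair_ab = np.std(np.log2(frame.loc["a"] / frame.loc["b"]), ddof=1)
        assert pair_ab == 0.0
        assert oracle["a"] == pytest.approx(oracle["b"], abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_per_sample_scaling(self, seed):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(
            rng.uniform(10, 1000, (5, 6)),
            index=list("abcde"), columns=[f"s{i}" for i in range(6)],
        )
        scales = rng.uniform(0.1, 10, 6)
        r1 = genorm_rank(self._matrix(frame), list("abcde"), 3)
        r2 = genorm_rank(self._matrix(frame * scales), list("abcde"), 3)
        assert r1.selected == r2.selected
        for m1, m2 in zip(r1.m_values, r2.m_values):
            for g in m1:
                assert m1[g] == pytest.approx(m2[g], abs=1e-9)

    def test_pseudo_count_for_zeros_warns(self):
        frame = pd.DataFrame(
            {"s1": [0.0, 200.0, 130.0], "s2": [50.0, 100.0, 260.0]},
            index=["a", "b", "c"],
        )
        with pytest.warns(UserWarning, match="pseudo-count"):
            genorm_rank(self._matrix(frame), ["a", "b", "c"], 2)

    def test_selects_planted_most_stable_candidates(self, default_cohort):
        _, pp = default_cohort
        assert pp["ranking"].selected == ["RPL19", "RPLP0", "TPT1"]


class TestNormalize:
    def _matrix(self, values):
        genes = list(values)
        classes = {g: ("housekeeping" if g.startswith("hk") else "endogenous")
                   for g in genes}
        return matrix_from(values, classes, stage="background_corrected")

    def test_identical_hk_counts_give_unit_factors(self):
        m = self._matrix({"hk1": [100, 100], "hk2": [400, 400], "g": [7, 9]})
        normalized, f = normalize(m, ["hk1", "hk2"])
        assert np.allclose(f.factors, 1.0)
        pd.testing.assert_frame_equal(normalized.data, m.data)

    def test_two_sample_oracle(self):
        # hk geomeans 100 and 200 -> G = sqrt(2e4), factors sqrt2, 1/sqrt2
        m = self._matrix({"hk1": [50, 100], "hk2": [200, 400], "g": [10, 10]})
        _, f = normalize(m, ["hk1", "hk2"])
        assert f.reference_geomean == pytest.approx(math.sqrt(100 * 200))
        assert f.factors["s1"] == pytest.approx(math.sqrt(2))
        assert f.factors["s2"] == pytest.approx(1 / math.sqrt(2))

    def test_column_scaling_is_removed_up_to_global_anchor(self):
        # with the geomean-1 anchoring, scaling sample s's column by c
        # rescales the whole normalized matrix by the single scalar
        # c^(1/n_samples); between-sample structure and all ratios are
        # unchanged
        m = self._matrix({"hk1": [100, 100], "hk2": [400, 400], "g": [8, 8]})
        scaled = L.CountMatrix(m.data * [1.0, 7.5], m.probe_classes,
                               stage="background_corrected")
        n1, _ = normalize(m, ["hk1", "hk2"])
        n2, _ = normalize(scaled, ["hk1", "hk2"])
        anchor = 7.5 ** 0.5
        pd.testing.assert_frame_equal(n1.data * anchor, n2.data,
                                      atol=1e-9, rtol=1e-12)

    def test_factor_geomean_is_one_and_idempotent(self, default_cohort):
        _, pp = default_cohort
        factors = pp["factors"].factors
        assert geometric_mean(factors) == pytest.approx(1.0, abs=1e-12)
        again, f2 = normalize(pp["normalized"], pp["factors"].hk_genes)
        assert np.allclose(f2.factors, 1.0)

    def test_zero_hk_count_is_an_error(self):
        m = self._matrix({"hk1": [0, 100], "hk2": [400, 400], "g": [7, 9]})
        with pytest.raises(ValidationError, match="reselect|pseudo"):
            normalize(m, ["hk1", "hk2"])

    def test_removes_planted_size_factors_exactly_when_noiseless(self):
        cohort = L.generate_cohort(L.SimConfig().noiseless(), seed=5)
        pp = preprocess_pipeline(cohort.counts, cohort.probes)
        hk = pp["normalized"].data.loc[pp["ranking"].selected]
        spread = (hk.max(axis=1) - hk.min(axis=1)) / hk.mean(axis=1)
        # integer rounding of raw counts leaves sub-0.1% residuals at worst
        assert (spread < 2e-3).all()


class TestPositiveControlQC:
    PROBES = [L.ProbeDef(f"POS_{c}", "positive", "", conc)
              for c, conc in zip("ABC", (128.0, 32.0, 8.0))]

    def _matrix(self, counts):
        return matrix_from(
            {f"POS_{c}": [v] for c, v in zip("ABC", counts)},
            {f"POS_{c}": "positive" for c in "ABC"},
        )

    def test_geometric_series_closed_form(self):
        # count halves per 4x concentration step after the +1 offset is
        # negligible: use large counts so slope ~= 1, R^2 ~= 1
        qc = qc_positive_controls(self._matrix([128000, 32000, 8000]), self.PROBES)
        assert qc.loc["s1", "slope"] == pytest.approx(1.0, abs=1e-4)
        assert qc.loc["s1", "r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert not qc.loc["s1", "flagged"]

    def test_constant_counts_flagged(self):
        qc = qc_positive_controls(self._matrix([500, 500, 500]), self.PROBES)
        assert qc.loc["s1", "slope"] == 0.0 and bool(qc.loc["s1", "flagged"])

    def test_missing_concentrations_skips_with_warning(self):
        probes = [L.ProbeDef(f"POS_{c}", "positive") for c in "ABC"]
        with pytest.warns(UserWarning, match="skipped"):
            qc = qc_positive_controls(self._matrix([1, 2, 3]), probes)
        assert qc.empty
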