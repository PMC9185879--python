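import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootmorph.diagnostics import (
    SampleSizeSpec,
    classify,
    contingency_metrics,
    group_compare,
    icc,
    mann_whitney_auc,
    roc_auc,
    roc_curve,
    sample_size,
    second_group_size,
    youden_cutoff,
)


def brute_force_auc(crt, nrt):
    """P(crt < nrt) + 0.5 P(crt == nrt) over all pairs."""
    wins = ties = 0
    for c, n in itertools.product(crt, nrt):
        if c < n:
            wins += 1
        elif c == n:
            ties += 1
    return (wins + 0.5 * ties) / (len(crt) * len(nrt))


def brute_force_youden(crt, nrt):
    """Exhaustive YI maximum over midpoint thresholds (rule: value < t -> CRT)."""
    pooled = sorted(set(crt) | set(nrt))
    cands = [-math.inf, math.inf] + [
        (a + b) / 2 for a, b in zip(pooled, pooled[1:])
    ]
    best = (-math.inf, None)
    for t in sorted(cands):
        se = sum(1 for v in crt if v < t) / len(crt)
        sp = sum(1 for v in nrt if v >= t) / len(nrt)
        yi = se + sp - 1
        if yi > best[0] + 1e-15:
            best = (yi, t)
    return best


small_group = st.lists(st.integers(0, 6), min_size=1, max_size=8)


class TestAuc:
    def test_complete_separation(self):
        assert roc_auc([1, 2], [3, 4]).auc == pytest.approx(1.0)

    def test_interleaved_three_quarters(self):
        # frozen from brute_force_auc([1,3],[2,4]) = 3/4
        assert brute_force_auc([1, 3], [2, 4]) == 0.75
        assert roc_auc([1, 3], [2, 4]).auc == pytest.approx(0.75)

    def test_identical_groups_half(self):
        vals = [1.0, 2.0, 2.0, 5.0]
        assert roc_auc(vals, vals).auc == pytest.approx(0.5)

    def test_curve_endpoints_monotone(self):
        rng = np.random.default_rng(3)
        rep = roc_curve(rng.normal(0, 1, 25), rng.normal(1, 1, 30))
        assert rep.fpr[0] == 0 and rep.tpr[0] == 0
        assert rep.fpr[-1] == 1 and rep.tpr[-1] == 1
        assert (np.diff(rep.fpr) >= 0).all() and (np.diff(rep.tpr) >= 0).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])

    @given(crt=small_group, nrt=small_group)
    @settings(max_examples=120, deadline=None)
    def test_trapezoid_equals_mann_whitney(self, crt, nrt):
        rep = roc_curve(crt, nrt)
        expected = brute_force_auc(crt, nrt)
        assert rep.auc == pytest.approx(expected, abs=1e-12)
        assert mann_whitney_auc(crt, nrt) == pytest.approx(expected, abs=1e-12)

    @given(crt=small_group, nrt=small_group)
    @settings(max_examples=60, deadline=None)
    def test_swapping_groups_complements(self, crt, nrt):
        assert roc_curve(crt, nrt).auc == pytest.approx(
            1.0 - roc_curve(nrt, crt).auc, abs=1e-12
        )


class TestYouden:
    def test_separated_midpoint(self):
        rep = youden_cutoff(roc_auc([1, 2], [3, 4]), [1, 2], [3, 4])
        assert rep.cutoff == pytest.approx(2.5)
        assert rep.se_at_cutoff == 1.0 and rep.sp_at_cutoff == 1.0

    def test_interleaved_brute_force(self):
        # brute-force enumeration: YI max 0.5, first attained at threshold 1.5
        yi, cut = brute_force_youden([1, 3], [2, 4])
        assert yi == pytest.approx(0.5)
        assert cut == pytest.approx(1.5)
        rep = youden_cutoff(roc_auc([1, 3], [2, 4]), [1, 3], [2, 4])
        assert rep.cutoff == pytest.approx(1.5)
        assert rep.se_at_cutoff + rep.sp_at_cutoff - 1 == pytest.approx(0.5)

    def test_tie_takes_smallest(self):
        # both midpoints achieve YI = 0.5; smallest (1.5) must win
        rep = youden_cutoff(roc_auc([1, 3], [2, 4]), [1, 3], [2, 4])
        assert rep.cutoff == 1.5

    @given(crt=small_group, nrt=small_group)
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_search(self, crt, nrt):
        rep = youden_cutoff(roc_curve(crt, nrt), crt, nrt)
        yi_best, _ = brute_force_youden(crt, nrt)
        achieved = rep.se_at_cutoff + rep.sp_at_cutoff - 1
        assert achieved == pytest.approx(yi_best, abs=1e-12)


class TestClassify:
    def test_below_cutoff_is_crt(self):
        assert classify([19.60], 19.61)[0] == "CRT"

    def test_boundary_is_nrt(self):
        assert classify([19.61], 19.61)[0] == "NRT"

    def test_above_cutoff_is_nrt(self):
        assert classify([24.10], 24.05)[0] == "NRT"


class TestContingency:
    def test_reconstructed_table_counts(self):
        # TP=36 FP=10 FN=5 TN=44 (counts consistent with Se .88 / Sp .81 at 41/54)
        m = contingency_metrics(36, 10, 5, 44)
        assert m.Se == pytest.approx(0.88, abs=0.005)
        assert m.Sp == pytest.approx(0.81, abs=0.005)
        assert m.PV_pos == pytest.approx(0.78, abs=0.005)
        assert m.YI == pytest.approx(m.Se + m.Sp - 1, abs=1e-12)

    def test_rate_arithmetic(self):
        m = contingency_metrics(88, 19, 12, 81)  # Se=.88, Sp=.81 exactly
        assert m.YI == pytest.approx(0.69)
        assert m.LR_pos == pytest.approx(0.88 / 0.19)
        assert m.LR_neg == pytest.approx(0.12 / 0.81)

    def test_undefined_flagged_not_zero(self):
        m = contingency_metrics(0, 3, 0, 7)
        assert m.Se is None and m.YI is None
        assert m.Sp is not None

    def test_perfect_specificity_lr_pos_undefined(self):
        m = contingency_metrics(5, 0, 1, 10)
        assert m.LR_pos is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            contingency_metrics(-1, 0, 0, 0)


class TestSampleSize:
    def test_equal_allocation_example(self):
        # z_{.025} + z_{.20} = 2.8016; 2 * 2.8016^2 = 15.70 -> 16
        n1, n2 = sample_size(SampleSizeSpec(k=1.0, alpha=0.05, beta=0.20))
        assert (n1, n2) == (16, 16)

    def test_second_group_from_first(self):
        assert second_group_size(0.75, 54) == 41

    def test_huge_effect_floors_at_two(self):
        n1, n2 = sample_size(
            SampleSizeSpec(k=1.0, alpha=0.05, beta=0.20, sigma=1.0, delta=1e9)
        )
        assert n1 == 2 and n2 == 2

    @pytest.mark.parametrize("bad", [dict(k=0), dict(k=1, alpha=0), dict(k=1, sigma=0)])
    def test_invalid_specs(self, bad):
        with pytest.raises(ValueError):
            SampleSizeSpec(**{"k": 1.0, **bad})


class TestIcc:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        assert icc(x, x.copy()) == pytest.approx(1.0)

    def test_heavy_noise_low_icc(self):
        rng = np.random.default_rng(11)
        subj = rng.normal(0, 1, 200)
        a = subj + rng.normal(0, 3, 200)
        b = subj + rng.normal(0, 3, 200)
        assert icc(a, b) < 0.5

    def test_variance_ratio_oracle(self):
        # sigma_s = 10, sigma_e = 1 -> expected ICC ~ 100/101 > 0.8
        rng = np.random.default_rng(17)
        subj = rng.normal(50, 10, 500)
        a = subj + rng.normal(0, 1, 500)
        b = subj + rng.normal(0, 1, 500)
        val = icc(a, b)
        assert val > 0.8
        assert val == pytest.approx(100 / 101, abs=0.03)

    def test_against_pingouin(self):
        # independent implementation check: ICC2 (single rater, absolute)
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(23)
        subj = rng.normal(0, 2, 40)
        a = subj + rng.normal(0, 1, 40)
        b = subj + 0.5 + rng.normal(0, 1, 40)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": np.tile(["r1", "r2"], 40),
                "score": np.column_stack([a, b]).ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        # pingouin labels two-way random absolute-agreement single as ICC(A,1)
        # (older releases used "ICC2"); match either
        mask = table.Type.astype(str).str.replace(" ", "").isin(["ICC(A,1)", "ICC2"])
        expected = float(table.loc[mask, "ICC"].iloc[0])
        assert icc(a, b) == pytest.approx(expected, abs=1e-9)

    def test_zero_between_subject_variance_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            icc(np.ones(5), np.ones(5))

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            icc([1.0, 2.0], [1.0, 2.0])


class TestGroupCompare:
    def test_identical_groups(self):
        res = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["t_p"] == pytest.approx(1.0)

    def test_extreme_separation(self):
        res = group_compare([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert res["t_p"] < 0.01

    def test_hand_computed_pooled_t(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [3.0, 5.0, 7.0]
        na, nb = 4, 3
        va = np.var(a, ddof=1)
        vb = np.var(b, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        expected = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert group_compare(a, b)["t"] == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_distinct_means(self):
        res = group_compare([5.0, 5.0], [7.0, 7.0])
        assert res["t_p"] == 0.0

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0], [2.0, 3.0])
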