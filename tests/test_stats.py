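"""One-way ANOVA and Duncan's multiple range test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from desertfvc.datasets import ANOVA_AUDIT_FLAGGED, SURVEY_DF, survey_anova_rows
from desertfvc.stats import (
    anova_consistency,
    duncan_mrt,
    one_way_anova,
    replicate_study,
)


def test_two_group_hand_example():
    t = one_way_anova([[1, 2, 3], [2, 3, 4]])
    assert t.ss_between == pytest.approx(1.5)
    assert t.ss_within == pytest.approx(4.0)
    assert (t.df_between, t.df_within, t.df_total) == (1, 4, 5)
    assert t.ms_between == pytest.approx(1.5)
    assert t.ms_within == pytest.approx(1.0)
    assert t.f == pytest.approx(1.5)


def test_balanced_design_degrees_of_freedom(rng):
    groups = [rng.normal(size=6) for _ in range(19)]
    t = one_way_anova(groups)
    assert (t.df_between, t.df_within, t.df_total) == SURVEY_DF == (18, 95, 113)


def test_identical_groups_give_zero_f():
    t = one_way_anova([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
    assert t.f == 0.0 and t.p == 1.0


def test_zero_within_variance_flagged():
    t = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
    assert np.isnan(t.f) and np.isnan(t.p)


def test_sum_of_squares_additivity(rng):
    for _ in range(50):
        k = int(rng.integers(2, 8))
        groups = [rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2),
                             size=int(rng.integers(2, 12))) for _ in range(k)]
        t = one_way_anova(groups)
        assert t.ss_between + t.ss_within == pytest.approx(t.ss_total, rel=1e-9)
        assert t.df_between + t.df_within == t.df_total


def test_agrees_with_scipy_f_oneway(rng):
    groups = [rng.normal(i * 0.3, 1, size=8) for i in range(5)]
    t = one_way_anova(groups)
    f, p = sps.f_oneway(*groups)
    assert t.f == pytest.approx(f, rel=1e-12)
    assert t.p == pytest.approx(p, rel=1e-12)


def test_type_one_error_rate():
    """Under the null (19 groups x 6 obs from one normal), rejection at
    alpha = 0.05 occurs in 5% +/- 1.5% of 1000 replicates."""
    rng = np.random.default_rng(0)
    rejections = 0
    for _ in range(1000):
        groups = rng.normal(size=(19, 6))
        if one_way_anova(groups).p < 0.05:
            rejections += 1
    assert 35 <= rejections <= 65


# ---------------------------------------------------------------------------
# Printed-table audit
# ---------------------------------------------------------------------------

def test_anova_consistency_identity():
    ms_b, ms_w, f = anova_consistency(5.0, 1, 5.0, 1)
    assert (ms_b, ms_w, f) == (5.0, 5.0, 1.0)


def test_survey_tables_internally_consistent():
    """MS and F recomputed from each published TSS/df row match the printed
    3-dp values within 2 units in the last place (except the two flagged
    kappa rows whose printed TSS is visibly rounded)."""
    for row in survey_anova_rows().itertuples():
        ms_b, ms_w, f = anova_consistency(row.tss_between, 18, row.tss_within, 95)
        assert row.tss_between + row.tss_within == pytest.approx(row.tss_total, abs=0.005)
        assert ms_b == pytest.approx(row.ms_between_printed, abs=2e-3)
        assert ms_w == pytest.approx(row.ms_within_printed, abs=2e-3)
        p = float(sps.f.sf(f, 18, 95))
        tol = 0.01 if (row.grade, row.metric) in ANOVA_AUDIT_FLAGGED else 2e-3
        assert f == pytest.approx(row.f_printed, abs=tol), (row.grade, row.metric)
        assert p == pytest.approx(row.p_printed, abs=2e-3), (row.grade, row.metric)


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

def test_duncan_two_separated_groups():
    d = duncan_mrt([[10.0, 10.1, 9.9, 10.0, 10.2, 9.8],
                    [1.0, 1.1, 0.9, 1.0, 1.2, 0.8]], names=["hi", "lo"])
    assert d.letters == {"hi": "a", "lo": "b"}
    assert d.means[0] > d.means[1]


def test_duncan_identical_groups_share_letter():
    d = duncan_mrt([[2.0, 2.0, 2.0]] * 4)
    assert set(d.letters.values()) == {"a"}


def test_duncan_unbalanced_rejected():
    with pytest.raises(ValueError, match="balanced"):
        duncan_mrt([[1, 2, 3], [1, 2]])


def test_duncan_two_known_blocks_recovered():
    """Groups with true means (0, 0, 3, 3) and small within-variance yield
    exactly two letter blocks in the vast majority of seeded replicates.

    The rate is scale-invariant: each equal adjacent pair splits spuriously
    with probability 2*Phi(-q95(2, 20)/2) ~ 3.7-4.5% (t tails), so the
    expected two-block rate is (1 - ~0.04)^2 ~ 0.91; the distant pairs are
    ~10 sigma apart and never merge.  200 replicates at rate 0.91 leave
    >= 170 hits with overwhelming probability.
    """
    rng = np.random.default_rng(77)
    hits = 0
    for _ in range(200):
        groups = [rng.normal(m, 0.5, size=6) for m in (0, 0, 3, 3)]
        d = duncan_mrt(groups, names=list("abcd"))
        blocks = {d.letters["c"], d.letters["d"]}, {d.letters["a"], d.letters["b"]}
        if blocks == ({"a"}, {"b"}):
            hits += 1
    assert hits >= 170


def test_duncan_k2_reduces_to_studentized_range_comparison(rng):
    """With two groups the decision equals |mean diff| vs q_alpha(2, df) * SE."""
    for _ in range(50):
        g1 = rng.normal(0, 1, size=6)
        g2 = rng.normal(rng.uniform(0, 2), 1, size=6)
        t = one_way_anova([g1, g2])
        d = duncan_mrt([g1, g2], names=["x", "y"])
        q_crit = sps.studentized_range.ppf(0.95, 2, t.df_within)
        expect_sig = abs(g1.mean() - g2.mean()) > q_crit * np.sqrt(t.ms_within / 6)
        got_sig = d.letters["x"] != d.letters["y"]
        assert got_sig == expect_sig


def test_duncan_letters_contiguous(rng):
    """Each letter spans a contiguous block of the sorted means."""
    for _ in range(20):
        groups = [rng.normal(rng.uniform(0, 3), 0.8, size=6) for _ in range(8)]
        d = duncan_mrt(groups)
        for letter in set("".join(d.letters.values())):
            positions = [i for i, n in enumerate(d.names) if letter in d.letters[n]]
            assert positions == list(range(min(positions), max(positions) + 1))


# ---------------------------------------------------------------------------
# Study-level replication
# ---------------------------------------------------------------------------

def _metric_frame(rng, effect=0.0):
    rows = []
    for grade in ["Severe", "High"]:
        for metric in ["oa_percent", "kappa"]:
            for gi in range(19):
                shift = effect * gi
                for img in range(6):
                    rows.append(dict(index=f"I{gi:02d}", image_id=img, grade=grade,
                                     metric=metric,
                                     value=float(rng.normal(shift, 1.0))))
    return pd.DataFrame(rows)


def test_replicate_study_shapes_and_effects(rng):
    frame = _metric_frame(rng, effect=2.0)
    results = replicate_study(frame)
    assert set(results) == {(g, m) for g in ["Severe", "High"]
                            for m in ["oa_percent", "kappa"]}
    for table, duncan in results.values():
        assert (table.df_between, table.df_within) == (18, 95)
        assert table.p < 0.05  # constructed effect is enormous
        assert len(duncan.letters) == 19


def test_replicate_study_order_invariant(rng):
    frame = _metric_frame(rng, effect=1.0)
    shuffled = frame.sample(frac=1.0, random_state=3)
    a = replicate_study(frame)
    b = replicate_study(shuffled)
    for key in a:
        assert a[key][0].f == pytest.approx(b[key][0].f, rel=1e-12)
        assert a[key][1].letters == b[key][1].letters


def test_replicate_study_rejects_unbalanced(rng):
    frame = _metric_frame(rng)
    frame = frame.drop(frame.index[0])
    with pytest.raises(ValueError, match="unbalanced"):
        replicate_study(frame)
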