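"""Retention summaries, the unpaired t-test and the Yates chi-square.

The t and chi-square statistics are checked against from-scratch formula
evaluations written here, independent of scipy and of the package path.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snortools.annotations import IntronRecord
from snortools.intervals import GenomicInterval
from snortools.read_model import IntronCall
from snortools.retention_stats import (
    IntronRetentionSummary,
    compare_canonical,
    compare_intron_groups,
    summarize_intron,
)


def _summary(freq_num, freq_den):
    return IntronRetentionSummary(None, freq_num, freq_den - freq_num)


def _calls(n_ret, n_spl, n_part=0):
    intron = IntronRecord("g", GenomicInterval("chr1", 100, 200))
    out = []
    for i in range(n_ret):
        out.append(IntronCall(f"r{i}", "g", intron, "RETAINED"))
    for i in range(n_spl):
        out.append(IntronCall(f"s{i}", "g", intron, "SPLICED"))
    for i in range(n_part):
        out.append(IntronCall(f"p{i}", "g", intron, "PARTIAL"))
    return out


def welch_oracle(a, b):
    """Direct evaluation of the Welch t-test formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def student_oracle(a, b):
    """Direct evaluation of the pooled-variance t-test formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as tdist

    return t, na + nb - 2, 2 * tdist.sf(abs(t), na + nb - 2)


def yates_oracle(table):
    """Sum of (|O-E| - 0.5)^2 / E with the correction floored at zero."""
    table = np.asarray(table, float)
    rows, cols, n = table.sum(1), table.sum(0), table.sum()
    chi = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            d = max(0.0, abs(table[i, j] - e) - 0.5)
            chi += d * d / e
    from scipy.stats import chi2

    return chi, chi2.sf(chi, 1)


def test_summarize_intron_counts():
    s = summarize_intron(_calls(3, 97))
    assert (s.n_retained, s.n_spliced) == (3, 97)
    assert s.frequency == pytest.approx(0.03)
    assert summarize_intron(_calls(0, 50)).frequency == 0.0


def test_summarize_intron_partial_excluded_everywhere():
    s = summarize_intron(_calls(2, 8, n_part=10))
    assert s.n_informative == 10
    assert s.frequency == pytest.approx(0.2)
    undefined = summarize_intron(_calls(0, 0, n_part=5))
    assert undefined.frequency is None


def test_identical_groups_null_case():
    a = [_summary(1, 10), _summary(2, 10)]
    b = [_summary(1, 10), _summary(2, 10)]
    cmp = compare_intron_groups(a, b)
    assert cmp.fold_change == pytest.approx(1.0)
    assert cmp.t_statistic == pytest.approx(0.0)
    assert cmp.p_value == pytest.approx(1.0)


def test_welch_fixture_against_oracle():
    """Groups {0.6, 0.5, 0.7} vs {0.1, 0.2, 0.15}: FC 4, t ~ 6.97."""
    a = [_summary(6, 10), _summary(5, 10), _summary(7, 10)]
    b = [_summary(1, 10), _summary(2, 10), IntronRetentionSummary(None, 3, 17)]
    cmp = compare_intron_groups(a, b)
    assert cmp.fold_change == pytest.approx(4.0)
    t, df, p = welch_oracle([0.6, 0.5, 0.7], [0.1, 0.2, 0.15])
    assert cmp.t_statistic == pytest.approx(t, abs=1e-10)
    assert cmp.degrees_freedom == pytest.approx(df, abs=1e-10)
    assert cmp.p_value == pytest.approx(p, abs=1e-10)
    assert cmp.t_statistic == pytest.approx(6.9714, abs=2e-4)


@pytest.mark.parametrize("variant", ["welch", "student"])
def test_t_test_matches_oracle_on_random_fixtures(variant):
    """100 random small fixtures agree with the from-scratch formulas."""
    rng = np.random.default_rng(42)
    oracle = welch_oracle if variant == "welch" else student_oracle
    for _ in range(100):
        na, nb = rng.integers(2, 12, size=2)
        ka = rng.integers(0, 21, size=na)
        kb = rng.integers(0, 21, size=nb)
        a = [_summary(int(k), 20) for k in ka]
        b = [_summary(int(k), 20) for k in kb]
        fa, fb = ka / 20, kb / 20
        if fa.var(ddof=1) + fb.var(ddof=1) == 0:
            continue  # degenerate: no variance in either group
        cmp = compare_intron_groups(a, b, test_variant=variant)
        t, df, p = oracle(fa, fb)
        assert cmp.t_statistic == pytest.approx(t, abs=1e-10)
        assert cmp.degrees_freedom == pytest.approx(df, abs=1e-10)
        assert cmp.p_value == pytest.approx(p, abs=1e-10)


def test_swapping_groups_inverts_fold_change_and_negates_t():
    a = [_summary(6, 10), _summary(5, 10), _summary(7, 10)]
    b = [_summary(1, 10), _summary(2, 10), _summary(3, 10)]
    fwd = compare_intron_groups(a, b)
    rev = compare_intron_groups(b, a)
    assert fwd.fold_change == pytest.approx(1 / rev.fold_change)
    assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
    assert fwd.p_value == pytest.approx(rev.p_value)


def test_undefined_frequencies_excluded_listwise():
    a = [_summary(1, 10), _summary(2, 10), IntronRetentionSummary(None, 0, 0)]
    b = [_summary(3, 10), _summary(4, 10)]
    cmp = compare_intron_groups(a, b)
    assert cmp.mean_snorna_freq == pytest.approx(0.15)


def test_too_few_defined_frequencies_raises():
    a = [_summary(1, 10)]
    b = [_summary(1, 10), _summary(2, 10)]
    with pytest.raises(ValueError, match="snorna_introns"):
        compare_intron_groups(a, b)


def test_yates_chi_square_fixture():
    cmp = compare_canonical({"canonical": (10, 90), "noncanonical": (30, 70)})
    chi, p = yates_oracle([[10, 90], [30, 70]])
    assert chi == pytest.approx(11.28125)
    assert cmp.chi_square_yates == pytest.approx(chi, abs=1e-10)
    assert cmp.p_value == pytest.approx(p, abs=1e-10)


def test_yates_chi_square_independence():
    cmp = compare_canonical({"canonical": (50, 50), "noncanonical": (50, 50)})
    assert cmp.chi_square_yates == 0.0
    assert cmp.p_value == 1.0


def test_yates_invariant_under_simultaneous_row_and_column_swap():
    fwd = compare_canonical({"canonical": (10, 90), "noncanonical": (30, 70)})
    swapped = compare_canonical({"canonical": (70, 30), "noncanonical": (90, 10)})
    assert fwd.chi_square_yates == pytest.approx(swapped.chi_square_yates)


def test_zero_marginal_raises():
    with pytest.raises(ValueError, match="marginal"):
        compare_canonical({"canonical": (0, 10), "noncanonical": (0, 20)})


@settings(deadline=None, max_examples=200)
@given(
    a=st.integers(1, 500), b=st.integers(1, 500),
    c=st.integers(1, 500), d=st.integers(1, 500),
)
def test_yates_never_exceeds_uncorrected_chi_square(a, b, c, d):
    from scipy.stats import chi2_contingency

    table = {"canonical": (a, b), "noncanonical": (c, d)}
    corrected = compare_canonical(table).chi_square_yates
    uncorrected, _, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
    assert corrected <= uncorrected + 1e-12
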