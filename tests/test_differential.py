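import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rescuescreen.differential import (
    Contrast,
    TestParams,
    bh_adjust,
    log2_fold_change,
    squeeze_variance,
    test_contrast,
)
from rescuescreen.quantify import fpkm_matrix
from rescuescreen.simulate import SimulationConfig, simulate_dataset


def bh_oracle(p):
    """Brute-force BH step-up: q_i = min_{j: p_j-rank >= rank_i} p_(j)*n/j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# --- log2 fold change -------------------------------------------------------


@pytest.mark.parametrize(
    "m_from,m_to,pc,expected",
    [(10, 10, 1, 0.0), (0, 0, 1, 0.0), (3, 15, 1, 2.0)],
)
def test_log2_fold_change_closed_forms(m_from, m_to, pc, expected):
    assert log2_fold_change(m_from, m_to, pc) == pytest.approx(expected, abs=1e-12)


def test_log2_fold_change_rejects_negative():
    with pytest.raises(ValueError):
        log2_fold_change(-1.0, 3.0, 1.0)


# --- BH adjustment ----------------------------------------------------------


@pytest.mark.parametrize(
    "pvals,expected",
    [
        ([0.5], [0.5]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ],
)
def test_bh_hand_examples(pvals, expected):
    assert bh_adjust(pvals) == pytest.approx(expected, abs=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


def test_bh_matches_oracle_random_vectors():
    rng = np.random.default_rng(123)
    for _ in range(300):
        n = rng.integers(1, 51)
        p = rng.random(n)
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_properties(pvals):
    q = bh_adjust(pvals)
    assert ((0 <= q) & (q <= 1)).all()
    # q respects the p-rank ordering
    order = np.argsort(pvals, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-12).all()


# --- variance moderation ----------------------------------------------------


def test_squeeze_pulls_toward_prior():
    rng = np.random.default_rng(5)
    true_var = 0.25
    s2 = true_var * rng.chisquare(4, size=4000) / 4
    post, d0, s0 = squeeze_variance(s2, df=4)
    assert d0 > 0
    assert s0 == pytest.approx(true_var, rel=0.15)
    # posterior lies between the observation and the prior, so its spread shrinks
    assert post.std() < s2.std()


def test_squeeze_degenerate_all_equal():
    """Zero spread in the observed variances collapses to a single common
    variance (infinite prior df, constant posterior)."""
    post, d0, s0 = squeeze_variance(np.full(100, 0.3), df=4)
    assert np.isinf(d0)
    assert np.allclose(post, post[0])
    assert post[0] == pytest.approx(s0)


# --- contrast test ----------------------------------------------------------


def _toy_fpkm(rows, samples):
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))], columns=samples)


def _sheet(samples, groups):
    return pd.DataFrame(
        {"genotype": groups, "replicate": list(range(1, len(samples) + 1))},
        index=pd.Index(samples, name="sample_id"),
    )


SAMPLES = ["a1", "a2", "a3", "b1", "b2", "b3"]
SHEET = _sheet(SAMPLES, ["WT"] * 3 + ["PATHOGENIC"] * 3)
CONTRAST = Contrast("wt_vs_path", "WT", "PATHOGENIC")


@pytest.mark.parametrize("moderate", [True, False])
def test_identical_groups_give_null_result(moderate):
    fpkm = _toy_fpkm([[7, 7, 7, 7, 7, 7], [3, 3, 3, 3, 3, 3]], SAMPLES)
    out = test_contrast(fpkm, CONTRAST, SHEET, TestParams(moderate_variance=moderate))
    assert np.allclose(out["log2fc"], 0.0)
    assert np.allclose(out["p"], 1.0)


def test_separated_groups_with_floored_variance():
    """log2-scale group values {2,2,2} vs {4,4,4}: log2FC = 2 and the
    floored-variance Welch t drives p below 1e-6."""
    fpkm = _toy_fpkm([[3, 3, 3, 15, 15, 15]], SAMPLES)  # log2(x+1): 2 vs 4
    out = test_contrast(fpkm, CONTRAST, SHEET, TestParams(moderate_variance=False))
    assert out["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-12)
    assert out["p"].iloc[0] < 1e-6


@pytest.mark.parametrize("moderate", [True, False])
def test_swapping_groups_is_antisymmetric(moderate):
    rng = np.random.default_rng(8)
    fpkm = _toy_fpkm(rng.uniform(0, 50, (20, 6)), SAMPLES)
    params = TestParams(moderate_variance=moderate)
    fwd = test_contrast(fpkm, CONTRAST, SHEET, params)
    rev = test_contrast(fpkm, CONTRAST.flipped(), SHEET, params)
    assert np.allclose(fwd["log2fc"], -rev["log2fc"])
    assert np.allclose(fwd["stat"], -rev["stat"])
    assert np.allclose(fwd["p"], rev["p"])
    assert np.allclose(fwd["q"], rev["q"])


def test_single_replicate_group_rejected():
    samples = ["a1", "a2", "a3", "b1"]
    sheet = _sheet(samples, ["WT"] * 3 + ["PATHOGENIC"])
    fpkm = _toy_fpkm([[1, 2, 3, 4]], samples)
    with pytest.raises(ValueError, match="variance"):
        test_contrast(fpkm, CONTRAST, sheet)


def test_type_one_error_controlled_on_null_data():
    """On all-NULL data the fraction of q<0.05 calls stays within the
    nominal rate plus three binomial standard errors."""
    ds = simulate_dataset(SimulationConfig(n_null=2000, n_restored=0, dispersion=0.05, seed=21))
    fpkm = fpkm_matrix(ds.counts, ds.lengths)
    out = test_contrast(fpkm, CONTRAST, ds.sample_sheet)
    frac = float((out["q"] < 0.05).mean())
    se = np.sqrt(0.05 * 0.95 / 2000)
    assert frac <= 0.05 + 3 * se


def test_power_monotone_in_effect_size():
    """Larger planted effects never lose per-gene power (grid 0.5/1.0/2.0)."""
    powers = []
    for effect in (0.5, 1.0, 2.0):
        cfg = SimulationConfig(
            n_null=1500, n_restored=500, effect_log2fc=effect, dispersion=0.05, seed=31
        )
        ds = simulate_dataset(cfg)
        fpkm = fpkm_matrix(ds.counts, ds.lengths)
        out = test_contrast(fpkm, CONTRAST, ds.sample_sheet)
        truth = ds.truth["gene_class"] == "RESTORED"
        powers.append(float((out.loc[truth.values, "q"] < 0.05).mean()))
    assert powers[0] <= powers[1] <= powers[2]
    assert powers[2] > 0.9
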