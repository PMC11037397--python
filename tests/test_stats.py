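"""Statistical machinery: TOST, epsilons, split-plot sums of squares.

The split-plot ANOVA is validated against two independent oracles: a
brute-force computation from explicit cell/marginal means on a toy design,
and pingouin's mixed ANOVA for the single-within-factor case.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from argait.stats import (
    _orthonormal_contrasts,
    bonferroni_posthoc,
    equivalence_bound,
    mixed_anova,
    tost_paired,
)


# ---------------------------------------------------------------------------
# TOST
# ---------------------------------------------------------------------------

def test_tost_hand_derived_example():
    res = tost_paired([1, 2, 3, 4, 5], [0, 0, 0, 0, 0], bound=5.0)
    assert res.mean_diff == pytest.approx(3.0)
    assert res.df == 4
    assert res.t_conventional == pytest.approx(4.243, abs=1e-3)
    assert res.t_lower == pytest.approx(11.314, abs=1e-3)
    assert res.t_upper == pytest.approx(-2.828, abs=1e-3)
    assert res.p_upper == pytest.approx(0.0237, abs=5e-4)
    assert res.equivalent


def test_tost_boundary_difference_is_not_equivalent():
    imposed = np.array([10.0, 12.0, 14.0, 16.0, 18.0, 20.0])
    executed = imposed + 3.0 + np.array([-1, 1, -1, 1, -1, 1]) * 0.5
    res = tost_paired(executed, imposed, bound=3.0)  # mean diff == bound
    assert res.t_upper == pytest.approx(0.0, abs=1e-12)
    assert res.p_upper == pytest.approx(0.5, abs=1e-12)
    assert not res.equivalent


def test_tost_null_difference_with_wide_bound():
    imposed = np.array([10.0, 12.0, 14.0, 16.0])
    executed = imposed + np.array([-1.0, 1.0, -1.0, 1.0])
    res = tost_paired(executed, imposed, bound=50.0)
    assert res.p_conventional == pytest.approx(1.0)
    assert res.equivalent


def test_tost_degenerate_zero_variance_flagged():
    res = tost_paired([1.0, 1.0, 1.0], [0.0, 0.0, 0.0], bound=2.0)
    assert res.degenerate and not res.equivalent


@settings(max_examples=100, deadline=None)
@given(
    diffs=st.lists(st.floats(-10, 10), min_size=4, max_size=12),
    bound=st.floats(0.5, 20),
    alpha=st.floats(0.01, 0.2),
)
def test_tost_verdict_consistent_with_pvalues(diffs, bound, alpha):
    executed = np.array(diffs)
    imposed = np.zeros_like(executed)
    if np.std(executed, ddof=1) < 1e-3:
        return
    res = tost_paired(executed, imposed, bound=bound, alpha=alpha)
    assert res.equivalent == (max(res.p_lower, res.p_upper) < alpha)
    # two one-sided t's always straddle the conventional t by bound/SE
    assert res.t_lower + res.t_upper == pytest.approx(2 * res.t_conventional, rel=1e-6, abs=1e-6)


def test_equivalence_bound_rule():
    assert equivalence_bound("gait_speed", 20.0) == pytest.approx(5.0)
    assert equivalence_bound("step_length", 15.0) == pytest.approx(3.75)
    assert equivalence_bound("step_length", 10.0) == pytest.approx(2.5)
    with pytest.raises(ValueError):
        equivalence_bound("gait_speed", -1.0)


# ---------------------------------------------------------------------------
# Split-plot ANOVA
# ---------------------------------------------------------------------------

def _long(y, within_names, level_sets, groups):
    """y indexed [subject, cell]; cells iterate the within product."""
    rows = []
    cells = list(itertools.product(*level_sets))
    for s in range(y.shape[0]):
        for c, cell in enumerate(cells):
            row = dict(subj=f"s{s}", grp=groups[s], y=y[s, c])
            row.update(dict(zip(within_names, cell)))
            rows.append(row)
    return pd.DataFrame(rows)


def _brute_force_split_plot(y, groups, a, b):
    """Independent sums-of-squares oracle from explicit marginal means.

    Balanced design: y[s, cell] with cells = A x B in row-major order,
    equal group sizes. Returns dict of SS per effect and error term.
    """
    n, k = y.shape
    assert k == a * b
    cube = y.reshape(n, a, b)
    glabels = np.asarray(groups)
    glevels = sorted(set(glabels))
    g = len(glevels)
    grand = cube.mean()
    m_g = {lv: cube[glabels == lv].mean() for lv in glevels}
    m_gs = cube.mean(axis=(1, 2))  # per subject
    m_i = cube.mean(axis=(0, 2))  # per A level
    m_j = cube.mean(axis=(0, 1))  # per B level
    m_ij = cube.mean(axis=0)
    m_gi = {lv: cube[glabels == lv].mean(axis=(0, 2)) for lv in glevels}
    m_gj = {lv: cube[glabels == lv].mean(axis=(0, 1)) for lv in glevels}
    m_gij = {lv: cube[glabels == lv].mean(axis=0) for lv in glevels}
    n_g = {lv: int((glabels == lv).sum()) for lv in glevels}

    ss = {}
    ss["G"] = a * b * sum(n_g[lv] * (m_g[lv] - grand) ** 2 for lv in glevels)
    ss["subj(G)"] = a * b * sum(
        (m_gs[s] - m_g[glabels[s]]) ** 2 for s in range(n)
    )
    ss["A"] = n * b * np.sum((m_i - grand) ** 2)
    ss["GA"] = b * sum(
        n_g[lv] * np.sum((m_gi[lv] - m_g[lv] - m_i + grand) ** 2) for lv in glevels
    )
    ss["err_A"] = b * sum(
        np.sum((cube[s].mean(axis=1) - m_gs[s] - m_gi[glabels[s]] + m_g[glabels[s]]) ** 2)
        for s in range(n)
    )
    ss["B"] = n * a * np.sum((m_j - grand) ** 2)
    ss["GB"] = a * sum(
        n_g[lv] * np.sum((m_gj[lv] - m_g[lv] - m_j + grand) ** 2) for lv in glevels
    )
    ss["err_B"] = a * sum(
        np.sum((cube[s].mean(axis=0) - m_gs[s] - m_gj[glabels[s]] + m_g[glabels[s]]) ** 2)
        for s in range(n)
    )
    ss["AB"] = n * np.sum((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2)
    ss["GAB"] = sum(
        n_g[lv]
        * np.sum(
            (m_gij[lv] - m_gi[lv][:, None] - m_gj[lv][None, :] + m_g[lv] - (m_ij - m_i[:, None] - m_j[None, :] + grand)) ** 2
        )
        for lv in glevels
    )
    ss["err_AB"] = sum(
        np.sum(
            (
                cube[s]
                - cube[s].mean(axis=1)[:, None]
                - cube[s].mean(axis=0)[None, :]
                + m_gs[s]
                - (m_gij[glabels[s]] - m_gi[glabels[s]][:, None] - m_gj[glabels[s]][None, :] + m_g[glabels[s]])
            )
            ** 2
        )
        for s in range(n)
    )
    return ss


def test_split_plot_ss_match_brute_force_oracle():
    """8-subject, 2-group, 2x3-within toy: every SS matches the mean-based
    brute force."""
    rng = np.random.default_rng(7)
    y = rng.normal(size=(8, 6))
    groups = ["A"] * 4 + ["B"] * 4
    df = _long(y, ["f1", "f2"], [["a1", "a2"], ["b1", "b2", "b3"]], groups)
    tab = mixed_anova(df, "y", "subj", "grp", ["f1", "f2"]).set_index("effect")
    bf = _brute_force_split_plot(y, groups, a=2, b=3)

    assert tab.loc["grp", "ss_effect"] == pytest.approx(bf["G"])
    assert tab.loc["grp", "ss_error"] == pytest.approx(bf["subj(G)"])
    assert tab.loc["f1", "ss_effect"] == pytest.approx(bf["A"])
    assert tab.loc["grp * f1", "ss_effect"] == pytest.approx(bf["GA"])
    assert tab.loc["f1", "ss_error"] == pytest.approx(bf["err_A"])
    assert tab.loc["f2", "ss_effect"] == pytest.approx(bf["B"])
    assert tab.loc["grp * f2", "ss_effect"] == pytest.approx(bf["GB"])
    assert tab.loc["f2", "ss_error"] == pytest.approx(bf["err_B"])
    assert tab.loc["f1 * f2", "ss_effect"] == pytest.approx(bf["AB"])
    assert tab.loc["grp * f1 * f2", "ss_effect"] == pytest.approx(bf["GAB"])
    assert tab.loc["f1 * f2", "ss_error"] == pytest.approx(bf["err_AB"])


def test_one_df_within_effect_equals_pooled_t_squared():
    """6-subject, 2-group, 2-level within: F equals the squared pooled
    one-sample t on the paired contrasts."""
    rng = np.random.default_rng(3)
    y = rng.normal(size=(6, 2)) + np.array([0.0, 0.8])
    groups = ["A"] * 3 + ["B"] * 3
    df = _long(y, ["w"], [["w1", "w2"]], groups)
    tab = mixed_anova(df, "y", "subj", "grp", ["w"]).set_index("effect")

    z = (y[:, 1] - y[:, 0]) / np.sqrt(2)  # orthonormal paired contrast
    group_means = np.array([z[:3].mean(), z[3:].mean()])
    resid = np.concatenate([z[:3] - group_means[0], z[3:] - group_means[1]])
    s2 = (resid**2).sum() / (6 - 2)
    t = group_means.mean() / np.sqrt(s2 / 6 * 1.0)  # balanced groups
    assert tab.loc["w", "F"] == pytest.approx(t**2, rel=1e-10)
    assert tab.loc["w", "correction"] == "none"


def test_matches_pingouin_single_within_factor():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(1)
    rows = []
    for s in range(14):
        grp = "A" if s < 7 else "B"
        for j, w in enumerate(["w1", "w2", "w3"]):
            rows.append(dict(subj=f"s{s}", grp=grp, w=w, y=rng.normal(0.4 * j, 1)))
    df = pd.DataFrame(rows)
    ours = mixed_anova(df, "y", "subj", "grp", ["w"]).set_index("effect")
    theirs = pg.mixed_anova(data=df, dv="y", within="w", subject="subj", between="grp").set_index("Source")
    assert ours.loc["w", "ss_effect"] == pytest.approx(theirs.loc["w", "SS"])
    assert ours.loc["w", "F"] == pytest.approx(theirs.loc["w", "F"])
    assert ours.loc["grp", "F"] == pytest.approx(theirs.loc["grp", "F"])
    assert ours.loc["grp * w", "F"] == pytest.approx(theirs.loc["Interaction", "F"])
    assert ours.loc["w", "eta_p_sq"] == pytest.approx(theirs.loc["w", "np2"])


def test_epsilon_tends_to_one_under_compound_symmetry():
    """Spherical (iid + subject-effect) data: epsilon_GG near 1 at n=200."""
    rng = np.random.default_rng(5)
    n = 200
    subj_effect = rng.normal(0, 2, size=n)[:, None]
    y = subj_effect + rng.normal(size=(n, 3))
    groups = ["A"] * 100 + ["B"] * 100
    df = _long(y, ["w"], [["w1", "w2", "w3"]], groups)
    tab = mixed_anova(df, "y", "subj", "grp", ["w"]).set_index("effect")
    assert tab.loc["w", "epsilon_gg"] > 0.95


def test_epsilon_lower_bound_for_maximally_nonspherical_data():
    """All contrast variance on one dimension drives epsilon to 1/(k-1)."""
    rng = np.random.default_rng(6)
    a = rng.normal(size=8)
    y = np.stack([a, np.zeros(8), -a], axis=1)  # rank-1 contrast covariance
    groups = ["A"] * 4 + ["B"] * 4
    df = _long(y, ["w"], [["w1", "w2", "w3"]], groups)
    tab = mixed_anova(df, "y", "subj", "grp", ["w"]).set_index("effect")
    assert tab.loc["w", "epsilon_gg"] == pytest.approx(0.5, abs=1e-10)


def test_correction_policy_switches_on_epsilon():
    rng = np.random.default_rng(5)
    n = 60
    y = rng.normal(size=(n, 3))  # spherical -> high epsilon -> HF
    df = _long(y, ["w"], [["w1", "w2", "w3"]], ["A"] * 30 + ["B"] * 30)
    tab = mixed_anova(df, "y", "subj", "grp", ["w"]).set_index("effect")
    assert tab.loc["w", "epsilon_gg"] > 0.750
    assert tab.loc["w", "correction"] == "HF"

    a = rng.normal(size=8)
    y2 = np.stack([a, 0.05 * rng.normal(size=8), -a], axis=1)  # near rank-1 -> GG
    df2 = _long(y2, ["w"], [["w1", "w2", "w3"]], ["A"] * 4 + ["B"] * 4)
    tab2 = mixed_anova(df2, "y", "subj", "grp", ["w"]).set_index("effect")
    assert tab2.loc["w", "epsilon_gg"] < 0.750
    assert tab2.loc["w", "correction"] == "GG"


@settings(max_examples=20, deadline=None)
@given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
def test_eta_p_sq_invariant_to_affine_rescaling(scale, shift):
    rng = np.random.default_rng(9)
    y = rng.normal(size=(8, 3)) + np.array([0.0, 0.5, 1.0])
    groups = ["A"] * 4 + ["B"] * 4
    base = _long(y, ["w"], [["w1", "w2", "w3"]], groups)
    scaled = base.assign(y=base["y"] * scale + shift)
    t1 = mixed_anova(base, "y", "subj", "grp", ["w"]).set_index("effect")
    t2 = mixed_anova(scaled, "y", "subj", "grp", ["w"]).set_index("effect")
    for eff in ("w", "grp * w"):
        assert t1.loc[eff, "eta_p_sq"] == pytest.approx(t2.loc[eff, "eta_p_sq"], rel=1e-8)


def test_missing_cell_raises_naming_the_cell():
    rng = np.random.default_rng(2)
    y = rng.normal(size=(6, 6))
    df = _long(y, ["f1", "f2"], [["a1", "a2"], ["b1", "b2", "b3"]], ["A"] * 3 + ["B"] * 3)
    df = df[~((df.f1 == "a2") & (df.f2 == "b3"))]  # the (a2, b3) cell is empty
    with pytest.raises(ValueError, match="b3"):
        mixed_anova(df, "y", "subj", "grp", ["f1", "f2"])


def test_listwise_deletion_drops_incomplete_subjects():
    rng = np.random.default_rng(2)
    y = rng.normal(size=(8, 3))
    df = _long(y, ["w"], [["w1", "w2", "w3"]], ["A"] * 4 + ["B"] * 4)
    df = df.drop(df[(df.subj == "s0") & (df.w == "w2")].index)  # s0 incomplete
    tab = mixed_anova(df, "y", "subj", "grp", ["w"])
    assert tab.attrs["n_subjects"] == 7


def test_orthonormal_contrasts_are_orthonormal():
    for k in (2, 3, 5, 7):
        q = _orthonormal_contrasts(k)
        np.testing.assert_allclose(q @ q.T, np.eye(k - 1), atol=1e-12)
        np.testing.assert_allclose(q @ np.ones(k), 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# Bonferroni post-hocs
# ---------------------------------------------------------------------------

def test_posthoc_combinatorics_three_levels():
    rng = np.random.default_rng(0)
    rows = [
        dict(subj=f"s{s}", m=m, y=rng.normal({"lo": 0, "mid": 1, "hi": 2}[m]))
        for s in range(10)
        for m in ("lo", "mid", "hi")
    ]
    tab = bonferroni_posthoc(pd.DataFrame(rows), "y", "subj", "m")
    assert len(tab) == 3 and tab.attrs["n_comparisons"] == 3


def test_posthoc_identical_level_means_give_p_one():
    rows = []
    for s, vals in enumerate([(1.0, 3.0), (2.0, 2.0), (3.0, 1.0)]):
        rows.append(dict(subj=f"s{s}", m="a", y=vals[0]))
        rows.append(dict(subj=f"s{s}", m="b", y=vals[1]))
    tab = bonferroni_posthoc(pd.DataFrame(rows), "y", "subj", "m")
    assert tab["p_bonf"].iloc[0] == pytest.approx(1.0)
    assert not tab["significant"].any()


def test_posthoc_power_for_large_modulation_effect():
    """+15 cm steps between levels with 3 cm noise, n=20: every pair
    significant in at least 95% of 200 simulated datasets."""
    rng = np.random.default_rng(11)
    all_sig = 0
    for _ in range(200):
        rows = [
            dict(subj=f"s{s}", m=m, y=15.0 * j + rng.normal(0, 3))
            for s in range(20)
            for j, m in enumerate(("lo", "mid", "hi"))
        ]
        tab = bonferroni_posthoc(pd.DataFrame(rows), "y", "subj", "m")
        all_sig += tab["significant"].all()
    assert all_sig / 200 >= 0.95
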