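"""Equivalence testing and split-plot repeated-measures ANOVA.

Two pieces of machinery:

* ``tost_paired`` — the two one-sided tests (TOST) procedure on paired
  differences. With differences d = executed - imposed, the conventional
  paired t-test asks whether mean(d) differs from 0; the TOST declares
  *equivalence* within a pre-set bound +/-Delta when (mean(d) + Delta)/SE is
  significantly positive AND (mean(d) - Delta)/SE is significantly negative.
  Bounds here follow a proportional rule: 25% of the imposed modulation
  magnitude (e.g. 5 cm/s for +/-20 cm/s speed modulations, 3.75 cm for
  +/-15 cm step-length modulations).

* ``mixed_anova`` — a split-plot (mixed) ANOVA with one between-subjects
  factor and any number of fully-crossed within-subjects factors. Each
  within-involving effect is computed on orthonormal contrast scores: the
  effect sum of squares comes from the grand mean of the scores, the
  effect-by-group interaction from group differences, and the error from the
  residual score variation (the effect x subjects-within-groups term).
  Sphericity is handled with the Greenhouse-Geisser epsilon computed from
  the pooled within-group covariance of the scores; the Huynh-Feldt
  correction is applied when epsilon_GG exceeds 0.750, otherwise
  Greenhouse-Geisser is used, and 1-df effects are never corrected. Effect
  sizes are partial eta-squared, SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TOSTResult",
    "tost_paired",
    "equivalence_bound",
    "mixed_anova",
    "bonferroni_posthoc",
]


# ---------------------------------------------------------------------------
# TOST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TOSTResult:
    n: int
    mean_diff: float
    sd_diff: float
    t_conventional: float
    df: int
    p_conventional: float
    t_lower: float
    p_lower: float
    t_upper: float
    p_upper: float
    bound: float
    alpha: float
    equivalent: bool
    degenerate: bool = False


def tost_paired(
    executed: np.ndarray,
    imposed: np.ndarray,
    bound: float,
    alpha: float = 0.05,
) -> TOSTResult:
    """Paired TOST equivalence test of executed vs imposed values.

    ``t_lower`` tests H0: mean difference <= -bound (rejected by a large
    positive t); ``t_upper`` tests H0: mean difference >= +bound (rejected by
    a large negative t). Equivalence is declared when both one-sided p's are
    below alpha, i.e. the difference lies significantly inside (-bound, +bound).
    """
    executed = np.asarray(executed, float)
    imposed = np.asarray(imposed, float)
    if executed.shape != imposed.shape:
        raise ValueError("executed and imposed must have equal length")
    n = executed.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if bound <= 0:
        raise ValueError("bound must be positive")
    d = executed - imposed
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    df = n - 1
    if sd_d == 0.0:
        return TOSTResult(
            n=n, mean_diff=mean_d, sd_diff=0.0,
            t_conventional=np.nan, df=df, p_conventional=np.nan,
            t_lower=np.nan, p_lower=np.nan, t_upper=np.nan, p_upper=np.nan,
            bound=bound, alpha=alpha, equivalent=False, degenerate=True,
        )
    se = sd_d / np.sqrt(n)
    t_conv = mean_d / se
    p_conv = 2.0 * sps.t.sf(abs(t_conv), df)
    t_lower = (mean_d + bound) / se
    p_lower = sps.t.sf(t_lower, df)  # upper tail: evidence mean_d > -bound
    t_upper = (mean_d - bound) / se
    p_upper = sps.t.cdf(t_upper, df)  # lower tail: evidence mean_d < +bound
    equivalent = max(p_lower, p_upper) < alpha
    return TOSTResult(
        n=n, mean_diff=mean_d, sd_diff=sd_d,
        t_conventional=float(t_conv), df=df, p_conventional=float(p_conv),
        t_lower=float(t_lower), p_lower=float(p_lower),
        t_upper=float(t_upper), p_upper=float(p_upper),
        bound=bound, alpha=alpha, equivalent=bool(equivalent),
    )


def equivalence_bound(task: str, modulation_magnitude: float) -> float:
    """Equivalence bound as 25% of the imposed modulation magnitude.

    E.g. speed modulations of +/-20 cm/s give a 5 cm/s bound; step-length
    modulations of +/-15 cm give 3.75 cm.
    """
    if task not in ("gait_speed", "step_length", "crossing_length", "crossing_height"):
        raise ValueError(f"unknown task {task!r}")
    if modulation_magnitude <= 0:
        raise ValueError("modulation magnitude must be positive")
    return 0.25 * modulation_magnitude


# ---------------------------------------------------------------------------
# Split-plot ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal Helmert-style contrasts, rows orthogonal to 1."""
    if k < 2:
        raise ValueError("need at least 2 levels")
    rows = []
    for i in range(1, k):
        row = np.zeros(k)
        row[:i] = 1.0
        row[i] = -float(i)
        rows.append(row / np.linalg.norm(row))
    return np.array(rows)


def _pivot_balanced(
    data: pd.DataFrame, dv: str, subject: str, between: str, within: list[str]
) -> tuple[np.ndarray, np.ndarray, list[list]]:
    """Subjects x within-cells response matrix after listwise deletion.

    Multiple observations per subject x cell are averaged. Subjects with any
    missing within-cell are dropped; a within-cell empty for *all* subjects
    is a design error and raises, naming the cell.
    """
    levels = [sorted(data[w].dropna().unique().tolist()) for w in within]
    pivot = data.pivot_table(index=[subject, between], columns=within, values=dv, aggfunc="mean")
    full_cols = list(itertools.product(*levels)) if len(within) > 1 else [
        (lv,) for lv in levels[0]
    ]
    existing = [c if isinstance(c, tuple) else (c,) for c in pivot.columns.tolist()]
    for cell in full_cols:
        if cell not in existing:
            raise ValueError(f"within-cell {dict(zip(within, cell))} has no data")
    # fixed column order matching the Kronecker construction (first factor slowest)
    ordered = [c if len(within) > 1 else c[0] for c in full_cols]
    pivot = pivot[ordered]
    pivot = pivot.dropna(axis=0, how="any")
    if pivot.shape[0] < 3:
        raise ValueError("fewer than 3 complete subjects after listwise deletion")
    y = pivot.to_numpy(float)
    groups = pivot.index.get_level_values(between).to_numpy()
    return y, groups, levels


def _f_ratio(ss: float, dfn: int, ss_err: float, dfd: int) -> float:
    """F statistic, degenerate-safe: zero error variance yields inf (or nan
    when the effect is also zero)."""
    ms, mse = ss / dfn, ss_err / dfd
    if mse == 0.0:
        return float("inf") if ms > 0 else float("nan")
    return ms / mse


def _hf_epsilon(eps_gg: float, d: int, n_subjects: int, n_groups: int) -> float:
    """Huynh-Feldt epsilon with the between-groups degrees-of-freedom
    adjustment (Lecoutre-corrected numerator, as in R's car package);
    capped at 1."""
    num = (n_subjects - n_groups + 1) * d * eps_gg - 2.0
    den = d * (n_subjects - n_groups - d * eps_gg)
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str] | str,
    epsilon_switch: float = 0.750,
) -> pd.DataFrame:
    """Split-plot ANOVA table for one between and >=1 within factors.

    Parameters
    ----------
    data : long-format table, one or more rows per subject x within-cell.
    dv, subject, between : column names.
    within : within-subject factor column name(s), fully crossed.
    epsilon_switch : apply the Huynh-Feldt correction when the
        Greenhouse-Geisser epsilon exceeds this value, else Greenhouse-Geisser.

    Returns a table with one row per effect: sums of squares, uncorrected
    and corrected degrees of freedom, the epsilons, F, p and partial
    eta-squared. Missing subjects are removed listwise (per call, i.e.
    analysis-by-analysis).
    """
    if isinstance(within, str):
        within = [within]
    y, groups, levels = _pivot_balanced(data, dv, subject, between, within)
    n_subj, n_cells = y.shape
    group_levels = sorted(pd.unique(groups).tolist())
    g = len(group_levels)
    if g < 2:
        raise ValueError("between factor needs >= 2 groups")
    group_idx = [np.flatnonzero(groups == lv) for lv in group_levels]
    n_g = np.array([idx.size for idx in group_idx], float)

    ks = [len(lv) for lv in levels]
    unit_rows = [np.full((1, k), 1.0 / np.sqrt(k)) for k in ks]
    contrast_rows = [_orthonormal_contrasts(k) for k in ks]

    rows = []

    def _one_way(z: np.ndarray) -> tuple[float, float, float, np.ndarray]:
        """Per-column group decomposition of score matrix z (n_subj x d)."""
        gm = np.array([z[idx].mean(axis=0) for idx in group_idx])  # g x d
        weighted_grand = (n_g[:, None] * gm).sum(axis=0) / n_subj
        ss_groups = float((n_g[:, None] * (gm - weighted_grand) ** 2).sum())
        resid = z - np.concatenate(
            [np.repeat(gm[j][None, :], int(n_g[j]), axis=0) for j in range(g)]
        )[_inverse_order]
        ss_resid = float((resid**2).sum())
        # unweighted-means intercept (Type III style, exact under balance)
        mu = gm.mean(axis=0)
        ss_intercept = float((mu**2).sum() * g**2 / (1.0 / n_g).sum())
        return ss_intercept, ss_groups, ss_resid, resid

    # residual computation above needs group-sorted alignment; precompute maps
    order = np.concatenate(group_idx)
    _inverse_order = np.empty_like(order)
    _inverse_order[order] = np.arange(n_subj)

    # between-subjects effect on the cell-mean scores
    u_all = unit_rows[0]
    for u in unit_rows[1:]:
        u_all = np.kron(u_all, u)
    z0 = y @ u_all.T  # n_subj x 1
    _, ss_b, ss_b_err, _ = _one_way(z0)
    df_b, df_b_err = g - 1, n_subj - g
    F_b = _f_ratio(ss_b, df_b, ss_b_err, df_b_err)
    rows.append(
        dict(
            effect=between, ss_effect=ss_b, ss_error=ss_b_err,
            df_num=df_b, df_den=df_b_err, df_num_corr=float(df_b), df_den_corr=float(df_b_err),
            epsilon_gg=np.nan, epsilon_hf=np.nan, epsilon_used=np.nan, correction="none",
            F=F_b, p=float(sps.f.sf(F_b, df_b, df_b_err)),
            eta_p_sq=ss_b / (ss_b + ss_b_err) if ss_b + ss_b_err > 0 else np.nan,
        )
    )

    m = len(within)
    for r in range(1, m + 1):
        for combo in itertools.combinations(range(m), r):
            name = " * ".join(within[j] for j in combo)
            mat = None
            for j in range(m):
                part = contrast_rows[j] if j in combo else unit_rows[j]
                mat = part if mat is None else np.kron(mat, part)
            z = y @ mat.T  # n_subj x d
            d = mat.shape[0]
            ss_e, ss_be, ss_err, resid = _one_way(z)
            df_err = d * (n_subj - g)

            s = resid.T @ resid / (n_subj - g)
            tr_s = float(np.trace(s))
            tr_s2 = float(np.trace(s @ s))
            eps_gg = (tr_s**2) / (d * tr_s2) if tr_s2 > 0 else 1.0
            eps_gg = float(np.clip(eps_gg, 1.0 / d, 1.0))
            eps_hf = _hf_epsilon(eps_gg, d, n_subj, g)

            for eff_name, ss, df_num in ((name, ss_e, d), (f"{between} * {name}", ss_be, d * (g - 1))):
                if d == 1:
                    correction, eps_used = "none", 1.0
                elif eps_gg > epsilon_switch:
                    correction, eps_used = "HF", eps_hf
                else:
                    correction, eps_used = "GG", eps_gg
                dfn_c, dfd_c = eps_used * df_num, eps_used * df_err
                F = _f_ratio(ss, df_num, ss_err, df_err)
                rows.append(
                    dict(
                        effect=eff_name, ss_effect=ss, ss_error=ss_err,
                        df_num=df_num, df_den=df_err, df_num_corr=dfn_c, df_den_corr=dfd_c,
                        epsilon_gg=eps_gg if d > 1 else np.nan,
                        epsilon_hf=eps_hf if d > 1 else np.nan,
                        epsilon_used=eps_used if d > 1 else np.nan,
                        correction=correction,
                        F=F, p=float(sps.f.sf(F, dfn_c, dfd_c)),
                        eta_p_sq=ss / (ss + ss_err) if ss + ss_err > 0 else np.nan,
                    )
                )
    table = pd.DataFrame(rows)
    table.attrs["n_subjects"] = n_subj
    table.attrs["groups"] = {lv: int(c) for lv, c in zip(group_levels, n_g)}
    return table


def bonferroni_posthoc(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    factor: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise paired t-tests between levels of one within factor.

    Values are first collapsed to one marginal mean per subject x level
    (averaging over any other factors); each pair is tested on the subjects
    providing both levels; p-values are Bonferroni-multiplied by the number
    of comparisons.
    """
    marg = data.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
    levels = sorted(marg.columns.tolist())
    pairs = list(itertools.combinations(levels, 2))
    n_comp = len(pairs)
    rows = []
    for a, b in pairs:
        paired = marg[[a, b]].dropna()
        n = len(paired)
        if n < 3:
            rows.append(dict(level_a=a, level_b=b, n=n, mean_diff=np.nan, t=np.nan,
                             df=n - 1, p=np.nan, p_bonf=np.nan, significant=False))
            continue
        diff = paired[a] - paired[b]
        t, p = sps.ttest_rel(paired[a], paired[b])
        p_bonf = min(1.0, float(p) * n_comp)
        rows.append(
            dict(
                level_a=a, level_b=b, n=n, mean_diff=float(diff.mean()),
                t=float(t), df=n - 1, p=float(p), p_bonf=p_bonf,
                significant=p_bonf < alpha,
            )
        )
    out = pd.DataFrame(rows)
    out.attrs["n_comparisons"] = n_comp
    return out
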