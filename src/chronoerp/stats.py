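"""Mixed repeated-measures ANOVA, effect sizes, follow-up tests, correlations.

The central routine is :func:`mixed_anova`, a sums-of-squares decomposition
for split-plot designs with one between-subjects factor and one or two
within-subjects factors, complete (balanced) within-cells per subject and
arbitrary group sizes.  For every within-subject effect a Greenhouse–Geisser
epsilon is estimated from the pooled within-group covariance of the subject
cell scores and reported next to the uncorrected p-value; nothing is
switched silently — the caller sees both.

Effect sizes are partial eta squared, ``SS_effect / (SS_effect + SS_error)``,
equivalently ``F·df1 / (F·df1 + df2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "mixed_anova",
    "oneway_anova",
    "partial_eta_squared",
    "pairwise_bonferroni",
    "pearson_r",
    "format_result",
]


class UnbalancedDesignError(ValueError):
    pass


class DegenerateTestWarningError(ValueError):
    pass


@dataclass(frozen=True)
class StatResult:
    effect: str
    F: float
    df_effect: float
    df_error: float
    p_uncorrected: float
    gg_epsilon: float
    p_gg: float
    partial_eta_sq: float
    ss_effect: float = float("nan")
    ss_error: float = float("nan")


def partial_eta_squared(F: float, df_effect: float, df_error: float) -> float:
    """Partial eta squared from an F statistic and its degrees of freedom."""
    if F < 0 or df_effect <= 0 or df_error <= 0:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    return F * df_effect / (F * df_effect + df_error)


def _helmert(k: int) -> np.ndarray:
    """Orthonormal contrast matrix, (k-1) x k, rows orthogonal to the constant."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -float(i)
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


def _gg_epsilon(S: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon for the contrast space C of covariance S."""
    M = C @ S @ C.T
    d = C.shape[0]
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0 or tr <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / d, tr**2 / (d * tr2))))


def _check_long_table(table, dv, subject, between, within):
    cells = table.groupby([subject] + list(within), observed=True).size()
    if (cells != 1).any():
        raise UnbalancedDesignError("duplicate subject/within-cell rows")
    per_subj = table.groupby(subject, observed=True)[within[0]].count()
    n_cells = int(np.prod([table[w].nunique() for w in within]))
    if (per_subj != n_cells).any():
        raise UnbalancedDesignError("every subject must have every within-cell")
    g_per_subj = table.groupby(subject, observed=True)[between].nunique()
    if (g_per_subj != 1).any():
        raise UnbalancedDesignError("each subject must belong to exactly one group")


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str = "group",
    within: list | tuple = ("condition",),
    return_ss: bool = False,
) -> list:
    """Split-plot ANOVA: one between factor, one or two within factors.

    Parameters
    ----------
    table : DataFrame
        Long format, one row per subject x within-cell.
    within : sequence of str
        One or two within-subject factor columns.

    Returns
    -------
    list of :class:`StatResult`
        Main effects and interactions, each tested against its proper
        split-plot error term, with GG-corrected p for within effects.
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within factors are supported")
    table = table.copy()

    # listwise exclusion of subjects with missing values (logged, not silent)
    bad = table.loc[table[dv].isna(), subject].unique()
    if len(bad):
        logger.warning("excluding %d subject(s) with missing cells: %s", len(bad), list(bad))
        table = table[~table[subject].isin(bad)]
    _check_long_table(table, dv, subject, between, within)

    w1 = within[0]
    w2 = within[1] if len(within) == 2 else None
    lev1 = list(pd.unique(table[w1]))
    lev2 = list(pd.unique(table[w2])) if w2 else ["_"]
    a, b = len(lev1), len(lev2)
    groups = list(pd.unique(table[between]))

    # D[g] : (n_g, a, b) cell arrays
    D = []
    for g in groups:
        sub = table[table[between] == g]
        subs = list(pd.unique(sub[subject]))
        arr = np.empty((len(subs), a, b))
        for si, s in enumerate(subs):
            rows = sub[sub[subject] == s]
            for ai, l1 in enumerate(lev1):
                sel = rows[rows[w1] == l1]
                for bi, l2 in enumerate(lev2):
                    v = sel if w2 is None else sel[sel[w2] == l2]
                    arr[si, ai, bi] = v[dv].iloc[0]
        D.append(arr)
    n_g = np.array([d.shape[0] for d in D])
    if (n_g < 2).any():
        raise ValueError("need at least 2 subjects per group")
    N, G = int(n_g.sum()), len(groups)

    ABGg = np.stack([d.mean(axis=0) for d in D])          # (G, a, b)
    Gg = ABGg.mean(axis=(1, 2))                            # (G,)
    mu = float(np.sum(n_g * Gg) / N)
    AB = np.tensordot(n_g, ABGg, axes=(0, 0)) / N          # (a, b)
    A = AB.mean(axis=1)
    B = AB.mean(axis=0)
    AGg = ABGg.mean(axis=2)                                # (G, a)
    BGg = ABGg.mean(axis=1)                                # (G, b)

    ss = {}
    ss["Group"] = a * b * float(np.sum(n_g * (Gg - mu) ** 2))
    ss["S(Group)"] = a * b * sum(float(((d.mean(axis=(1, 2)) - Gg[i]) ** 2).sum())
                                 for i, d in enumerate(D))
    ss[w1] = N * b * float(((A - mu) ** 2).sum())
    e_ag = AGg - A[None, :] - Gg[:, None] + mu
    ss[f"{w1}*Group"] = b * float(np.sum(n_g[:, None] * e_ag**2))
    ss_sa = 0.0
    for i, d in enumerate(D):
        SA = d.mean(axis=2)                                # (n, a)
        S = d.mean(axis=(1, 2))                            # (n,)
        ss_sa += float(((SA - S[:, None] - AGg[i][None, :] + Gg[i]) ** 2).sum())
    ss[f"{w1}*S(Group)"] = b * ss_sa

    results = []

    def add(effect, ss_eff, df_eff, ss_err, df_err, eps=1.0):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(F, df_eff, df_err)) if ms_err > 0 else float("nan")
        p_gg = float(sps.f.sf(F, eps * df_eff, eps * df_err)) if ms_err > 0 else float("nan")
        results.append(StatResult(
            effect=effect, F=float(F), df_effect=df_eff, df_error=df_err,
            p_uncorrected=p, gg_epsilon=float(eps), p_gg=p_gg,
            partial_eta_sq=ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
            ss_effect=ss_eff, ss_error=ss_err,
        ))

    # pooled within-group covariance of subject cell vectors (for GG epsilon)
    dev = np.concatenate([d.reshape(d.shape[0], a * b) - ABGg[i].reshape(1, a * b)
                          for i, d in enumerate(D)])
    S_pool = dev.T @ dev / (N - G)
    C1 = _helmert(a)
    u_b = np.ones((1, b)) / np.sqrt(b)
    u_a = np.ones((1, a)) / np.sqrt(a)
    eps1 = _gg_epsilon(S_pool, np.kron(C1, u_b)) if a > 2 else 1.0

    add("Group", ss["Group"], G - 1, ss["S(Group)"], N - G)
    add(w1, ss[w1], a - 1, ss[f"{w1}*S(Group)"], (N - G) * (a - 1), eps1)
    add(f"{w1}*Group", ss[f"{w1}*Group"], (a - 1) * (G - 1),
        ss[f"{w1}*S(Group)"], (N - G) * (a - 1), eps1)

    if w2 is not None:
        C2 = _helmert(b)
        eps2 = _gg_epsilon(S_pool, np.kron(u_a, C2)) if b > 2 else 1.0
        eps12 = _gg_epsilon(S_pool, np.kron(C1, C2)) if (a - 1) * (b - 1) > 1 else 1.0
        ss[w2] = N * a * float(((B - mu) ** 2).sum())
        e_bg = BGg - B[None, :] - Gg[:, None] + mu
        ss[f"{w2}*Group"] = a * float(np.sum(n_g[:, None] * e_bg**2))
        ss_sb = 0.0
        for i, d in enumerate(D):
            SB = d.mean(axis=1)
            S = d.mean(axis=(1, 2))
            ss_sb += float(((SB - S[:, None] - BGg[i][None, :] + Gg[i]) ** 2).sum())
        ss[f"{w2}*S(Group)"] = a * ss_sb
        e_ab = AB - A[:, None] - B[None, :] + mu
        ss[f"{w1}*{w2}"] = N * float((e_ab**2).sum())
        e_abg = (ABGg - AGg[:, :, None] - BGg[:, None, :] - AB[None]
                 + A[None, :, None] + B[None, None, :] + Gg[:, None, None] - mu)
        ss[f"{w1}*{w2}*Group"] = float(np.sum(n_g[:, None, None] * e_abg**2))
        ss_total = 0.0
        for i, d in enumerate(D):
            ss_total += float(((d - mu) ** 2).sum())
        ss[f"{w1}*{w2}*S(Group)"] = ss_total - sum(
            ss[k] for k in ss if k != f"{w1}*{w2}*S(Group)"
        )
        add(w2, ss[w2], b - 1, ss[f"{w2}*S(Group)"], (N - G) * (b - 1), eps2)
        add(f"{w2}*Group", ss[f"{w2}*Group"], (b - 1) * (G - 1),
            ss[f"{w2}*S(Group)"], (N - G) * (b - 1), eps2)
        add(f"{w1}*{w2}", ss[f"{w1}*{w2}"], (a - 1) * (b - 1),
            ss[f"{w1}*{w2}*S(Group)"], (N - G) * (a - 1) * (b - 1), eps12)
        add(f"{w1}*{w2}*Group", ss[f"{w1}*{w2}*Group"], (a - 1) * (b - 1) * (G - 1),
            ss[f"{w1}*{w2}*S(Group)"], (N - G) * (a - 1) * (b - 1), eps12)

    if return_ss:
        return results, ss
    return results


def sums_of_squares(table: pd.DataFrame, **kwargs) -> dict:
    """All SS components (effects and error strata) plus the total."""
    _, ss = mixed_anova(table, return_ss=True, **kwargs)
    out = dict(ss)
    vals = table[kwargs.get("dv", "value")].dropna().to_numpy(float)
    out["_total"] = float(((vals - vals.mean()) ** 2).sum())
    return out


def oneway_anova(values_by_group: dict) -> StatResult:
    """One-way between-subjects ANOVA with partial eta squared."""
    samples = [np.asarray(v, float) for v in values_by_group.values()]
    F, p = sps.f_oneway(*samples)
    k = len(samples)
    N = sum(len(s) for s in samples)
    return StatResult(
        effect="Group", F=float(F), df_effect=k - 1, df_error=N - k,
        p_uncorrected=float(p), gg_epsilon=1.0, p_gg=float(p),
        partial_eta_sq=partial_eta_squared(float(F), k - 1, N - k),
    )


def pairwise_bonferroni(
    data: pd.DataFrame,
    factor: str,
    comparisons: list,
    dv: str = "value",
    subject: str | None = "subject",
) -> pd.DataFrame:
    """Follow-up t-tests with Bonferroni adjustment (p_adj = min(1, p*m)).

    Paired tests when ``subject`` is given (within-subject factor), independent
    otherwise.  Zero-variance comparisons are flagged degenerate with p = NaN.
    """
    m = len(comparisons)
    rows = []
    for l1, l2 in comparisons:
        x = data.loc[data[factor] == l1]
        y = data.loc[data[factor] == l2]
        if subject is not None:
            merged = x.merge(y, on=subject, suffixes=("_1", "_2"))
            xv = merged[f"{dv}_1"].to_numpy(float)
            yv = merged[f"{dv}_2"].to_numpy(float)
            degenerate = np.allclose(xv - yv, (xv - yv)[0])
            if degenerate and not np.allclose(xv, yv):
                t, p = np.nan, np.nan
            elif np.allclose(xv, yv):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(xv, yv)
        else:
            xv, yv = x[dv].to_numpy(float), y[dv].to_numpy(float)
            degenerate = xv.std() == 0 and yv.std() == 0
            if degenerate:
                t, p = (0.0, 1.0) if np.isclose(xv.mean(), yv.mean()) else (np.nan, np.nan)
            else:
                t, p = sps.ttest_ind(xv, yv)
        if np.isnan(p) if isinstance(p, float) else False:
            logger.warning("degenerate comparison %s vs %s: p undefined", l1, l2)
        rows.append({
            "A": l1, "B": l2, "t": float(t) if t == t else np.nan,
            "p_uncorrected": float(p) if p == p else np.nan,
            "p_bonferroni": min(1.0, float(p) * m) if p == p else np.nan,
            "degenerate": bool(degenerate),
        })
    return pd.DataFrame(rows)


def pearson_r(x, y) -> tuple:
    """Product-moment correlation with two-tailed p (t transform)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def format_result(r: StatResult) -> str:
    """Render a result the way ERP papers print them."""
    return (f"{r.effect}: F({r.df_effect:g}, {r.df_error:g}) = {r.F:.2f}; "
            f"p = {r.p_uncorrected:.3g} (GG: eps = {r.gg_epsilon:.2f}, p = {r.p_gg:.3g}); "
            f"eta_p^2 = {r.partial_eta_sq:.2f}")
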