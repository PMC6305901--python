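"""Repeated-measures inference: condition normalization, rmANOVA with
sphericity handling, Spearman correlations and Benjamini-Yekutieli FDR.

The rmANOVA covers fully within-subject balanced designs with one or two
factors.  Greenhouse-Geisser correction is applied only when Mauchly's test
rejects sphericity (p < 0.05), and partial eta squared is
SS_effect / (SS_effect + SS_error) with each effect's own error term.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError, UnbalancedDesignError


# --------------------------------------------------------------------------
# condition normalization


def normalize_to_predicted(df: pd.DataFrame, value_col: str,
                           subject_col: str = "subject",
                           condition_col: str = "condition",
                           by=()) -> pd.DataFrame:
    """Express values as % of the same subject's predicted-condition mean.

    ``by`` lists extra identity columns (e.g. muscle, phase) within which the
    predicted mean is computed.  Variables whose predicted mean is zero are
    flagged and dropped from the normalized output.
    """
    by = list(by)
    key = [subject_col] + by
    pred = (df[df[condition_col] == "predicted"]
            .groupby(key)[value_col].mean().rename("_pred_mean"))
    out = df.merge(pred, left_on=key, right_index=True, how="left")
    zero = out["_pred_mean"] == 0
    if zero.any():
        dropped = out.loc[zero, key].drop_duplicates()
        out = out[~zero].copy()
        out.attrs["dropped_zero_predicted"] = dropped
    out[value_col + "_pct_predicted"] = out[value_col] / out["_pred_mean"] * 100.0
    return out.drop(columns=["_pred_mean"])


# --------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    f: float
    df_num: float
    df_den: float
    p: float                   # sphericity-corrected when applicable
    p_uncorrected: float
    gg_epsilon: float
    mauchly_w: float
    mauchly_p: float
    ss_effect: float
    ss_error: float

    @property
    def partial_eta_sq(self) -> float:
        denom = self.ss_effect + self.ss_error
        return self.ss_effect / denom if denom > 0 else 0.0


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _sphericity(scores: np.ndarray):
    """Mauchly W/p and Greenhouse-Geisser epsilon from contrast scores.

    ``scores`` is n_subjects x d where d = product of (levels - 1) for the
    effect.  For d == 1 sphericity is vacuous (W = 1, epsilon = 1).
    """
    n, d = scores.shape
    if d <= 1:
        return 1.0, 1.0, 1.0
    s = np.cov(scores, rowvar=False)
    tr = np.trace(s)
    eps = (tr ** 2) / (d * np.trace(s @ s)) if tr > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / d, 1.0))

    det = np.linalg.det(s)
    denom = (tr / d) ** d
    w = float(det / denom) if denom > 0 and det > 0 else np.finfo(float).tiny
    w = min(w, 1.0)
    f_corr = 1.0 - (2.0 * d ** 2 + d + 2.0) / (6.0 * d * (n - 1.0))
    chi2 = -(n - 1.0) * f_corr * math.log(w)
    df = d * (d + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return w, p, eps


def _effect(name, ss_eff, df_num, ss_err, df_den, scores):
    w, mauchly_p, eps = _sphericity(scores)
    ms_eff = ss_eff / df_num
    ms_err = ss_err / df_den
    f = ms_eff / ms_err if ms_err > 0 else 0.0
    p_unc = float(sps.f.sf(f, df_num, df_den)) if f > 0 else 1.0
    if mauchly_p < 0.05 and eps < 1.0:
        p = float(sps.f.sf(f, df_num * eps, df_den * eps)) if f > 0 else 1.0
    else:
        p = p_unc
    return AnovaResult(effect=name, f=f, df_num=df_num, df_den=df_den,
                       p=p, p_uncorrected=p_unc, gg_epsilon=eps,
                       mauchly_w=w, mauchly_p=mauchly_p,
                       ss_effect=ss_eff, ss_error=ss_err)


def _pivot_cells(df, dv, within, subject_col):
    """subject x cell matrix of cell means; raises on unbalanced designs."""
    cells = df.groupby([subject_col] + within, observed=True)[dv].mean().unstack(within)
    if isinstance(cells.columns, pd.MultiIndex):
        cells = cells.sort_index(axis=1)
    missing = cells.isna().any(axis=1)
    if missing.any():
        raise UnbalancedDesignError(
            "incomplete cells for subject(s): "
            + ", ".join(map(str, cells.index[missing])),
            offenders=list(cells.index[missing]),
        )
    return cells


def rm_anova(df: pd.DataFrame, dv: str, within, subject_col: str = "subject"):
    """Main and interaction effects for 1 or 2 within-subject factors.

    Returns a list of AnovaResult (one per effect).  Requires a balanced
    complete-case table; replicate observations per cell are averaged.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise InvalidParameterError("rm_anova supports 1 or 2 within factors")
    cells = _pivot_cells(df, dv, within, subject_col)
    y = cells.to_numpy(dtype=float)
    n = y.shape[0]
    if n < 2:
        raise UnbalancedDesignError("need at least 2 subjects")

    if len(within) == 1:
        levels = list(cells.columns)
        return [_anova_one_factor(y, within[0], levels)]

    a_levels = cells.columns.get_level_values(0).unique().tolist()
    b_levels = cells.columns.get_level_values(1).unique().tolist()
    a, b = len(a_levels), len(b_levels)
    y3 = y.reshape(n, a, b)
    gm = y3.mean()
    m_a = y3.mean(axis=(0, 2))
    m_b = y3.mean(axis=(0, 1))
    m_ab = y3.mean(axis=0)
    m_s = y3.mean(axis=(1, 2))
    y_sa = y3.mean(axis=2)
    y_sb = y3.mean(axis=1)

    results = []
    # main effect A with A x S error
    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_as = b * np.sum((y_sa - m_a[None, :] - m_s[:, None] + gm) ** 2)
    results.append(_effect(within[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1),
                           y_sa @ _orthonormal_contrasts(a).T))
    # main effect B with B x S error
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_bs = a * np.sum((y_sb - m_b[None, :] - m_s[:, None] + gm) ** 2)
    results.append(_effect(within[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1),
                           y_sb @ _orthonormal_contrasts(b).T))
    # interaction with A x B x S error
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    resid = (y3 - m_ab[None] - y_sa[:, :, None] - y_sb[:, None, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None] - gm)
    ss_abs = np.sum(resid ** 2)
    cab = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))
    results.append(_effect(f"{within[0]} x {within[1]}", ss_ab,
                           (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1),
                           y.reshape(n, a * b) @ cab.T))
    return results


def _anova_one_factor(y: np.ndarray, name: str, levels):
    n, k = y.shape
    gm = y.mean()
    m_a = y.mean(axis=0)
    m_s = y.mean(axis=1)
    ss_a = n * np.sum((m_a - gm) ** 2)
    ss_err = np.sum((y - m_a[None, :] - m_s[:, None] + gm) ** 2)
    scores = y @ _orthonormal_contrasts(k).T
    return _effect(name, ss_a, k - 1, ss_err, (k - 1) * (n - 1), scores)


# --------------------------------------------------------------------------
# Spearman correlation


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int
    undefined: bool = False
    fdr_reject: bool | None = None
    p_adjusted: float | None = None


def _spearman_r(x, y):
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2))
    return float(np.sum(rx * ry) / denom) if denom > 0 else np.nan


def spearman(x, y, var_x: str = "x", var_y: str = "y",
             exact_max_n: int = 10) -> CorrelationResult:
    """Two-tailed Spearman rank correlation with midrank ties.

    p-values: exact permutation enumeration for n <= ``exact_max_n``,
    otherwise the t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or y.size != n:
        raise InvalidParameterError("need paired observations with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(var_x, var_y, np.nan, np.nan, n, undefined=True)

    r = _spearman_r(x, y)
    if n <= exact_max_n:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(np.sum(rx_c ** 2) * np.sum(ry_c ** 2))
        obs = abs(np.sum(rx_c * ry_c))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(np.sum(rx_c * ry_c[list(perm)]))
            if stat >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        t = r * math.sqrt((n - 2) / max(1.0 - r * r, np.finfo(float).tiny))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(var_x, var_y, r, min(p, 1.0), n)


# --------------------------------------------------------------------------
# false discovery rate (Benjamini-Yekutieli)


def fdr_by(p_values, q: float = 0.05):
    """Benjamini-Yekutieli step-up control under arbitrary dependence.

    Returns (reject boolean array, adjusted p-values).  The harmonic-sum
    penalty c(m) = sum_{i=1..m} 1/i makes the procedure valid for any
    dependence structure; its rejection set is a subset of plain BH's.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order]

    adj = ranked * m * c_m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)

    thresh = np.arange(1, m + 1) * q / (m * c_m)
    below = np.flatnonzero(ranked <= thresh)
    reject_sorted = np.zeros(m, dtype=bool)
    if below.size:
        reject_sorted[: below[-1] + 1] = True

    reject = np.zeros(m, dtype=bool)
    p_adj = np.zeros(m)
    reject[order] = reject_sorted
    p_adj[order] = adj
    return reject, p_adj


def correlation_family(pairs, q: float = 0.05, exact_max_n: int = 10):
    """Run Spearman on (name_x, name_y, x, y) tuples and apply BY-FDR jointly."""
    results = [spearman(x, y, nx, ny, exact_max_n=exact_max_n)
               for nx, ny, x, y in pairs]
    testable = [i for i, r in enumerate(results) if not r.undefined]
    if testable:
        reject, p_adj = fdr_by([results[i].p for i in testable], q=q)
        for j, i in enumerate(testable):
            r = results[i]
            results[i] = CorrelationResult(r.var_x, r.var_y, r.r, r.p, r.n,
                                           fdr_reject=bool(reject[j]),
                                           p_adjusted=float(p_adj[j]))
    return results


# --------------------------------------------------------------------------
# reporting


def summary_table(df: pd.DataFrame, value_col: str, by, condition_col="condition",
                  conditions=("predicted", "unpredicted", "cheated")) -> pd.DataFrame:
    """Per-condition mean +/- SD table in fixed condition order."""
    g = df.groupby(list(by) + [condition_col], observed=True)[value_col]
    stats = g.agg(["mean", "std"]).reset_index()
    wide = stats.pivot(index=list(by), columns=condition_col)
    cols = []
    for cond in conditions:
        if ("mean", cond) in wide.columns:
            cols += [("mean", cond), ("std", cond)]
    wide = wide[cols]
    wide.columns = [f"{cond}_{stat}" for stat, cond in wide.columns]
    return wide.reset_index()


def render_report(tables: dict, correlations=None, path=None) -> str:
    """Human-readable text report; significance markers only on FDR rejections."""
    lines = []
    for name, tab in tables.items():
        lines.append(f"== {name} ==")
        lines.append(tab.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        lines.append("")
    if correlations:
        lines.append("== correlations ==")
        for r in correlations:
            marker = " *" if r.fdr_reject else ""
            lines.append(f"{r.var_x} vs {r.var_y}: R = {r.r:.3f}, "
                         f"p = {r.p:.4f}{marker}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text
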