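"""Statistics layer: mixed ANOVA, paired t, correlation comparison, FDR,
and 3xIQR outlier sensitivity re-runs.

The mixed ANOVA supports one between-subject factor (group) crossed with one
or two within-subject factors, computed by the classical univariate
error-stratum decomposition with sum-to-zero (sigma-restricted) coding, so
Type III hypothesis sums of squares are produced for unbalanced group sizes.
Partial eta squared obeys eta_p^2 = F*df1 / (F*df1 + df2) on every row.
For within factors with more than two levels the uncorrected F is reported
(matching the conventional degrees of freedom) with the Greenhouse-Geisser
epsilon and corrected p alongside as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mixed_anova",
    "paired_ttest",
    "pearson",
    "compare_correlations",
    "fdr_bh",
    "outlier_sensitivity",
    "TTestResult",
    "CorrComparison",
    "OutlierSensitivity",
]


# --------------------------------------------------------------------------
# Mixed ANOVA
# --------------------------------------------------------------------------


def _effect_codes(levels: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Sum-to-zero coding: one column per non-reference level."""
    n_levels = len(levels)
    cols = np.zeros((len(values), n_levels - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[values == lev, j] = 1.0
    cols[values == levels[-1], :] = -1.0
    return cols


def _type3_ss(y: np.ndarray, blocks: dict[str, np.ndarray]) -> tuple[dict[str, float], float]:
    """Drop-column Type III SS for each named block; returns (SS dict, SSE full)."""
    X_full = np.hstack(list(blocks.values()))
    sse_full = _sse(y, X_full)
    ss = {}
    for name in blocks:
        X_red = np.hstack([b for n, b in blocks.items() if n != name])
        ss[name] = _sse(y, X_red) - sse_full
    return ss, sse_full


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    if X.size == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _gg_epsilon(scores: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from pooled within-group covariance."""
    j = scores.shape[1]
    centred = scores.copy()
    for g in np.unique(groups):
        sel = groups == g
        centred[sel] -= scores[sel].mean(axis=0)
    S = centred.T @ centred / max(1, scores.shape[0] - len(np.unique(groups)))
    C = np.eye(j) - np.ones((j, j)) / j
    Sd = C @ S @ C
    tr = np.trace(Sd)
    denom = (j - 1) * np.trace(Sd @ Sd)
    if denom <= 0:
        return 1.0
    return float(min(1.0, tr**2 / denom))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str = "group",
    within: tuple[str, ...] = ("condition",),
) -> pd.DataFrame:
    """Mixed-design ANOVA with partial eta squared.

    ``data`` is long-format with one row per subject x within-cell.  Every
    subject must have a value in every within-cell and each group needs at
    least two subjects.  Returns a table with columns effect, F, df1, df2,
    p, eta_p2 (plus gg_eps / p_gg for within effects with > 1 numerator df).
    """
    within = tuple(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("supported designs have one or two within factors")
    w_levels = [pd.unique(data[w]) for w in within]
    J = len(w_levels[0])
    K = len(w_levels[1]) if len(within) == 2 else 1

    grp = data.groupby(subject)[between].agg(pd.unique)
    if any(len(g) != 1 for g in grp):
        raise ValueError("each subject must belong to exactly one group")
    subj_ids = np.array(grp.index)
    groups = np.array([g[0] for g in grp])
    g_levels = pd.unique(data[between])
    n_per_group = pd.Series(groups).value_counts()
    if (n_per_group < 2).any():
        raise ValueError("each group needs at least 2 subjects")
    N, G = len(subj_ids), len(g_levels)

    # Assemble subject x J x K value array, erroring on missing cells.
    key_cols = [subject] + list(within)
    indexed = data.set_index(key_cols)[dv]
    if indexed.index.has_duplicates:
        raise ValueError("duplicate subject x cell observations")
    Y = np.empty((N, J, K))
    missing = []
    for si, sid in enumerate(subj_ids):
        for j, wl in enumerate(w_levels[0]):
            for k in range(K):
                key = (sid, wl) if K == 1 else (sid, wl, w_levels[1][k])
                try:
                    Y[si, j, k] = indexed.loc[key]
                except KeyError:
                    missing.append(key)
    if missing:
        raise ValueError(f"missing cells for: {missing[:10]}")

    rows = []

    def _row(effect, ss_eff, df1, ss_err, df2, gg=None):
        if ss_err <= 0:
            raise ValueError(f"zero residual variance in the {effect} error stratum")
        F = (ss_eff / df1) / (ss_err / df2)
        p = float(sps.f.sf(F, df1, df2))
        eta = ss_eff / (ss_eff + ss_err)
        row = {
            "effect": effect,
            "SS": ss_eff,
            "SS_error": ss_err,
            "F": F,
            "df1": df1,
            "df2": df2,
            "p": p,
            "eta_p2": eta,
        }
        if gg is not None and df1 > 1:
            row["gg_eps"] = gg
            row["p_gg"] = float(sps.f.sf(F, df1 * gg, df2 * gg))
        rows.append(row)

    m = J * K
    subj_means = Y.mean(axis=(1, 2))
    grand = subj_means.mean()
    g_means = {g: subj_means[groups == g].mean() for g in g_levels}
    ss_between = m * sum(
        (groups == g).sum() * (g_means[g] - grand) ** 2 for g in g_levels
    )
    ss_subj = m * sum(
        ((subj_means[groups == g] - g_means[g]) ** 2).sum() for g in g_levels
    )
    _row(between, ss_between, G - 1, ss_subj, N - G)

    g_codes = _effect_codes(g_levels, groups)

    def _within_stratum(axis: int):
        w_name = within[axis]
        levels = w_levels[axis]
        n_lev = len(levels)
        t = Y.mean(axis=2) if axis == 0 else Y.mean(axis=1)  # (N, n_lev)
        c = Y.shape[2] if axis == 0 else Y.shape[1]  # levels collapsed over
        d = t - t.mean(axis=1, keepdims=True)
        y_flat = d.reshape(-1)
        lev_rep = np.tile(levels, N)
        w_codes = _effect_codes(levels, lev_rep)
        g_rep = np.repeat(g_codes, n_lev, axis=0)
        inter = np.einsum("ni,nj->nij", g_rep, w_codes).reshape(len(y_flat), -1)
        ss, sse = _type3_ss(y_flat, {"w": w_codes, "gw": inter})
        df_err = (N - G) * (n_lev - 1)
        gg = _gg_epsilon(t, groups) if n_lev > 2 else None
        _row(w_name, c * ss["w"], n_lev - 1, c * sse, df_err, gg)
        _row(f"{between} x {w_name}", c * ss["gw"], (G - 1) * (n_lev - 1), c * sse, df_err, gg)

    _within_stratum(0)
    if K > 1:
        _within_stratum(1)
        # W1 x W2 stratum
        e = (
            Y
            - Y.mean(axis=2, keepdims=True)
            - Y.mean(axis=1, keepdims=True)
            + Y.mean(axis=(1, 2), keepdims=True)[:, :, :]
        )
        y_flat = e.reshape(-1)
        cells = list(product(w_levels[0], w_levels[1]))
        w1_rep = np.tile([c0 for c0, _ in cells], N)
        w2_rep = np.tile([c1 for _, c1 in cells], N)
        w1_codes = _effect_codes(w_levels[0], np.asarray(w1_rep, dtype=object))
        w2_codes = _effect_codes(w_levels[1], np.asarray(w2_rep, dtype=object))
        ww = np.einsum("ni,nj->nij", w1_codes, w2_codes).reshape(len(y_flat), -1)
        g_rep = np.repeat(g_codes, J * K, axis=0)
        gww = np.einsum("ni,nj->nij", g_rep, ww).reshape(len(y_flat), -1)
        ss, sse = _type3_ss(y_flat, {"ww": ww, "gww": gww})
        df_err = (N - G) * (J - 1) * (K - 1)
        df_ww = (J - 1) * (K - 1)
        scores = e.reshape(N, J * K)
        gg = _gg_epsilon(scores, groups) if df_ww > 1 else None
        _row(f"{within[0]} x {within[1]}", ss["ww"], df_ww, sse, df_err, gg)
        _row(
            f"{between} x {within[0]} x {within[1]}",
            ss["gww"],
            (G - 1) * df_ww,
            sse,
            df_err,
            gg,
        )

    table = pd.DataFrame(rows)
    table.attrs["design"] = {"between": between, "within": within, "n_per_group": dict(n_per_group)}
    return table


# --------------------------------------------------------------------------
# Paired t-test
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d: float            # Cohen's d for paired data: mean diff / SD of diffs
    n: int


def paired_ttest(differences) -> TTestResult:
    """Two-sided paired t-test on per-subject differences; d = t / sqrt(n)."""
    diffs = np.asarray(differences, float)
    n = diffs.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in differences")
    mean = diffs.mean()
    t = mean / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return TTestResult(t=float(t), df=n - 1, p=p, d=float(mean / sd), n=n)


# --------------------------------------------------------------------------
# Correlations
# --------------------------------------------------------------------------


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided p-value."""
    r, p = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


@dataclass(frozen=True)
class CorrComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p: float
    q: float | None = None


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> CorrComparison:
    """Two-sample comparison of independent correlations via Fisher's r-to-z:
    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p.
    """
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 per group")
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 (transform diverges)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = float(2 * sps.norm.sf(abs(z)))
    return CorrComparison(r1=r1, n1=n1, r2=r2, n2=n2, z=float(z), p=p)


# --------------------------------------------------------------------------
# FDR
# --------------------------------------------------------------------------


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over the supplied family.

    Returns (significance flags, monotone adjusted q-values).
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, q_adj


# --------------------------------------------------------------------------
# Outlier sensitivity
# --------------------------------------------------------------------------


@dataclass
class OutlierSensitivity:
    flags: pd.DataFrame             # rows: subject, cell, value flagged
    primary: object
    rerun: object | None            # None when no outliers were flagged


def outlier_sensitivity(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    cells: list[str],
    analysis,
) -> OutlierSensitivity:
    """3xIQR extreme-outlier screen with a sensitivity re-run.

    Values outside [Q1 - 3*IQR, Q3 + 3*IQR] within each cell (quartiles by
    linear interpolation) are flagged; when any are, ``analysis`` is run
    both on the full data and with flagged subjects removed.
    """
    flagged_rows = []
    group_iter = data.groupby(cells) if cells else [((), data)]
    for key, cell in group_iter:
        vals = cell[dv].to_numpy(float)
        if vals.size < 4:
            raise ValueError(f"cell {key}: need >= 4 observations for the IQR rule")
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 3 * iqr, q3 + 3 * iqr
        out = cell[(cell[dv] < lo) | (cell[dv] > hi)]
        for _, row in out.iterrows():
            flagged_rows.append({subject: row[subject], "cell": key, dv: row[dv]})
    flags = pd.DataFrame(flagged_rows, columns=[subject, "cell", dv])
    primary = analysis(data)
    rerun = None
    if len(flags):
        keep = ~data[subject].isin(flags[subject])
        rerun = analysis(data[keep])
    return OutlierSensitivity(flags=flags, primary=primary, rerun=rerun)
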