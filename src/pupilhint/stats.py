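"""Repeated-measures statistics for the subject x condition outcome table.

The long table holds one (SNR, PPD) pair per subject x configuration x
microphone cell (quiet rows excluded). The battery comprises:

* one-way repeated-measures ANOVA per factor (the other factor averaged
  out), with the classical within-subject decomposition
  F = MS_factor / MS_error on (k-1, (k-1)(n-1)) df;
* a two-way interaction model with a subject block and a single pooled
  residual stratum, giving numerator dfs (1, 2, 2, 4) and a common
  denominator df of (n-1)(ab-1) - i.e. 56 for 8 subjects in a 3x3
  crossing - matching the conditional-F layout of an nlme-style
  random-intercept fit on balanced data;
* Shapiro-Wilk on ANOVA residuals;
* Games-Howell pairwise post hoc tests (Welch SEs, Welch-Satterthwaite
  df, studentized-range p);
* a Bonferroni-adjusted significance threshold;
* Spearman rank correlation with an exact permutation p-value for
  n <= 10 pairs;
* the pure-tone average over 500/1000/2000/4000 Hz.

No sphericity correction is applied by default; Greenhouse-Geisser is
available as an option on the one-way test.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import NOISE_CONFIGURATIONS

ANOVA_COLUMNS = ("term", "num_df", "den_df", "F", "p")


# ---------------------------------------------------------------------------
# long-table plumbing

def _pivot_complete(table: pd.DataFrame, response: str, index: str,
                    columns) -> pd.DataFrame:
    """Pivot subject x factor-level means, rejecting incomplete crossings."""
    df = table[table["configuration"] != "S0"]
    wide = df.pivot_table(index=index, columns=columns, values=response,
                          aggfunc="mean")
    if wide.isna().any().any():
        missing = [
            f"{subj} x {col}" for col in wide.columns
            for subj in wide.index[wide[col].isna()]
        ]
        raise ValueError(f"incomplete crossing; missing cell(s): {missing}")
    return wide


# ---------------------------------------------------------------------------
# repeated-measures ANOVA cores (vectorised over leading axes)

def _rm_oneway_core(y: np.ndarray):
    """Within-subject one-way decomposition on y[..., subject, level]."""
    n, k = y.shape[-2], y.shape[-1]
    grand = y.mean(axis=(-2, -1), keepdims=True)
    subj = y.mean(axis=-1, keepdims=True)
    lev = y.mean(axis=-2, keepdims=True)
    ss_factor = n * ((lev - grand) ** 2).sum(axis=(-2, -1))
    ss_subject = k * ((subj - grand) ** 2).sum(axis=(-2, -1))
    ss_total = ((y - grand) ** 2).sum(axis=(-2, -1))
    ss_error = ss_total - ss_factor - ss_subject
    df1, df2 = k - 1, (k - 1) * (n - 1)
    tol = 1e-12 * (ss_total + 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_factor / df1) / (ss_error / df2)
    F = np.where(ss_factor <= tol, 0.0, F)
    p = sps.f.sf(F, df1, df2)
    return F, p, df1, df2, ss_factor, ss_error


def _rm_twoway_core(y: np.ndarray):
    """Subject-blocked two-way decomposition with pooled residual.

    y[..., subject, a, b]; returns per-term F/p for intercept, A, B, AxB
    against the pooled residual with df n*a*b - 1 - (n-1) - (a-1) - (b-1)
    - (a-1)(b-1).
    """
    n, a, b = y.shape[-3], y.shape[-2], y.shape[-1]
    N = n * a * b
    grand = y.mean(axis=(-3, -2, -1), keepdims=True)
    m_s = y.mean(axis=(-2, -1), keepdims=True)
    m_a = y.mean(axis=(-3, -1), keepdims=True)
    m_b = y.mean(axis=(-3, -2), keepdims=True)
    m_ab = y.mean(axis=-3, keepdims=True)
    ss_subject = a * b * ((m_s - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_a = n * b * ((m_a - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_b = n * a * ((m_b - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_ab = n * ((m_ab - m_a - m_b + grand) ** 2).sum(axis=(-3, -2, -1))
    ss_total = ((y - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_resid = ss_total - ss_subject - ss_a - ss_b - ss_ab
    den_df = N - 1 - (n - 1) - (a - 1) - (b - 1) - (a - 1) * (b - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ms_resid = ss_resid / den_df
        grand_flat = y.mean(axis=(-3, -2, -1))
        F_int = N * grand_flat ** 2 / ms_resid
        F_a = (ss_a / (a - 1)) / ms_resid
        F_b = (ss_b / (b - 1)) / ms_resid
        F_ab = (ss_ab / ((a - 1) * (b - 1))) / ms_resid
    tol = 1e-12 * (ss_total + 1e-300)
    terms = {
        "(Intercept)": (1, N * grand_flat ** 2, F_int),
        "A": (a - 1, ss_a, F_a),
        "B": (b - 1, ss_b, F_b),
        "A:B": ((a - 1) * (b - 1), ss_ab, F_ab),
    }
    out = {}
    for name, (df1, ss_term, F) in terms.items():
        F = np.where(np.asarray(ss_term) <= tol, 0.0, F)
        out[name] = (df1, den_df, F, sps.f.sf(F, df1, den_df))
    return out, ss_resid, den_df


def rm_anova_oneway(table: pd.DataFrame, response: str, factor: str,
                    gg_correction: bool = False):
    """One-way repeated-measures ANOVA on the long table.

    Values are averaged over the other factor so every subject
    contributes one value per level of ``factor``. Returns
    ``(anova_table, residuals)``; the residuals (cell minus subject and
    level effects) feed the Shapiro-Wilk normality check.
    """
    if factor not in ("configuration", "microphone"):
        raise ValueError("factor must be 'configuration' or 'microphone'")
    wide = _pivot_complete(table, response, "subject", factor)
    y = wide.to_numpy()
    F, p, df1, df2, ss_f, ss_e = _rm_oneway_core(y)
    if gg_correction:
        eps = _greenhouse_geisser_epsilon(y)
        p = float(sps.f.sf(F, df1 * eps, df2 * eps))
    out = pd.DataFrame([(factor, df1, df2, float(F), float(p))],
                       columns=list(ANOVA_COLUMNS))
    resid = y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True) + y.mean()
    return out, resid.ravel()


def _greenhouse_geisser_epsilon(y: np.ndarray) -> float:
    k = y.shape[1]
    cov = np.cov(y.T)
    mean_diag = np.trace(cov) / k
    eps = (k * mean_diag - cov.mean()) ** 2 / (
        (k - 1) * ((cov ** 2).sum() - 2 * k * (cov.mean(1) ** 2).sum()
                   + k ** 2 * cov.mean() ** 2))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_twoway_interaction(table: pd.DataFrame, response: str):
    """Two-way interaction model with a subject block and pooled residual.

    For 8 subjects in a full 3x3 crossing the layout is numerator dfs
    (1, 2, 2, 4) against a common denominator df of 56. Returns
    ``(anova_table, residuals)``.
    """
    wide = _pivot_complete(table, response, "subject",
                           ["configuration", "microphone"])
    configs = sorted({c for c, _ in wide.columns})
    mics = sorted({m for _, m in wide.columns})
    a, b = len(configs), len(mics)
    y = np.stack([
        np.stack([wide[(c, m)].to_numpy() for m in mics], axis=-1)
        for c in configs], axis=-2)  # (subject, a, b)
    terms, ss_resid, den_df = _rm_twoway_core(y)
    names = {"A": "Sound configuration", "B": "Microphone",
             "A:B": "Configuration/microphone"}
    rows = [(names.get(k, k), df1, den_df, float(F), float(p))
            for k, (df1, _dden, F, p) in terms.items()]
    out = pd.DataFrame(rows, columns=list(ANOVA_COLUMNS))
    # fitted cell = subject effect + cell mean (A, B and AxB are all in m_ab)
    resid = y - y.mean(axis=(1, 2), keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    return out, resid.ravel()


def shapiro_wilk(residuals) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) for 3 <= n <= 5000 residuals."""
    x = np.asarray(residuals, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# Games-Howell

def _gh_pairstats(means, variances, ns):
    """Vectorised Welch pair statistics for Games-Howell.

    Inputs are (..., k) arrays; returns per-pair (i, j, diff, se, df)
    stacked on the last axis as dicts of arrays plus the pair index list.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = means.shape[-1]
    pairs = list(itertools.combinations(range(k), 2))
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    vi = variances[..., i] / ns[..., i]
    vj = variances[..., j] / ns[..., j]
    diff = means[..., i] - means[..., j]
    se = np.sqrt(vi + vj)
    df = (vi + vj) ** 2 / (vi ** 2 / (ns[..., i] - 1) + vj ** 2 / (ns[..., j] - 1))
    return pairs, diff, se, df


def games_howell(groups) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for >= 2 independent samples.

    Welch standard errors and Welch-Satterthwaite df accommodate unequal
    variances; p-values come from the studentized-range distribution
    with q = |diff| / se * sqrt(2). The result is symmetric in group
    order (only |t| enters the p-value).
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for idx, g in enumerate(samples):
        if len(g) < 2:
            raise ValueError(f"group {idx} has fewer than 2 observations")
    k = len(samples)
    means = np.array([g.mean() for g in samples])
    variances = np.array([g.var(ddof=1) for g in samples])
    ns = np.array([len(g) for g in samples])
    pairs, diff, se, df = _gh_pairstats(means, variances, ns)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
        q = np.abs(t) * np.sqrt(2.0)
    p = np.where(se > 0, sps.studentized_range.sf(q, k, df), 1.0)
    p = np.where(np.abs(diff) == 0, 1.0, p)
    return pd.DataFrame({
        "group_i": [pairs[m][0] for m in range(len(pairs))],
        "group_j": [pairs[m][1] for m in range(len(pairs))],
        "mean_diff": diff, "se": se, "t": t, "df": df,
        "p_adjusted": np.clip(p, 0.0, 1.0),
    })


def studentized_range_crit(k: int, df, alpha: float = 0.05) -> np.ndarray:
    """Critical q for the studentized range, interpolated over a df grid.

    ``sf(q, k, df) < alpha  iff  q > crit`` because the survival
    function is monotone; interpolation over ~1% df spacing keeps the
    critical value accurate to well under 0.1%.
    """
    df = np.asarray(df, dtype=float)
    lo, hi = float(np.min(df)), float(np.max(df))
    if np.isclose(lo, hi):
        return np.full(df.shape, sps.studentized_range.ppf(1 - alpha, k, lo))
    grid = np.geomspace(max(lo, 1.01), hi, 60)
    crit = sps.studentized_range.ppf(1 - alpha, k, grid)
    return np.interp(df, grid, crit)


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Familywise significance threshold alpha/m for m comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Spearman

@lru_cache(maxsize=8)
def _spearman_exact_null(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (no ties)."""
    ranks = np.arange(1, n + 1)
    denom = n * (n ** 2 - 1)
    perms = np.array(list(itertools.permutations(ranks)), dtype=np.int16)
    d2 = ((perms - ranks) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / denom
    return np.sort(np.abs(rho))


def spearman(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with a small-sample exact p-value.

    rho uses midranks for ties. For n <= ``exact_max_n`` with no ties in
    either variable, the two-sided p is the exact permutation
    probability P(|rho_perm| >= |rho|); otherwise the t approximation
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx, sy = np.std(rx), np.std(ry)
    if sx == 0 or sy == 0:
        raise ValueError("a constant variable has no rank correlation")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    ties = len(np.unique(rx)) < n or len(np.unique(ry)) < n
    if n <= exact_max_n and not ties:
        null = _spearman_exact_null(n)
        # count permutations at least as extreme, tolerating float fuzz
        idx = np.searchsorted(null, abs(rho) - 1e-12, side="left")
        p = (len(null) - idx) / len(null)
    else:
        rho_c = min(max(rho, -1.0), 1.0)
        if abs(rho_c) == 1.0:
            p = 0.0
        else:
            t = rho_c * np.sqrt((n - 2) / (1.0 - rho_c ** 2))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


def pure_tone_average(thresholds) -> float:
    """Mean hearing threshold (dB HL) across 500/1000/2000/4000 Hz."""
    t = np.asarray(thresholds, dtype=float)
    if t.shape != (4,) or np.any(np.isnan(t)):
        raise ValueError("need exactly four thresholds (500/1000/2000/4000 Hz)")
    return float(np.mean(t))
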