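"""Statistical layer: one-sample t-tests against chance, repeated-measures
and mixed ANOVA with Greenhouse-Geisser correction, Bonferroni-adjusted
pairwise comparisons, partial eta squared, and observed power.

The ANOVA follows the classical univariate repeated-measures approach:
each within-subject effect is projected onto orthonormal within-cell
contrasts and tested against its own subject-by-effect error stratum.
With a between-subject factor and unequal group sizes, within-effect sums
of squares use unweighted (Type III-equivalent) marginal means, the
convention under which the reference marginals (e.g. unweighted task and
group means) reproduce exactly.

Observed power follows the SPSS convention: noncentrality lambda = F * df1
evaluated against the alpha-level critical F.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import null_space

__all__ = [
    "TTestResult",
    "one_sample_t",
    "one_sample_t_from_summary",
    "rm_anova",
    "mixed_anova",
    "gg_epsilon",
    "partial_eta_sq",
    "observed_power",
    "bonferroni",
    "pairwise_bonferroni",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    sd: float
    n: int
    mu: float


def one_sample_t_from_summary(mean: float, sd: float, n: int,
                              mu: float = 50.0) -> TTestResult:
    """One-sample t from summary statistics (sd with the n-1 denominator).

    Zero variance with ``mean != mu`` is flagged as t = +-inf with p = 0
    (documented convention); ``mean == mu`` gives t = 0, p = 1.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    if sd == 0:
        if mean == mu:
            return TTestResult(0.0, df, 1.0, mean, sd, n, mu)
        t = math.inf if mean > mu else -math.inf
        return TTestResult(t, df, 0.0, mean, sd, n, mu)
    t = (mean - mu) / (sd / math.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), df))
    return TTestResult(float(t), df, p, mean, sd, n, mu)


def one_sample_t(values: Sequence[float], mu: float = 50.0) -> TTestResult:
    """Two-tailed one-sample t-test of ``values`` against ``mu``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2 observations")
    return one_sample_t_from_summary(float(x.mean()), float(x.std(ddof=1)),
                                     int(x.size), mu)


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    return F * df1 / (F * df1 + df2)


def observed_power(F: float, df1: float, df2: float,
                   alpha: float = 0.05) -> float:
    """Post-hoc power under the noncentral F with lambda = F * df1."""
    if F < 0:
        raise ValueError("F must be non-negative")
    fcrit = sps.f.isf(alpha, df1, df2)
    lam = F * df1
    if lam == 0:  # scipy's ncf is numerically unreliable at zero noncentrality
        return alpha
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def bonferroni(p_values: Sequence[float] | float,
               m: int | None = None) -> np.ndarray | float:
    """Bonferroni adjustment: p -> min(1, m * p)."""
    scalar = np.isscalar(p_values)
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    adj = np.minimum(1.0, m * p)
    return float(adj[0]) if scalar else adj


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-cell covariance.

    Computed from the covariance of orthonormal contrast scores and clipped
    to [1/(k-1), 1]; k < 3 (sphericity trivially satisfied) returns 1.
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if cov.shape != (k, k):
        raise ValueError("covariance must be square")
    if k < 3:
        return 1.0
    C = null_space(np.ones((1, k)))  # k x (k-1), orthonormal
    V = C.T @ cov @ C
    eps = np.trace(V) ** 2 / ((k - 1) * np.trace(V @ V))
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


# ---------------------------------------------------------------------------
# ANOVA machinery


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the contrast space (sum-to-zero)."""
    return null_space(np.ones((1, k)))


def _wide_cells(data: pd.DataFrame, dv: str, within: Sequence[str],
                subject: str) -> tuple[pd.DataFrame, list[tuple], list[int]]:
    """Pivot long data to subjects x cells; raises on missing cells."""
    levels = [list(pd.unique(data[f])) for f in within]
    cells = list(itertools.product(*levels))
    wide = data.pivot_table(index=subject, columns=list(within), values=dv,
                            aggfunc="mean", observed=True)
    # enforce the cell order of `cells`
    cols = [c if len(within) > 1 else c[0] for c in cells]
    missing = [c for c in cols if c not in wide.columns]
    if missing:
        raise ValueError(f"missing design cell(s): {missing}")
    wide = wide[cols]
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing observations in cell(s): {bad}")
    return wide, cells, [len(lv) for lv in levels]


def _effect_projection(effect: Sequence[str], within: Sequence[str],
                       k_levels: Sequence[int]) -> np.ndarray:
    """K x q projection for a within effect: Kronecker product of contrast
    matrices (factor in the effect) and averaging vectors (factor not)."""
    mats = []
    for f, k in zip(within, k_levels):
        if f in effect:
            mats.append(_orthonormal_contrasts(k))
        else:
            mats.append(np.full((k, 1), 1 / math.sqrt(k)))
    W = mats[0]
    for m in mats[1:]:
        W = np.kron(W, m)
    return W


def _effect_label(effect: Sequence[str]) -> str:
    return " * ".join(effect)


def rm_anova(data: pd.DataFrame, dv: str, within: Sequence[str],
             subject: str = "subject") -> pd.DataFrame:
    """Fully repeated-measures ANOVA (all factors within-subject).

    ``data`` is long-format with one observation per subject x cell.
    Returns a tidy table with one row per effect: SS, SS_error, df1, df2,
    F, Greenhouse-Geisser epsilon, uncorrected and epsilon-adjusted p,
    partial eta squared and observed power.
    """
    return mixed_anova(data, dv=dv, between=None, within=within,
                       subject=subject)


def mixed_anova(data: pd.DataFrame, dv: str, between: str | None,
                within: Sequence[str], subject: str = "subject") -> pd.DataFrame:
    """Mixed ANOVA with one between-subject factor and >= 1 within factors.

    Each subject must contribute one observation per within-cell; groups
    may be unbalanced (unweighted-means partitioning for within effects).
    Greenhouse-Geisser epsilon is estimated from the pooled within-group
    contrast covariance and applied to effects with more than one numerator
    degree of freedom; two-level effects have epsilon = 1 by construction.
    """
    within = list(within)
    if not within:
        raise ValueError("need at least one within-subject factor")
    wide, cells, k_levels = _wide_cells(data, dv, within, subject)

    if between is not None:
        group_of = (data[[subject, between]].drop_duplicates()
                    .set_index(subject)[between])
        groups = list(pd.unique(data[between]))
        membership = [np.flatnonzero(group_of.loc[wide.index] == g)
                      for g in groups]
        if any(len(m) < 2 for m in membership):
            raise ValueError("need >= 2 subjects per group")
    else:
        groups = [None]
        membership = [np.arange(len(wide))]

    Y = wide.to_numpy(dtype=float)
    N = Y.shape[0]
    G = len(groups)
    n_g = np.array([len(m) for m in membership])

    rows = []

    # between-subject stratum: project onto the cell average
    K = Y.shape[1]
    y_avg = Y.mean(axis=1) * math.sqrt(K)
    gmeans = np.array([y_avg[m].mean() for m in membership])
    ss_sub_err = sum(((y_avg[m] - gm) ** 2).sum()
                     for m, gm in zip(membership, gmeans))
    df_sub_err = N - G
    if between is not None:
        wmean = (n_g * gmeans).sum() / N
        ss_b = float((n_g * (gmeans - wmean) ** 2).sum())
        df_b = G - 1
        F = (ss_b / df_b) / (ss_sub_err / df_sub_err)
        p = float(sps.f.sf(F, df_b, df_sub_err))
        rows.append(dict(effect=between, SS=ss_b, SS_error=float(ss_sub_err),
                         df1=df_b, df2=df_sub_err, F=F, eps=1.0, p=p,
                         p_gg=p, eta_p2=ss_b / (ss_b + ss_sub_err),
                         power=observed_power(F, df_b, df_sub_err)))

    # within strata
    for r in range(1, len(within) + 1):
        for effect in itertools.combinations(within, r):
            W = _effect_projection(effect, within, k_levels)
            Z = Y @ W  # subjects x q
            q = Z.shape[1]
            zbar_g = np.stack([Z[m].mean(axis=0) for m in membership])
            resid = np.concatenate([Z[m] - zbar_g[i]
                                    for i, m in enumerate(membership)])
            ss_err = float((resid ** 2).sum())
            df_err = (N - G) * q

            # pooled within-group contrast covariance -> GG epsilon
            if q > 1 and N - G > 1:
                V = resid.T @ resid / (N - G)
                eps = float(min(1.0, max(np.trace(V) ** 2 /
                                         (q * np.trace(V @ V)), 1.0 / q)))
            else:
                eps = 1.0

            # unweighted grand mean of group means (Type III-equivalent)
            mu = zbar_g.mean(axis=0)
            ss_eff = float(G ** 2 / (1.0 / n_g).sum() * (mu ** 2).sum())
            F = (ss_eff / q) / (ss_err / df_err)
            p = float(sps.f.sf(F, q, df_err))
            p_gg = float(sps.f.sf(F, eps * q, eps * df_err))
            rows.append(dict(effect=_effect_label(effect), SS=ss_eff,
                             SS_error=ss_err, df1=q, df2=df_err, F=F,
                             eps=eps, p=p, p_gg=p_gg,
                             eta_p2=ss_eff / (ss_eff + ss_err),
                             power=observed_power(F, q, df_err)))

            if between is not None:
                zbar_w = (n_g[:, None] * zbar_g).sum(axis=0) / N
                ss_int = float((n_g[:, None] * (zbar_g - zbar_w) ** 2).sum())
                df_int = (G - 1) * q
                F = (ss_int / df_int) / (ss_err / df_err)
                p = float(sps.f.sf(F, df_int, df_err))
                p_gg = float(sps.f.sf(F, eps * df_int, eps * df_err))
                rows.append(dict(
                    effect=_effect_label((between,) + effect), SS=ss_int,
                    SS_error=ss_err, df1=df_int, df2=df_err, F=F, eps=eps,
                    p=p, p_gg=p_gg, eta_p2=ss_int / (ss_int + ss_err),
                    power=observed_power(F, df_int, df_err)))

    return pd.DataFrame(rows)


def pairwise_bonferroni(data: pd.DataFrame, dv: str, factor: str,
                        subject: str = "subject",
                        m: int | None = None) -> pd.DataFrame:
    """Paired t-tests between all level pairs of ``factor`` (collapsing any
    other repeated cells per subject), Bonferroni-adjusted."""
    wide = data.pivot_table(index=subject, columns=factor, values=dv,
                            aggfunc="mean", observed=True)
    levels = list(wide.columns)
    rows = []
    raw_ps = []
    for a, b in itertools.combinations(levels, 2):
        d = (wide[a] - wide[b]).dropna()
        t, p = sps.ttest_1samp(d, 0.0)
        rows.append(dict(contrast=f"{a} - {b}", mean_diff=float(d.mean()),
                         t=float(t), df=len(d) - 1, p_raw=float(p)))
        raw_ps.append(float(p))
    n_comp = m if m is not None else len(rows)
    for row, p in zip(rows, raw_ps):
        row["p_adj"] = float(bonferroni(p, n_comp))
    return pd.DataFrame(rows)
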