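"""Differential expression for the three-group design.

Implements quantile normalization, empirical-Bayes moderated t-statistics
(gene-wise variances shrunk toward a common prior estimated by
method-of-moments on log sample variances), Benjamini-Hochberg adjustment,
and selection of the differentially expressed gene universe as the union of
the three pairwise contrasts.

Groups are labelled ``control``, ``MCAO`` and ``MCAO_NRG1`` throughout:
sham controls, middle-cerebral-artery-occlusion injury, and injury plus
neuregulin-1 treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

GROUPS = ("control", "MCAO", "MCAO_NRG1")
#: The three pairwise contrasts, each (test group, reference group).
CONTRASTS = (("MCAO", "control"), ("MCAO_NRG1", "control"), ("MCAO_NRG1", "MCAO"))

_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class ModeratedTParams:
    """Hyperparameters of the variance prior: s_g^2 ~ s0_sq * d0 / chi^2_d0.

    ``d0`` is the prior degrees of freedom (may be ``inf`` when variances are
    fully shared) and ``s0_sq`` the prior variance in (log2 units)^2.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError(f"d0 must be >= 0, got {self.d0}")
        if self.d0 > 0 and not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0 when d0 > 0")


def _check_design(matrix: pd.DataFrame, design: Mapping[str, str]) -> pd.Series:
    design = pd.Series(dict(design))
    missing = [s for s in matrix.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    design = design.loc[list(matrix.columns)]
    bad = set(design) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
    absent = [g for g in GROUPS if g not in set(design)]
    if absent:
        raise ValueError(f"groups missing from design: {absent}")
    return design


def normalize_quantile(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean order-statistic distribution.

    After normalization every column holds the same multiset of values (the
    across-sample means of the sorted columns), assigned by within-column
    rank; within-column rank orders are unchanged.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    x = matrix.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    ranks = np.argsort(order, axis=0, kind="stable")
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = mean_sorted[ranks]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _residual_variances(
    matrix: pd.DataFrame, design: pd.Series
) -> tuple[np.ndarray, float]:
    """Pooled within-group residual variance per gene and its df (N - #groups)."""
    x = matrix.to_numpy(dtype=float)
    n_total = x.shape[1]
    rss = np.zeros(x.shape[0])
    for g in GROUPS:
        cols = np.flatnonzero((design == g).to_numpy())
        if cols.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
        sub = x[:, cols]
        rss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = float(n_total - len(GROUPS))
    return rss / df, df


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone branch)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_prior(matrix: pd.DataFrame, design: Mapping[str, str]) -> ModeratedTParams:
    """Estimate the variance-prior hyperparameters (d0, s0_sq).

    Method of moments on log residual variances: for s_g^2 with d_g df drawn
    from a scaled inverse-chi-square prior, e_g = log s_g^2 - psi(d_g/2) +
    log(d_g/2) has mean log s0^2 - psi(d0/2) + log(d0/2) and the variance of
    log s_g^2 exceeds trigamma(d_g/2) by trigamma(d0/2). Zero variances are
    floored at 1e-8. When the observed spread does not exceed the chi-square
    sampling spread, d0 = +inf (variance fully shared).
    """
    design = _check_design(matrix, design)
    s2, df = _residual_variances(matrix, design)
    if np.all(s2 <= _VAR_FLOOR):
        raise ValueError("all residual variances are zero; prior is undefined")
    s2 = np.maximum(s2, _VAR_FLOOR)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    mean_e = float(e.mean())
    if len(e) < 2:
        return ModeratedTParams(d0=np.inf, s0_sq=float(np.exp(mean_e)))
    var_e = float(e.var(ddof=1))
    excess = var_e - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return ModeratedTParams(d0=np.inf, s0_sq=float(np.exp(mean_e)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModeratedTParams(d0=d0, s0_sq=s0_sq)


def moderated_t(
    matrix: pd.DataFrame,
    design: Mapping[str, str],
    contrast: tuple[str, str],
    params: ModeratedTParams,
) -> pd.DataFrame:
    """Moderated two-sample t-test for one pairwise contrast.

    The posterior variance is s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g) and
    t~_g = (mean_A - mean_B) / (s~_g * sqrt(1/n_A + 1/n_B)), with two-sided
    p-values from a t distribution on d0 + d_g degrees of freedom. At d0 = 0
    this is the ordinary pooled-variance t; at d0 = inf every gene uses s0^2.

    Returns a frame indexed by gene with columns ``log2fc, s2, s2_post, t,
    df_total, p, q`` (q is the BH-adjusted p within this contrast).
    """
    design = _check_design(matrix, design)
    a, b = contrast
    if a == b or a not in GROUPS or b not in GROUPS:
        raise ValueError(f"contrast must name two distinct groups, got {contrast}")
    s2, df = _residual_variances(matrix, design)
    x = matrix.to_numpy(dtype=float)
    cols_a = np.flatnonzero((design == a).to_numpy())
    cols_b = np.flatnonzero((design == b).to_numpy())
    diff = x[:, cols_a].mean(axis=1) - x[:, cols_b].mean(axis=1)

    d0, s0 = params.d0, params.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / cols_a.size + 1.0 / cols_b.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    t = np.where(diff == 0, 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.minimum(p, 1.0)
    return pd.DataFrame(
        {
            "log2fc": diff,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "df_total": df_total,
            "p": p,
            "q": bh_adjust(p),
        },
        index=matrix.index,
    )


def moderated_f(
    matrix: pd.DataFrame, design: Mapping[str, str], params: ModeratedTParams
) -> pd.DataFrame:
    """Moderated one-way F-test across the three groups (alternative DE rule).

    F_g = (between-group SS / (k-1)) / s~_g^2 with p from F(k-1, d0 + d_g).
    """
    design = _check_design(matrix, design)
    s2, df = _residual_variances(matrix, design)
    x = matrix.to_numpy(dtype=float)
    grand = x.mean(axis=1)
    ssb = np.zeros(x.shape[0])
    for g in GROUPS:
        cols = np.flatnonzero((design == g).to_numpy())
        ssb += cols.size * (x[:, cols].mean(axis=1) - grand) ** 2
    k = len(GROUPS)
    d0, s0 = params.d0, params.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df2 = np.inf
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df2 = d0 + df
    f = (ssb / (k - 1)) / s2_post
    if np.isinf(df2):
        p = stats.chi2.sf(f * (k - 1), k - 1)
    else:
        p = stats.f.sf(f, k - 1, df2)
    return pd.DataFrame({"F": f, "p": p, "q": bh_adjust(p)}, index=matrix.index)


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} min(1, p_(j) * n / j) over the sorted p-values.
    """
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def select_de_genes(
    results: Mapping[tuple[str, str], pd.DataFrame],
    alpha: float,
    use_adjusted: bool = True,
) -> list[str]:
    """Differentially expressed gene universe: union over pairwise contrasts.

    A gene enters the universe if its BH-adjusted p (or raw p when
    ``use_adjusted`` is False) is below ``alpha`` in at least one contrast.
    Returned in the gene order of the first result frame.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    col = "q" if use_adjusted else "p"
    selected: set[str] = set()
    order: list[str] = []
    for res in results.values():
        if not order:
            order = list(res.index)
        selected.update(res.index[res[col] < alpha])
    return [g for g in order if g in selected]


def delta_ct(ct_target: float | Sequence[float], ct_reference: float | Sequence[float]) -> float:
    """qPCR delta-Ct: Ct(gene of interest) - Ct(housekeeping reference).

    Sequences are averaged before differencing.
    """
    return float(np.mean(ct_target) - np.mean(ct_reference))
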