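"""Per-cohort differential expression between responders and non-responders.

The comparison of interest is "up in non-responders": every fold change is
mean(nonresponder) - mean(responder) on the log2 scale. Two test statistics
are provided:

* an empirical-Bayes moderated t in which each gene's pooled variance is
  shrunk toward a prior ``s0^2`` with prior degrees of freedom ``d0``,
  estimated across genes by moment matching of log variances against a
  scaled-F model (digamma/trigamma inversion);
* a Welch t with Satterthwaite degrees of freedom, which makes no
  equal-variance assumption and needs no cross-gene prior.

One-tailed p-values (upper tail = up in non-responders) are carried along
for downstream combination across cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

RESPONDER = "responder"
NONRESPONDER = "nonresponder"

__all__ = [
    "ExpressionStudy",
    "ComparisonResult",
    "ModeratedTParams",
    "log2_fold_changes",
    "estimate_prior",
    "moderated_t",
    "welch_t",
]


@dataclass
class ExpressionStudy:
    """One cohort: a log2 expression matrix plus a binary response label.

    Parameters
    ----------
    study_id
        Cohort identifier.
    expr
        Genes x samples matrix of finite log2 expression values.
    labels
        Sample -> {"responder", "nonresponder"} mapping covering every column.
    comparison_id
        Distinguishes multiple pairwise comparisons drawn from one cohort
        (e.g. responsive-vs-nonresponsive and responsive-vs-low-responsive);
        defaults to the study id.
    """

    study_id: str
    expr: pd.DataFrame
    labels: pd.Series
    comparison_id: str | None = None

    def __post_init__(self) -> None:
        if self.comparison_id is None:
            self.comparison_id = self.study_id
        if self.expr.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if not np.isfinite(self.expr.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        missing = set(self.expr.columns) - set(self.labels.index)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)[:5]}")
        self.labels = self.labels.loc[list(self.expr.columns)]
        bad = set(self.labels.unique()) - {RESPONDER, NONRESPONDER}
        if bad:
            raise ValueError(f"unknown response labels: {sorted(bad)}")
        for grp in (RESPONDER, NONRESPONDER):
            if int((self.labels == grp).sum()) < 2:
                raise ValueError(f"group {grp!r} has < 2 samples")

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    def group_matrix(self, group: str) -> np.ndarray:
        return self.expr.loc[:, (self.labels == group).to_numpy()].to_numpy()


@dataclass(frozen=True)
class ModeratedTParams:
    """Variance-shrinkage prior: ``d0`` prior df (``inf`` allowed), ``s0_sq`` prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("prior df d0 must be >= 0")
        if not (self.s0_sq > 0) and self.d0 > 0:
            raise ValueError("prior variance s0_sq must be > 0")


@dataclass
class ComparisonResult:
    """Per-gene statistics for one responder-vs-nonresponder comparison.

    ``table`` columns: log2fc, s2 (gene-wise variance), df (residual df),
    s2_post (moderated variance), t, df_total, p_two, p_one_up, flag.
    ``p_one_up`` is the upper-tail probability, small when the gene is up
    in non-responders.
    """

    comparison_id: str
    study_id: str
    table: pd.DataFrame
    params: ModeratedTParams | None = None
    method: str = "moderated"

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def p_one_up(self) -> pd.Series:
        return self.table["p_one_up"]


def _group_arrays(study: ExpressionStudy) -> tuple[np.ndarray, np.ndarray]:
    x_nr = study.group_matrix(NONRESPONDER)
    x_r = study.group_matrix(RESPONDER)
    return x_nr, x_r


def log2_fold_changes(study: ExpressionStudy) -> pd.Series:
    """log2FC = mean(nonresponder) - mean(responder), per gene."""
    x_nr, x_r = _group_arrays(study)
    return pd.Series(x_nr.mean(axis=1) - x_r.mean(axis=1), index=study.genes, name="log2fc")


def _pooled_stats(study: ExpressionStudy) -> tuple[pd.Series, np.ndarray, int, int, int]:
    """Fold change, pooled gene-wise variance, residual df and group sizes."""
    x_nr, x_r = _group_arrays(study)
    n1, n2 = x_nr.shape[1], x_r.shape[1]
    d_g = n1 + n2 - 2
    ss = ((x_nr - x_nr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((x_r - x_r.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / d_g
    lfc = pd.Series(x_nr.mean(axis=1) - x_r.mean(axis=1), index=study.genes, name="log2fc")
    return lfc, s2, d_g, n1, n2


def _floor_variances(s2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace zero variances by the 1st percentile of positive ones.

    Keeps degenerate genes in the rank universe with a finite statistic
    instead of dropping them or producing infinite t. Returns the floored
    variances and a boolean flag vector.
    """
    flag = s2 <= 0
    if flag.any():
        positive = s2[s2 > 0]
        if positive.size == 0:
            raise ValueError("all gene variances are zero; nothing to test")
        floor = np.percentile(positive, 1.0)
        s2 = np.where(flag, floor, s2)
    return s2, flag


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < tol:
            break
    return x


def estimate_prior(variances: np.ndarray | pd.Series, df: float | np.ndarray) -> ModeratedTParams:
    """Estimate (d0, s0^2) by moment matching of log gene-wise variances.

    Under the hierarchical model s_g^2 ~ s0^2 * F(d_g, d0), the log variances
    follow a location-shifted log-F whose first two moments involve digamma
    and trigamma functions; matching those moments and inverting trigamma
    yields the prior. When the dispersion of log variances does not exceed
    the trigamma floor (the dispersion expected from finite d_g alone),
    d0 is reported as infinity and s0^2 as the geometric-mean-scale variance.
    """
    s2 = np.asarray(variances, dtype=float)
    d = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    keep = s2 > 0
    s2, d = s2[keep], d[keep]
    if s2.size < 10:
        raise ValueError("need >= 10 genes with positive variance to estimate the prior")
    z = np.log(s2)
    if np.allclose(z, z[0]):
        # zero observed dispersion: no evidence of gene-level variance
        # heterogeneity, so the prior is the common value itself
        return ModeratedTParams(d0=math.inf, s0_sq=float(s2[0]))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(np.mean(special.polygamma(1, d / 2.0)))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return ModeratedTParams(d0=d0, s0_sq=s0_sq)


def _t_pvalues(t: np.ndarray, df_total: float) -> tuple[np.ndarray, np.ndarray]:
    if math.isinf(df_total):
        p_two = 2.0 * stats.norm.sf(np.abs(t))
        p_one_up = stats.norm.sf(t)
    else:
        p_two = 2.0 * stats.t.sf(np.abs(t), df_total)
        p_one_up = stats.t.sf(t, df_total)
    # clip into (0, 1]: exact zeros break downstream log-combination
    tiny = np.finfo(float).tiny
    return np.clip(p_two, tiny, 1.0), np.clip(p_one_up, tiny, 1.0)


def moderated_t(study: ExpressionStudy, params: ModeratedTParams | None = None) -> ComparisonResult:
    """Empirical-Bayes moderated t-test of non-responders vs responders.

    The posterior variance is the precision-weighted blend
    ``s2_post = (d0*s0^2 + d_g*s2) / (d0 + d_g)`` and the statistic is
    referred to a Student t with ``d0 + d_g`` degrees of freedom
    (standard normal when d0 is infinite). With ``params.d0 == 0`` this
    reduces exactly to the classical pooled two-sample t.
    """
    lfc, s2, d_g, n1, n2 = _pooled_stats(study)
    s2_arr, flag = _floor_variances(s2.to_numpy() if isinstance(s2, pd.Series) else s2)
    if params is None:
        params = estimate_prior(s2_arr, d_g)
    d0, s0_sq = params.d0, params.s0_sq
    if math.isinf(d0):
        s2_post = np.full_like(s2_arr, s0_sq)
        df_total = math.inf
    elif d0 == 0:
        s2_post = s2_arr
        df_total = float(d_g)
    else:
        s2_post = (d0 * s0_sq + d_g * s2_arr) / (d0 + d_g)
        df_total = float(d0 + d_g)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = lfc.to_numpy() / se
    p_two, p_one_up = _t_pvalues(t, df_total)
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "s2": s2_arr,
            "df": float(d_g),
            "s2_post": s2_post,
            "t": t,
            "df_total": df_total,
            "p_two": p_two,
            "p_one_up": p_one_up,
            "flag": flag,
        },
        index=study.genes,
    )
    return ComparisonResult(
        comparison_id=study.comparison_id or study.study_id,
        study_id=study.study_id,
        table=table,
        params=params,
        method="moderated",
    )


def welch_t(study: ExpressionStudy) -> ComparisonResult:
    """Welch two-sample t with Satterthwaite df; no equal-variance assumption."""
    x_nr, x_r = _group_arrays(study)
    n1, n2 = x_nr.shape[1], x_r.shape[1]
    lfc = x_nr.mean(axis=1) - x_r.mean(axis=1)
    v1 = x_nr.var(axis=1, ddof=1)
    v2 = x_r.var(axis=1, ddof=1)
    v1, flag1 = _floor_variances(v1)
    v2, flag2 = _floor_variances(v2)
    q1, q2 = v1 / n1, v2 / n2
    se = np.sqrt(q1 + q2)
    df = (q1 + q2) ** 2 / (q1**2 / (n1 - 1) + q2**2 / (n2 - 1))
    t = lfc / se
    p_two = 2.0 * stats.t.sf(np.abs(t), df)
    p_one_up = stats.t.sf(t, df)
    tiny = np.finfo(float).tiny
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "s2": (v1 + v2) / 2.0,
            "df": df,
            "s2_post": (v1 + v2) / 2.0,
            "t": t,
            "df_total": df,
            "p_two": np.clip(p_two, tiny, 1.0),
            "p_one_up": np.clip(p_one_up, tiny, 1.0),
            "flag": flag1 | flag2,
        },
        index=study.genes,
    )
    return ComparisonResult(
        comparison_id=study.comparison_id or study.study_id,
        study_id=study.study_id,
        table=table,
        params=None,
        method="welch",
    )
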