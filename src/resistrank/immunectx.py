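"""Immune-context statistics downstream of the meta-analysis.

Three small analyses that place a candidate gene in its tumor-immune
context: (1) signature scoring and median dichotomization of a cohort into
e.g. macrophage-high/CD8-low vs macrophage-low/CD8-high strata, followed by
a two-sample t-test of the candidate's expression between strata; (2)
correlation of per-cell-type mean expression across independent datasets
(datasets are the observations, e.g. the gene in cancer cells vs a receptor
in macrophages); (3) dot-plot summaries (min-max scaled group means and the
fraction of samples expressing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ExpressionStudy
from .io import GeneSet

__all__ = [
    "score_signature",
    "score_signatures",
    "dichotomize",
    "compare_groups",
    "celltype_mean_correlation",
    "dotplot_summary",
]

STRATUM_A_HIGH = "sigA_high_sigB_low"
STRATUM_B_HIGH = "sigA_low_sigB_high"
EXCLUDED = "excluded"


def score_signature(
    expr: pd.DataFrame | ExpressionStudy, signature: GeneSet
) -> tuple[pd.Series, int]:
    """Per-sample mean z-score over the signature genes present in the matrix.

    Genes are z-scored across the cohort (so each contributes on the same
    scale regardless of absolute expression); constant genes get z = 0
    rather than dividing by zero. Returns (scores, number of signature genes
    missing from the matrix).
    """
    mat = expr.expr if isinstance(expr, ExpressionStudy) else expr
    present = [g for g in mat.index if g in signature]
    if not present:
        raise ValueError(f"no overlap between matrix and signature {signature.name!r}")
    sub = mat.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    scores = pd.Series(z.mean(axis=0), index=mat.columns, name=signature.name)
    return scores, len(signature) - len(present)


def score_signatures(
    expr: pd.DataFrame | ExpressionStudy, signatures: list[GeneSet]
) -> pd.DataFrame:
    """Samples x signatures score table (missing-gene counts attached in attrs)."""
    cols, missing = {}, {}
    for sig in signatures:
        scores, n_missing = score_signature(expr, sig)
        cols[sig.name] = scores
        missing[sig.name] = n_missing
    table = pd.DataFrame(cols)
    table.attrs["missing_genes"] = missing
    return table


def dichotomize(scores: pd.DataFrame, sig_a: str, sig_b: str) -> pd.Series:
    """Split samples into A-high/B-low vs A-low/B-high strata by cohort medians.

    Stratum A-high/B-low: score_A > median(A) and score_B < median(B);
    the converse for the other stratum; everything else (including ties on
    either median) is excluded, which is why stratum sizes are generally
    unequal and do not sum to the cohort.
    """
    if len(scores) < 4:
        raise ValueError("need >= 4 samples to dichotomize")
    a, b = scores[sig_a], scores[sig_b]
    med_a, med_b = a.median(), b.median()
    strata = pd.Series(EXCLUDED, index=scores.index, name="stratum")
    strata[(a > med_a) & (b < med_b)] = STRATUM_A_HIGH
    strata[(a < med_a) & (b > med_b)] = STRATUM_B_HIGH
    return strata


def compare_groups(
    values: pd.Series, strata: pd.Series,
    group_a: str = STRATUM_A_HIGH, group_b: str = STRATUM_B_HIGH,
) -> tuple[float, float, float]:
    """Unpaired two-tailed pooled-variance t-test of one gene between strata.

    Returns (t, df, p_two); t > 0 means higher expression in ``group_a``.
    """
    x = values[strata[strata == group_a].index].to_numpy(dtype=float)
    y = values[strata[strata == group_b].index].to_numpy(dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each stratum needs >= 2 samples")
    res = stats.ttest_ind(x, y, equal_var=True)
    df = x.size + y.size - 2
    return float(res.statistic), float(df), float(res.pvalue)


def celltype_mean_correlation(
    table: pd.DataFrame,
    x: tuple[str, str],
    y: tuple[str, str],
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Correlate two (gene, cell type) mean-expression profiles across datasets.

    ``table`` is long form (dataset, gene, cell_type, mean_expr); each
    dataset is one observation. Datasets missing either entry are dropped
    (pairwise-complete). Returns (r, two-sided p, number of datasets used).
    """
    def profile(gene: str, cell_type: str) -> pd.Series:
        sub = table[(table["gene"] == gene) & (table["cell_type"] == cell_type)]
        if sub.duplicated("dataset").any():
            raise ValueError(f"duplicate dataset entries for {gene}/{cell_type}")
        return sub.set_index("dataset")["mean_expr"].astype(float)

    px, py = profile(*x), profile(*y)
    shared = px.index.intersection(py.index)
    paired = pd.DataFrame({"x": px[shared], "y": py[shared]}).dropna()
    if len(paired) < 3:
        raise ValueError("need >= 3 datasets with both entries present")
    if method == "pearson":
        r, p = stats.pearsonr(paired["x"], paired["y"])
    elif method == "spearman":
        r, p = stats.spearmanr(paired["x"], paired["y"])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), len(paired)


def dotplot_summary(
    expr: pd.DataFrame | ExpressionStudy,
    genes: list[str],
    groups: pd.Series,
    expressing_threshold: float = 0.0,
    binarize: bool = False,
) -> pd.DataFrame:
    """Dot-plot statistics per (group, gene): scaled mean and fraction expressing.

    The group means of each gene are min-max scaled to [0, 1] across groups
    (with a single group, or all-equal means, the convention is 1); the
    fraction expressing counts samples with expression strictly above
    ``expressing_threshold``. ``binarize`` thresholds the scaled mean at 0.5.
    """
    mat = expr.expr if isinstance(expr, ExpressionStudy) else expr
    missing = set(mat.columns) - set(groups.index)
    if missing:
        raise ValueError(f"samples without a group: {sorted(missing)[:5]}")
    groups = groups.loc[list(mat.columns)]
    rows = []
    for gene in genes:
        vals = mat.loc[gene]
        means = vals.groupby(groups).mean()
        span = means.max() - means.min()
        scaled = (means - means.min()) / span if span > 0 else pd.Series(1.0, index=means.index)
        if binarize:
            scaled = (scaled >= 0.5).astype(float)
        frac = (vals > expressing_threshold).groupby(groups).mean()
        for grp in means.index:
            rows.append(
                {
                    "group": grp,
                    "gene": gene,
                    "scaled_mean": float(scaled[grp]),
                    "mean": float(means[grp]),
                    "fraction_expressing": float(frac[grp]),
                }
            )
    return pd.DataFrame(rows)
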