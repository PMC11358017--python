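"""Rank-product meta-analysis across responder/non-responder comparisons.

Each comparison contributes a fold-change ranking (rank 1 = most upregulated
in non-responders; ties get average ranks). For a gene present in k
comparisons the statistic is the relative geometric-mean rank product

    rho_g = (prod_i r_{g,i} / n_i) ** (1/k),

with the raw integer product ``prod_i r_{g,i}`` reported alongside. Small
rho means consistent upregulation in non-responders across cohorts.

Null p-values (independent uniform ranks per comparison) come from three
routes: exact enumeration (small problems; the reference the approximation
is validated against), a continuity-corrected Gamma(k, 1) tail
approximation of the discrete count (see ``rp_pvalue_gamma``), and seeded
Monte-Carlo permutation. Benjamini-Hochberg
adjustment and Fisher's one-sided combination of per-comparison one-tailed
p-values are computed side by side; the final ordering follows rho.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ComparisonResult, ExpressionStudy, estimate_prior, moderated_t, welch_t
from .io import GeneSet

__all__ = [
    "RankTable",
    "MetaConfig",
    "rank_by_lfc",
    "rank_product",
    "rp_pvalue_exact",
    "rp_pvalue_gamma",
    "rp_pvalue_permutation",
    "bh_adjust",
    "storey_qvalues",
    "fisher_combine",
    "fisher_combine_table",
    "filter_and_rank_metabolic",
    "run_meta",
]

P_FLOOR = 1e-300


@dataclass
class RankTable:
    """Fold-change ranks for one comparison: rank 1 = most up in non-responders."""

    comparison_id: str
    ranks: pd.Series
    n: int

    def __post_init__(self) -> None:
        self.n = int(self.n)
        if len(self.ranks) != self.n:
            raise ValueError("rank table length disagrees with n")
        r = self.ranks.to_numpy()
        if (r < 1).any() or (r > self.n).any():
            raise ValueError("ranks must lie in [1, n]")
        if not math.isclose(float(r.sum()), self.n * (self.n + 1) / 2, rel_tol=1e-9):
            raise ValueError("ranks do not sum to n(n+1)/2; not a valid average-rank vector")


def rank_by_lfc(comparison: ComparisonResult) -> RankTable:
    """Rank genes by descending log2 fold change (average ranks on ties)."""
    lfc = comparison.log2fc
    if len(lfc) == 0:
        raise ValueError("empty comparison")
    if not np.isfinite(lfc.to_numpy()).all():
        raise ValueError("non-finite fold changes cannot be ranked")
    ranks = pd.Series(stats.rankdata(-lfc.to_numpy(), method="average"), index=lfc.index)
    return RankTable(comparison_id=comparison.comparison_id, ranks=ranks, n=len(lfc))


def rank_product(
    rank_tables: list[RankTable], min_studies: int | None = None
) -> pd.DataFrame:
    """Combine fold-change ranks into per-gene rank products.

    Returns a DataFrame indexed by gene with one ``rank_<comparison>`` column
    per input table plus ``k`` (number of comparisons containing the gene),
    ``raw_product`` (product of ranks over those comparisons) and ``rho``
    (geometric mean of relative ranks r/n). Genes present in fewer than
    ``min_studies`` comparisons (default: all of them) are dropped.
    """
    if len(rank_tables) == 0:
        raise ValueError("need at least one rank table")
    if min_studies is None:
        min_studies = len(rank_tables)
    wide = pd.DataFrame({f"rank_{t.comparison_id}": t.ranks for t in rank_tables})
    sizes = np.array([t.n for t in rank_tables], dtype=float)
    present = wide.notna()
    k = present.sum(axis=1)
    keep = k >= min_studies
    if not keep.any():
        raise ValueError("no gene is present in enough comparisons")
    wide, present, k = wide.loc[keep], present.loc[keep], k.loc[keep]
    rel = wide.to_numpy() / sizes[None, :]
    log_rel = np.where(present.to_numpy(), np.log(np.where(present.to_numpy(), rel, 1.0)), 0.0)
    rho = np.exp(log_rel.sum(axis=1) / k.to_numpy())
    raw = np.where(present.to_numpy(), wide.to_numpy(), 1.0).prod(axis=1)
    out = wide.copy()
    out["k"] = k.astype(int)
    out["raw_product"] = raw
    out["rho"] = rho
    return out


def rp_pvalue_exact(
    raw_product: float, n: list[int] | np.ndarray, budget: int = 10_000_000
) -> float:
    """Exact null P(prod r_i <= raw_product) under independent uniform integer ranks.

    Counts tuples by dynamic programming on distinct products, so the work is
    bounded by the number of distinct partial products rather than the full
    tuple grid; the budget guards the worst case ``prod n_i``.
    """
    sizes = [int(v) for v in n]
    if any(v < 1 for v in sizes):
        raise ValueError("comparison sizes must be >= 1")
    total = math.prod(sizes)
    if total > budget:
        raise ValueError(
            f"enumeration over {total} tuples exceeds budget {budget}; "
            "use rp_pvalue_gamma or rp_pvalue_permutation"
        )
    products: dict[int, int] = {1: 1}
    for size in sizes:
        nxt: dict[int, int] = {}
        for prod_val, count in products.items():
            for r in range(1, size + 1):
                key = prod_val * r
                if key > raw_product:
                    # later factors are >= 1, so this state can never return
                    # below the threshold; prune it
                    break
                nxt[key] = nxt.get(key, 0) + count
        products = nxt
    favorable = sum(products.values())
    return favorable / total


def _box_tail_volume(sizes: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Vol{y in prod_i [1/2, n_i + 1/2] : prod_i y_i <= s}, vectorized over s.

    Computed by inclusion-exclusion over the 2^k box corners; each term is a
    Gamma(k, 1) upper tail (the distribution of -sum log U_i for uniform U).
    """
    k = sizes.size
    s = np.asarray(s, dtype=float)
    total = np.zeros_like(s)
    for corner in range(2**k):
        edge = np.where(
            [(corner >> i) & 1 for i in range(k)], 0.5, sizes + 0.5
        )
        pe = float(np.prod(edge))
        sign = -1.0 if bin(corner).count("1") % 2 else 1.0
        z = s / pe
        tail = np.where(
            z >= 1.0,
            1.0,
            np.where(z > 0.0, stats.gamma.sf(-np.log(np.clip(z, 1e-320, None)), a=k), 0.0),
        )
        total += sign * pe * tail
    return total


REFINE_SIZE_LIMIT = 256


def rp_pvalue_gamma(
    ranks: np.ndarray | list[float],
    sizes: np.ndarray | list[int],
    refine: bool | None = None,
) -> float | np.ndarray:
    """Continuity-corrected gamma approximation to the rank-product null p-value.

    Under the null the relative ranks are uniform, so -sum log(r_i/n_i) is
    approximately Gamma(k, 1). The discrete tail #{tuples: prod r_i <= q} is
    approximated by the volume of the half-unit-shifted rank box below the
    product cutoff q + 1/2, evaluated with 2^k gamma tails (inclusion-
    exclusion over box corners). When any comparison is small
    (min n_i <= 256, ``refine`` default), the sum over that comparison's
    integer ranks is taken exactly and only the remaining k-1 dimensions are
    approximated; this makes the approximation exact for k <= 2 and accurate
    to ~0.01 absolute at n_i = 8, k = 3 (certified against enumeration).
    Accepts a 2-D rank array (genes x comparisons) for vectorized use.
    """
    r = np.asarray(ranks, dtype=float)
    n = np.asarray(sizes, dtype=float)
    if np.any(r < 1) or np.any(r > n):
        raise ValueError("ranks must lie in [1, n]")
    scalar = r.ndim == 1
    r2 = r[None, :] if scalar else r
    k = r2.shape[1]
    if n.size != k:
        raise ValueError("sizes must match the number of comparisons")
    q = np.prod(r2, axis=1)
    big_n = float(np.prod(n))
    if refine is None:
        refine = float(n.min()) <= REFINE_SIZE_LIMIT
    if not refine or k == 1:
        if k == 1:
            p = np.clip(np.floor(q) / big_n, 0.0, 1.0)
        else:
            p = np.clip(_box_tail_volume(n, q + 0.5) / big_n, 0.0, 1.0)
        return float(p[0]) if scalar else p
    # exact summation over the smallest comparison's integer ranks
    i0 = int(np.argmin(n))
    n0 = int(n[i0])
    rest = np.delete(n, i0)
    outer = np.arange(1, n0 + 1, dtype=float)
    m = np.floor(q[:, None] / outer[None, :])  # genes x n0 inner cutoffs
    vol = _box_tail_volume(rest, m + 0.5)
    vol[m < 1] = 0.0
    p = np.clip(vol.sum(axis=1) / big_n, 0.0, 1.0)
    return float(p[0]) if scalar else p


def rp_pvalue_permutation(
    rho: float,
    sizes: list[int] | np.ndarray,
    n_permutations: int = 100_000,
    seed: int | np.random.Generator | None = 0,
) -> tuple[float, float]:
    """Monte-Carlo null p-value for the relative rank product rho.

    Draws ``n_permutations`` tuples of independent uniform integer ranks,
    computes each null rho* and returns the add-one estimator
    ``(1 + #{rho* <= rho}) / (B + 1)`` with its binomial standard error.
    """
    if n_permutations < 1000:
        raise ValueError("need at least 1,000 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = np.asarray(sizes, dtype=int)
    k = sizes.size
    draws = np.empty((n_permutations, k))
    for j, n in enumerate(sizes):
        draws[:, j] = rng.integers(1, n + 1, size=n_permutations) / n
    rho_null = np.exp(np.log(draws).sum(axis=1) / k)
    hits = int((rho_null <= rho).sum())
    p = (1 + hits) / (n_permutations + 1)
    se = math.sqrt(p * (1 - p) / n_permutations)
    return p, se


def _validate_pvalues(p: np.ndarray) -> None:
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")


def bh_adjust(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    _validate_pvalues(arr)
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def storey_qvalues(p: np.ndarray | pd.Series, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate (optional alternative to BH)."""
    arr = np.asarray(p, dtype=float)
    _validate_pvalues(arr)
    if not 0 <= lambda_ < 1:
        raise ValueError("lambda must lie in [0, 1)")
    pi0 = min(1.0, float((arr > lambda_).mean()) / (1.0 - lambda_))
    pi0 = max(pi0, 1.0 / arr.size)
    return np.minimum(pi0 * bh_adjust(arr), 1.0)


def fisher_combine(
    p_one: np.ndarray | list[float], eps: float = P_FLOOR
) -> tuple[float, int, float]:
    """Fisher's combined probability test on one-tailed p-values.

    Returns (X, df, p_combined) where ``X = -2 sum log p_i`` is chi-squared
    with ``2k`` degrees of freedom under the null. Zero p-values are floored
    at ``eps`` rather than erroring.
    """
    arr = np.asarray(p_one, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    arr = np.maximum(arr, eps)
    x = float(-2.0 * np.log(arr).sum())
    df = 2 * arr.size
    return x, df, float(stats.chi2.sf(x, df))


def fisher_combine_table(p_matrix: pd.DataFrame, eps: float = P_FLOOR) -> pd.DataFrame:
    """Row-wise Fisher combination over a genes x comparisons p-value matrix."""
    arr = np.maximum(p_matrix.to_numpy(dtype=float), eps)
    present = np.isfinite(arr)
    logs = np.where(present, np.log(np.where(present, arr, 1.0)), 0.0)
    x = -2.0 * logs.sum(axis=1)
    k = present.sum(axis=1)
    p = stats.chi2.sf(x, 2 * k)
    return pd.DataFrame(
        {"fisher_X": x, "fisher_df": 2 * k, "p_fisher": p}, index=p_matrix.index
    )


def filter_and_rank_metabolic(meta: pd.DataFrame, metabolic: GeneSet) -> pd.DataFrame:
    """Restrict a meta-analysis table to metabolic genes and re-rank by rho.

    P-values are not recomputed: the filter is applied after inference, so the
    multiplicity correction still reflects the full tested universe. The final
    ``meta_rank`` is a permutation of 1..m (ties on rho broken by p and then
    gene id so the ranking is total).
    """
    keep = meta.index.isin(metabolic.genes)
    if not keep.any():
        raise ValueError("no overlap between meta-analysis genes and the metabolic set")
    sub = meta.loc[keep].copy()
    tie_break = sub.get("p_rp", pd.Series(0.0, index=sub.index))
    order = np.lexsort((sub.index.to_numpy(), tie_break.to_numpy(), sub["rho"].to_numpy()))
    meta_rank = np.empty(len(sub), dtype=int)
    meta_rank[order] = np.arange(1, len(sub) + 1)
    sub["meta_rank"] = meta_rank
    return sub.sort_values("meta_rank")


@dataclass
class MetaConfig:
    """Configuration for the full meta-analysis pipeline.

    p_method
        "gamma" (default production route), "exact" (enumeration; small
        problems, integer ranks only) or "perm" (seeded Monte-Carlo).
    de_method
        "moderated" (empirical-Bayes t) or "welch".
    min_studies
        Minimum number of comparisons a gene must appear in (default: all).
    filter_before_bh
        If True, restrict to metabolic genes before the BH adjustment instead
        of after (the default keeps the full universe for multiplicity).
    """

    p_method: str = "gamma"
    de_method: str = "moderated"
    min_studies: int | None = None
    filter_before_bh: bool = False
    n_permutations: int = 100_000
    exact_budget: int = 10_000_000
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "p_method": self.p_method,
            "de_method": self.de_method,
            "min_studies": self.min_studies,
            "filter_before_bh": self.filter_before_bh,
            "n_permutations": self.n_permutations,
            "exact_budget": self.exact_budget,
            "seed": self.seed,
        }


def _comparisons_from_studies(
    studies: list[ExpressionStudy | ComparisonResult], de_method: str
) -> list[ComparisonResult]:
    comps: list[ComparisonResult] = []
    for s in studies:
        if isinstance(s, ComparisonResult):
            comps.append(s)
        elif de_method == "moderated":
            comps.append(moderated_t(s))
        elif de_method == "welch":
            comps.append(welch_t(s))
        else:
            raise ValueError(f"unknown de_method {de_method!r}")
    return comps


def _rp_pvalues(table: pd.DataFrame, rank_cols: list[str], sizes: np.ndarray,
                config: MetaConfig) -> np.ndarray:
    ranks = table[rank_cols].to_numpy(dtype=float)
    present = np.isfinite(ranks)
    if config.p_method == "gamma":
        if present.all():
            return np.asarray(rp_pvalue_gamma(ranks, sizes))
        p = np.empty(len(table))
        for i in range(len(table)):
            m = present[i]
            p[i] = rp_pvalue_gamma(ranks[i, m], sizes[m])
        return p
    if config.p_method == "exact":
        if not np.allclose(ranks[present], np.round(ranks[present])):
            raise ValueError(
                "exact enumeration is defined on integer ranks; tied (average) "
                "ranks require the gamma or permutation method"
            )
        p = np.empty(len(table))
        for i in range(len(table)):
            m = present[i]
            raw = float(np.prod(ranks[i, m]))
            p[i] = rp_pvalue_exact(raw, sizes[m].astype(int), budget=config.exact_budget)
        return p
    if config.p_method == "perm":
        rng = np.random.default_rng(config.seed)
        # one shared null distribution per comparison-pattern; typically all
        # genes share the full pattern, so the draws are reused
        p = np.empty(len(table))
        cache: dict[tuple, np.ndarray] = {}
        for i in range(len(table)):
            m = present[i]
            key = tuple(np.flatnonzero(m))
            if key not in cache:
                k = int(m.sum())
                draws = np.empty((config.n_permutations, k))
                for j, n in enumerate(sizes[m]):
                    draws[:, j] = rng.integers(1, int(n) + 1, size=config.n_permutations) / n
                cache[key] = np.sort(np.exp(np.log(draws).sum(axis=1) / k))
            null_sorted = cache[key]
            rho = float(table["rho"].to_numpy()[i])
            hits = int(np.searchsorted(null_sorted, rho, side="right"))
            p[i] = (1 + hits) / (config.n_permutations + 1)
        return p
    raise ValueError(f"unknown p_method {config.p_method!r}")


def run_meta(
    studies: list[ExpressionStudy | ComparisonResult],
    metabolic: GeneSet | None = None,
    config: MetaConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full rank-product meta-analysis.

    Pipeline: per-comparison differential expression -> fold-change ranking ->
    rank product -> null p-values -> BH adjustment; in parallel, Fisher's
    one-sided combination of the per-comparison one-tailed p-values; finally
    the optional metabolic filter and the rho-ordered meta-rank.

    Returns the result table and a run manifest (config hash, seed, sizes).
    """
    config = config or MetaConfig()
    comps = _comparisons_from_studies(studies, config.de_method)
    if len(comps) < 2:
        raise ValueError("meta-analysis needs >= 2 comparisons")
    ids = [c.comparison_id for c in comps]
    if len(set(ids)) != len(ids):
        raise ValueError("comparison ids must be unique")
    tables = [rank_by_lfc(c) for c in comps]
    meta = rank_product(tables, min_studies=config.min_studies)
    rank_cols = [f"rank_{t.comparison_id}" for t in tables]
    sizes = np.array([t.n for t in tables], dtype=float)

    if metabolic is not None and config.filter_before_bh:
        meta = meta.loc[meta.index.isin(metabolic.genes)]
        if meta.empty:
            raise ValueError("no overlap between meta-analysis genes and the metabolic set")

    meta["p_rp"] = np.clip(_rp_pvalues(meta, rank_cols, sizes, config), P_FLOOR, 1.0)
    meta["p_adj"] = bh_adjust(meta["p_rp"].to_numpy())

    p_one = pd.DataFrame({c.comparison_id: c.p_one_up for c in comps}).loc[meta.index]
    meta = meta.join(fisher_combine_table(p_one))

    if metabolic is not None:
        meta["is_metabolic"] = meta.index.isin(metabolic.genes)
        result = filter_and_rank_metabolic(meta, metabolic)
    else:
        meta["is_metabolic"] = True
        result = filter_and_rank_metabolic(
            meta, GeneSet.from_iterable("all", meta.index.astype(str))
        )

    cfg = config.to_dict()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_comparisons": len(comps),
        "comparisons": ids,
        "n_genes": int(len(meta)),
        "n_reported": int(len(result)),
    }
    return result, manifest
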