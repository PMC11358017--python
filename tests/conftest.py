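import numpy as np
import pandas as pd
import pytest

from resistrank.diffexp import NONRESPONDER, RESPONDER, ExpressionStudy


def make_study(
    nonresp: dict[str, list[float]] | np.ndarray,
    resp: dict[str, list[float]] | np.ndarray,
    genes: list[str] | None = None,
    study_id: str = "s1",
) -> ExpressionStudy:
    """Build a study from per-gene value lists (nonresponder, responder)."""
    if isinstance(nonresp, dict):
        genes = list(nonresp)
        nr = np.array([nonresp[g] for g in genes], dtype=float)
        r = np.array([resp[g] for g in genes], dtype=float)
    else:
        nr = np.atleast_2d(np.asarray(nonresp, dtype=float))
        r = np.atleast_2d(np.asarray(resp, dtype=float))
        genes = genes or [f"g{i}" for i in range(nr.shape[0])]
    n_r, n_nr = r.shape[1], nr.shape[1]
    samples = [f"R{i}" for i in range(n_r)] + [f"N{i}" for i in range(n_nr)]
    expr = pd.DataFrame(np.hstack([r, nr]), index=genes, columns=samples)
    labels = pd.Series([RESPONDER] * n_r + [NONRESPONDER] * n_nr, index=samples)
    return ExpressionStudy(study_id=study_id, expr=expr, labels=labels)


def make_null_study(n_genes: int, n_per_arm: int, seed: int, study_id: str = "null"):
    """Pure-noise study: every gene null, unit-variance Gaussian log2 values."""
    rng = np.random.default_rng(seed)
    r = rng.normal(6.0, 1.0, size=(n_genes, n_per_arm))
    nr = rng.normal(6.0, 1.0, size=(n_genes, n_per_arm))
    return make_study(nr, r, genes=[f"g{i}" for i in range(n_genes)], study_id=study_id)


@pytest.fixture
def tiny_study():
    return make_study({"a": [4.0, 5.0, 6.0]}, {"a": [1.0, 2.0, 3.0]})
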