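"""Synthetic multi-cohort expression data and dose-response data with ground truth.

The cohort generator emulates the shape of a multi-study immunotherapy
responder/non-responder meta-analysis: k heterogeneous cohorts share one
gene universe; each cohort gets its own per-gene batch offset (mimicking
platform/species differences between, say, a mouse bulk RNA-seq cohort and
human melanoma or renal-cancer cohorts); a chosen minority of "spiked"
genes are truly shifted up in non-responders by a per-study log2 effect
delta; everything else is null. Expression is Gaussian on the log2 scale —
the downstream statistics consume log-scale values and ranks, so count-level
simulation would add nothing the rank product can see.

The dose-response generator draws noisy observations from a known Hill
curve, standing in for Fura-2 normalized peak responses at a ladder of
agonist concentrations.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .diffexp import NONRESPONDER, RESPONDER, ExpressionStudy
from .dosefit import HillParams, hill_curve
from .io import GeneSet

__all__ = [
    "SimConfig",
    "TruthTable",
    "default_sim_config",
    "simulate_cohorts",
    "simulate_dose_response",
    "default_concentrations",
]


@dataclass
class SimConfig:
    """Configuration of the multi-cohort simulator.

    Parameters
    ----------
    n_genes
        Size of the shared gene universe.
    n_studies
        Number of cohorts k.
    n_responders, n_nonresponders
        Per-study arm sizes; a single int applies to every study.
    baseline_mean, baseline_sd
        Per-gene baseline log2 abundance is drawn once (shared across
        studies) from N(baseline_mean, baseline_sd).
    batch_sd
        SD of the per-study, per-gene additive batch offset. Drawn once per
        study, it shifts all samples of that study equally, so cross-study
        rank agreement is driven only by true effects.
    spikes
        gene id -> per-study log2 effect delta (scalar applies to all
        studies; positive = up in non-responders).
    noise_sd
        Residual Gaussian noise SD per measurement (log2 units).
    dropout, dropout_floor
        Each measurement is independently set to ``dropout_floor`` with
        probability ``dropout`` (crude detection-limit censoring).
    metabolic_fraction
        Fraction of the universe flagged metabolic (spiked genes included
        first, mirroring a screen focused on metabolic candidates).
    seed
        Seed for the generator; fixed seed gives bit-identical output.
    """

    n_genes: int = 10_000
    n_studies: int = 4
    n_responders: int | Sequence[int] = 10
    n_nonresponders: int | Sequence[int] = 10
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    batch_sd: float = 0.5
    spikes: Mapping[str, float | Sequence[float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    dropout: float = 0.0
    dropout_floor: float = 0.0
    metabolic_fraction: float = 0.1321
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_studies < 1:
            raise ValueError("n_genes and n_studies must be >= 1")
        for arm in (self.per_study(self.n_responders), self.per_study(self.n_nonresponders)):
            if any(n < 2 for n in arm):
                raise ValueError("each response arm needs >= 2 samples per study")
        if self.noise_sd < 0 or self.batch_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must lie in [0, 1]")
        if not 0 <= self.metabolic_fraction <= 1:
            raise ValueError("metabolic_fraction must lie in [0, 1]")
        universe = set(self.gene_ids())
        unknown = set(self.spikes) - universe
        if unknown:
            raise ValueError(f"spiked genes outside the universe: {sorted(unknown)[:5]}")
        for gene, delta in self.spikes.items():
            deltas = self.spike_deltas(gene)
            if len(deltas) != self.n_studies or not np.isfinite(deltas).all():
                raise ValueError(f"spike for {gene!r} must give one finite delta per study")

    def per_study(self, value: int | Sequence[int]) -> list[int]:
        if isinstance(value, (int, np.integer)):
            return [int(value)] * self.n_studies
        vals = [int(v) for v in value]
        if len(vals) != self.n_studies:
            raise ValueError("per-study sizes must match n_studies")
        return vals

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"gene_{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def spike_deltas(self, gene: str) -> np.ndarray:
        value = self.spikes[gene]
        if isinstance(value, (int, float, np.floating, np.integer)):
            return np.full(self.n_studies, float(value))
        return np.asarray([float(v) for v in value])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class TruthTable:
    """Ground truth of a simulation: one row per spiked gene.

    ``table`` columns: gene, delta_<study> per study, is_metabolic.
    ``metabolic_genes`` is the full simulated metabolic gene set (spiked and
    null alike), exportable as a GMT.
    """

    table: pd.DataFrame
    metabolic_genes: GeneSet

    def __len__(self) -> int:
        return len(self.table)


def default_sim_config(**overrides) -> SimConfig:
    """The packaged default configuration: 4 cohorts, a 10,000-gene universe
    with a 1,321-gene metabolic subset (the shape of the original screen)."""
    ref = importlib.resources.files("resistrank").joinpath("data/default_simulation.yaml")
    cfg = yaml.safe_load(ref.read_text())
    cfg.update(overrides)
    return SimConfig(**cfg)


def simulate_cohorts(config: SimConfig) -> tuple[list[ExpressionStudy], TruthTable]:
    """Generate k cohorts over a shared gene universe plus their ground truth."""
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    g = len(genes)
    gene_pos = {gid: i for i, gid in enumerate(genes)}
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=g)

    n_resp = config.per_study(config.n_responders)
    n_nonresp = config.per_study(config.n_nonresponders)

    # metabolic flag: spiked genes first, then random fill to the target count
    n_metabolic = int(round(config.metabolic_fraction * g))
    spiked = list(config.spikes)
    metabolic = list(spiked[:n_metabolic])
    remaining = [gid for gid in genes if gid not in config.spikes]
    if n_metabolic > len(metabolic):
        extra = rng.choice(len(remaining), size=n_metabolic - len(metabolic), replace=False)
        metabolic += [remaining[i] for i in sorted(extra)]
    metabolic_set = set(metabolic)

    studies: list[ExpressionStudy] = []
    for s in range(config.n_studies):
        study_id = f"study_{s + 1}"
        n1, n2 = n_resp[s], n_nonresp[s]
        batch = rng.normal(0.0, config.batch_sd, size=g) if config.batch_sd > 0 else np.zeros(g)
        mean = baseline + batch
        mat = np.tile(mean[:, None], (1, n1 + n2))
        for gid in spiked:
            mat[gene_pos[gid], n1:] += config.spike_deltas(gid)[s]
        if config.noise_sd > 0:
            mat += rng.normal(0.0, config.noise_sd, size=mat.shape)
        if config.dropout > 0:
            mask = rng.random(mat.shape) < config.dropout
            mat[mask] = config.dropout_floor
        samples = [f"{study_id}_R{i + 1}" for i in range(n1)] + [
            f"{study_id}_NR{i + 1}" for i in range(n2)
        ]
        labels = pd.Series([RESPONDER] * n1 + [NONRESPONDER] * n2, index=samples)
        expr = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
        studies.append(ExpressionStudy(study_id=study_id, expr=expr, labels=labels))

    rows = []
    for gid in spiked:
        row: dict = {"gene": gid}
        deltas = config.spike_deltas(gid)
        for s in range(config.n_studies):
            row[f"delta_study_{s + 1}"] = deltas[s]
        row["is_metabolic"] = gid in metabolic_set
        rows.append(row)
    delta_cols = [f"delta_study_{s + 1}" for s in range(config.n_studies)]
    truth_df = pd.DataFrame(rows, columns=["gene", *delta_cols, "is_metabolic"])
    if n_metabolic == 0:
        # degenerate but explicit: an empty metabolic annotation is represented
        # by the full universe so downstream filters remain no-ops
        gene_set = GeneSet.from_iterable("metabolic", genes, "simulated (empty fraction)")
    else:
        gene_set = GeneSet.from_iterable("metabolic", metabolic, "simulated metabolic genes")
    return studies, TruthTable(table=truth_df, metabolic_genes=gene_set)


def default_concentrations(n: int = 8, low: float = 1e-9, high: float = 1e-5) -> np.ndarray:
    """Half-log agonist ladder, by default 8 steps from 1 nM to 10 uM."""
    return np.logspace(np.log10(low), np.log10(high), n)


def simulate_dose_response(
    params: HillParams,
    concentrations: Sequence[float] | np.ndarray,
    replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy draws from a Hill curve: columns concentration_M, replicate, response.

    Zero-concentration baseline points are allowed (response = baseline there).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    truth = hill_curve(conc, params)
    for rep in range(1, replicates + 1):
        noise = rng.normal(0.0, noise_sd, size=conc.size) if noise_sd > 0 else 0.0
        rows.append(
            pd.DataFrame(
                {
                    "concentration_M": conc,
                    "replicate": rep,
                    "response": truth + noise,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
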