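"""Negative-binomial count matrices with planted translation-efficiency shifts.

Counts for gene g in sample j follow NB(mean = size_factor_j * baseline_g *
effect), where the effect encodes the planted log2 FC TE on the polysomal
fraction of every non-reference condition: positive planted FC TE lowers
polysomal abundance under treatment (treatment reduces TE). Spike-in rows
track size factors only, carrying no condition effect by construction.
Dispersion 0 is the deterministic limit (counts equal their means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..te import FRACTIONS, MONOSOMAL, POLYSOMAL, SampleDesign

__all__ = ["SimSample", "CountSimSpec", "gen_count_matrix", "PolysomeExperiment"]

SPIKE_PREFIX = "ERCC-"


@dataclass(frozen=True)
class SimSample:
    fraction: str  # monosomal | polysomal
    condition: str
    replicate: int


@dataclass
class CountSimSpec:
    """Parameters for one simulated polysome-profiling experiment."""

    n_genes: int
    design: list[SimSample]
    true_size_factors: list[float]
    spike_in_count: int = 50
    baseline_means: np.ndarray | None = None  # per gene; drawn if None
    spike_means: np.ndarray | None = None  # per spike row; drawn if None
    dispersion: float | np.ndarray = 0.05  # NB dispersion (alpha); 0 = exact
    planted_log2_fc_te: np.ndarray | None = None  # per gene; zeros if None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.true_size_factors) != len(self.design):
            raise ValueError("one size factor per sample required")
        if any(f <= 0 for f in self.true_size_factors):
            raise ValueError("size factors must be > 0")
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if (disp < 0).any():
            raise ValueError("dispersion must be >= 0")
        for s in self.design:
            if s.fraction not in FRACTIONS:
                raise ValueError(f"unknown fraction {s.fraction!r}")
        conditions = {s.condition for s in self.design}
        for cond in conditions:
            for frac in FRACTIONS:
                n = sum(
                    1
                    for s in self.design
                    if s.condition == cond and s.fraction == frac
                )
                if n < 2:
                    raise ValueError(
                        f"condition {cond!r} needs >= 2 {frac} replicates"
                    )

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(s.condition for s in self.design))


@dataclass
class PolysomeExperiment:
    """Gene x sample count matrix plus its sample design."""

    counts: pd.DataFrame
    design: SampleDesign
    spike_ids: list[str]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp) -> np.ndarray:
    """NB draws with var = mu + disp * mu^2; disp 0 returns the means."""
    disp = np.broadcast_to(np.asarray(disp, dtype=float), mean.shape)
    out = np.array(mean, dtype=float)
    stochastic = disp > 0
    if stochastic.any():
        mu = mean[stochastic]
        alpha = disp[stochastic]
        size = 1.0 / alpha
        p = size / (size + mu)
        out[stochastic] = rng.negative_binomial(size, p)
    return out


def gen_count_matrix(
    spec: CountSimSpec,
) -> tuple[PolysomeExperiment, pd.DataFrame]:
    """Simulate the count matrix and a per-gene truth table.

    Truth columns: gene_id, baseline_mean, planted_log2_fc_te, is_spike.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = len(spec.design)
    baselines = (
        np.asarray(spec.baseline_means, dtype=float)
        if spec.baseline_means is not None
        else rng.lognormal(mean=5.0, sigma=1.0, size=spec.n_genes)
    )
    if baselines.shape != (spec.n_genes,):
        raise ValueError("baseline_means must have one entry per gene")
    spikes = (
        np.asarray(spec.spike_means, dtype=float)
        if spec.spike_means is not None
        else rng.lognormal(mean=5.0, sigma=1.0, size=spec.spike_in_count)
    )
    fc = (
        np.asarray(spec.planted_log2_fc_te, dtype=float)
        if spec.planted_log2_fc_te is not None
        else np.zeros(spec.n_genes)
    )
    if fc.shape != (spec.n_genes,):
        raise ValueError("planted_log2_fc_te must have one entry per gene")

    reference_condition = spec.conditions[0]
    gene_ids = [f"gene{i:05d}" for i in range(spec.n_genes)]
    spike_ids = [f"{SPIKE_PREFIX}{i:04d}" for i in range(spec.spike_in_count)]
    sample_ids = [
        f"{s.condition}_{s.fraction[:4]}_r{s.replicate}" for s in spec.design
    ]

    counts = np.empty((spec.n_genes + spec.spike_in_count, n_samples))
    for j, (sample, sf) in enumerate(zip(spec.design, spec.true_size_factors)):
        gene_mu = baselines * sf
        if (
            sample.fraction == POLYSOMAL
            and sample.condition != reference_condition
        ):
            # positive planted FC TE = treatment reduces polysomal abundance
            gene_mu = gene_mu * np.power(2.0, -fc)
        spike_mu = spikes * sf
        counts[: spec.n_genes, j] = _nb_draw(rng, gene_mu, spec.dispersion)
        counts[spec.n_genes :, j] = _nb_draw(rng, spike_mu, spec.dispersion)

    frame = pd.DataFrame(
        counts, index=gene_ids + spike_ids, columns=sample_ids
    )
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "fraction": [s.fraction for s in spec.design],
                "condition": [s.condition for s in spec.design],
                "replicate": [s.replicate for s in spec.design],
            }
        )
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids + spike_ids,
            "baseline_mean": np.concatenate([baselines, spikes]),
            "planted_log2_fc_te": np.concatenate(
                [fc, np.zeros(spec.spike_in_count)]
            ),
            "is_spike": [False] * spec.n_genes + [True] * spec.spike_in_count,
        }
    ).set_index("gene_id")
    return PolysomeExperiment(frame, design, spike_ids), truth


def standard_design(
    n_replicates: int = 3,
    conditions: tuple[str, str] = ("control", "treated"),
) -> list[SimSample]:
    """Fully crossed fraction x condition x replicate design."""
    return [
        SimSample(fraction=frac, condition=cond, replicate=r)
        for cond in conditions
        for frac in FRACTIONS
        for r in range(1, n_replicates + 1)
    ]
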