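"""Neutral Wright–Fisher drift null for founder-allele frequencies.

The null model for founder-breed ancestry at a locus in a composite breed:
starting from the founding proportion p0 (default 0.625), the frequency
drifts by binomial sampling of 2·Ne gene copies per generation, with no
selection, mutation or migration. Replicate trajectories give a
per-generation mean and SD, and a two-sided 99% Gaussian envelope
(mean ± 2.576·SD). Observed per-SNP founder probabilities outside the
final-generation envelope are called enriched or depleted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: two-sided 99% standard-normal quantile
Z_99 = 2.576


@dataclass
class DriftConfig:
    p0: float = 0.625
    ne: int = 100               # effective size, diploids
    n_generations: int = 10
    n_replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if self.ne < 1 or self.n_generations < 1 or self.n_replicates < 1:
            raise ValueError("ne, n_generations and n_replicates must be >= 1")


def simulate_trajectories(config: DriftConfig) -> np.ndarray:
    """Replicate drift paths, shape (n_replicates, n_generations + 1); column
    0 is p0. Each step draws Binomial(2·ne, p_prev) / (2·ne)."""
    rng = np.random.default_rng(config.seed)
    m = 2 * config.ne
    paths = np.empty((config.n_replicates, config.n_generations + 1))
    paths[:, 0] = config.p0
    for t in range(1, config.n_generations + 1):
        paths[:, t] = rng.binomial(m, paths[:, t - 1]) / m
    return paths


def drift_variance(p0: float, ne: int, t: int) -> float:
    """Closed-form variance of the frequency after t generations:
    p0(1-p0)(1 - (1 - 1/(2Ne))^t)."""
    return p0 * (1.0 - p0) * (1.0 - (1.0 - 1.0 / (2.0 * ne)) ** t)


@dataclass
class DriftEnvelope:
    """Per-generation summary of the drift null; bounds are mean ∓ z·SD
    clamped to [0, 1]."""

    table: pd.DataFrame  # columns: generation, mean, sd, lower, upper
    z: float = Z_99

    def at(self, generation: int | None = None) -> pd.Series:
        gen = (self.table["generation"].max() if generation is None
               else generation)
        row = self.table.loc[self.table["generation"] == gen]
        if row.empty:
            raise ValueError(f"no envelope at generation {generation}")
        return row.iloc[0]


def build_envelope(paths: np.ndarray, z: float = Z_99) -> DriftEnvelope:
    """Per-generation mean, sample SD and z·SD envelope over replicates."""
    paths = np.asarray(paths, dtype=float)
    if paths.shape[0] < 2:
        raise ValueError("need at least two replicate paths")
    mean = paths.mean(axis=0)
    sd = paths.std(axis=0, ddof=1)
    tab = pd.DataFrame({
        "generation": np.arange(paths.shape[1]),
        "mean": mean,
        "sd": sd,
        "lower": np.clip(mean - z * sd, 0.0, 1.0),
        "upper": np.clip(mean + z * sd, 0.0, 1.0),
    })
    return DriftEnvelope(tab, z)


def mirror_envelope(env: DriftEnvelope) -> DriftEnvelope:
    """Envelope of the complementary allele (1 - p): used when the null was
    simulated for founder A but observations are founder-B probabilities."""
    tab = env.table.copy()
    tab["mean"], tab["sd"] = 1.0 - tab["mean"], tab["sd"]
    tab["lower"], tab["upper"] = 1.0 - env.table["upper"], 1.0 - env.table["lower"]
    return DriftEnvelope(tab, env.z)


def classify_enrichment(observed: np.ndarray, env: DriftEnvelope,
                        generation: int | None = None) -> np.ndarray:
    """Label each observed frequency against the envelope at the given
    generation (default: final): 'enriched' above the upper bound,
    'depleted' below the lower bound, else 'neutral'.

    ``observed`` must be on the same allele scale as the envelope: mirror the
    envelope first (``mirror_envelope``) when the null was simulated for the
    other founder.
    """
    observed = np.asarray(observed, dtype=float)
    if np.any((observed < 0) | (observed > 1)):
        raise ValueError("observed frequencies must lie in [0, 1]")
    row = env.at(generation)
    labels = np.full(observed.shape, "neutral", dtype=object)
    labels[observed > row["upper"]] = "enriched"
    labels[observed < row["lower"]] = "depleted"
    return labels
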