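"""ROH islands: top-1% per-SNP ROH frequency regions and cross-breed overlap.

A SNP is "in an island" when the fraction of a population's animals carrying
an ROH over it reaches the empirical 99th percentile of that population's
per-SNP frequency distribution. Consecutive above-threshold SNPs form a
region; nearby regions on the same chromosome are merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MarkerMap


@dataclass
class IslandRegion:
    population: str
    chrom: str
    start: int          # bp of first above-threshold SNP (1-based)
    end: int            # bp of last above-threshold SNP
    n_snps: int         # SNPs at or above threshold in the region
    peak_freq: float
    founder_overlap: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start exceeds end")


def island_threshold(freqs: np.ndarray) -> float:
    """Empirical 99th-percentile threshold of the per-SNP ROH frequencies.

    Uses the 'higher' order-statistic convention: the smallest observed value
    such that at most 1% of observations exceed it. A constant vector maps to
    that constant; all-zero frequencies give 0 with a warning.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size < 100:
        raise ValueError("need at least 100 markers for a stable 1% threshold")
    if np.all(freqs == 0):
        warnings.warn("all per-SNP ROH frequencies are zero; threshold is 0",
                      stacklevel=2)
        return 0.0
    return float(np.quantile(freqs, 0.99, method="higher"))


def extract_islands(freqs: np.ndarray, threshold: float, markers: MarkerMap,
                    population: str = "", merge_gap: int = 500_000) -> list:
    """Maximal runs of SNPs with frequency >= threshold, merged across gaps
    of at most ``merge_gap`` bp on the same chromosome."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    freqs = np.asarray(freqs, dtype=float)
    tab = markers.table
    regions: list = []
    for chrom in markers.chroms:
        idx = markers.chrom_indices(chrom)
        above = freqs[idx] >= threshold
        pos = tab["pos"].to_numpy()[idx]
        hits = np.flatnonzero(above)
        if hits.size == 0:
            continue
        # split runs where consecutive hits are separated by > merge_gap bp
        runs = np.split(hits, np.flatnonzero(np.diff(pos[hits]) > merge_gap) + 1)
        for run in runs:
            f = freqs[idx[run]]
            regions.append(IslandRegion(
                population=population, chrom=str(chrom),
                start=int(pos[run[0]]), end=int(pos[run[-1]]),
                n_snps=int(run.size), peak_freq=float(f.max())))
    return regions


def cross_population_overlap(regions_by_population: dict,
                             focal: str) -> list:
    """Flag each focal-population region with the other populations that have
    a bp-overlapping island on the same chromosome."""
    if len(regions_by_population) < 2:
        raise ValueError("need regions from at least two populations")
    out = []
    for reg in regions_by_population[focal]:
        flags = set()
        for pop, regs in regions_by_population.items():
            if pop == focal:
                continue
            for other in regs:
                if (other.chrom == reg.chrom and other.start <= reg.end
                        and reg.start <= other.end):
                    flags.add(pop)
                    break
        out.append(IslandRegion(reg.population, reg.chrom, reg.start, reg.end,
                                reg.n_snps, reg.peak_freq, frozenset(flags)))
    return out


def islands_to_frame(regions: list) -> pd.DataFrame:
    """Region table in Mb, mirroring the usual published layout."""
    rows = [{"population": r.population, "chrom": r.chrom,
             "start_mb": r.start / 1e6, "end_mb": r.end / 1e6,
             "length_mb": (r.end - r.start) / 1e6, "n_snps": r.n_snps,
             "peak_freq": r.peak_freq,
             "founder_overlap": ",".join(sorted(r.founder_overlap))}
            for r in regions]
    return pd.DataFrame(rows, columns=["population", "chrom", "start_mb",
                                       "end_mb", "length_mb", "n_snps",
                                       "peak_freq", "founder_overlap"])
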