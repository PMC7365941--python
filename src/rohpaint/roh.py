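"""Runs-of-homozygosity detection, generation classes and F_ROH.

An ROH is defined here as a maximal window of consecutive markers on one
chromosome of one animal that satisfies six constraints simultaneously:
at most ``max_het`` heterozygous calls, at most ``max_missing`` missing
calls, every adjacent-marker gap at most ``max_gap`` bp, span at least
``min_length`` bp, at least ``min_snps`` markers, and marker density at
least ``min_density`` SNPs per bp. Overlapping candidate windows are
resolved greedily, keeping the longest (then leftmost) first — a
deterministic rule that reproduces the constraint semantics of standard
SNP-array ROH scanners.

ROH are binned into four generation classes from the expected length of an
identical-by-descent haplotype, E(L | g) = 100/(2g) cM for a common ancestor
g generations back; with the default conversion of 1.282 cM/Mb the class
bounds fall at 13.0, 7.8 and 3.9 Mb for g = 3, 5, 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

#: Total autosome length of the Btau5.0.1 cattle assembly, the default
#: denominator of genome-wide F_ROH.
AUTOSOME_LENGTH_BP = 2_522_199_562

CM_PER_MB_DEFAULT = 1.282


@dataclass
class ROHParameters:
    """Scanner constraints; defaults are the standard SNP-array settings
    (1 Mb / 70 SNP / 2 het / 5 missing / 50 kb gap / 1 SNP per 50 kb)."""

    min_length: int = 1_000_000
    min_snps: int = 70
    max_het: int = 2
    max_missing: int = 5
    max_gap: int = 50_000
    min_density: float = 1.0 / 50_000

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        for name in ("min_snps", "max_het", "max_missing", "max_gap",
                     "min_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MinSnpInputs:
    """Inputs of the false-positive-controlled minimum-SNP formula."""

    ns: int                 # SNPs per individual
    ni: int                 # number of individuals
    het: float              # mean SNP heterozygosity
    alpha: float = 0.01     # tolerated fraction of false-positive ROH

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.het < 1.0:
            raise ValueError("het must lie strictly in (0, 1)")
        if self.ns < 1 or self.ni < 1:
            raise ValueError("ns and ni must be at least 1")


def min_snp_count(inputs: MinSnpInputs) -> int:
    """Minimum number of SNPs for an ROH to exceed chance homozygosity.

    l = ceil( ln(alpha / (ns·ni)) / ln(1 - het) ): the run length at which a
    chance run of homozygous calls across ns SNPs in ni individuals has
    probability below alpha.
    """
    l = math.log(inputs.alpha / (inputs.ns * inputs.ni)) / math.log(1.0 - inputs.het)
    return math.ceil(l)


@dataclass
class GenerationClassBounds:
    """cM→Mb conversion and the class bounds it implies."""

    cm_per_mb: float = CM_PER_MB_DEFAULT

    def bound_mb(self, generations: int) -> float:
        """Expected IBD-haplotype length (Mb) for a common ancestor
        ``generations`` back: (100 / 2g) cM converted at cm_per_mb."""
        return (100.0 / (2.0 * generations)) / self.cm_per_mb

    @property
    def bounds(self) -> tuple:
        b = (self.bound_mb(3), self.bound_mb(5), self.bound_mb(10))
        if not b[0] > b[1] > b[2]:
            raise ValueError("class bounds must decrease with generations")
        return b


@dataclass
class ROHSegment:
    """One homozygous run; coordinates 1-based inclusive marker bp."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int
    n_missing: int
    generation_class: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def classify_generation(seg: ROHSegment,
                        bounds: GenerationClassBounds | None = None) -> int:
    """Generation class 1..4 of a segment (4 = common ancestor < 3
    generations back). A length exactly on a bound goes to the older class
    (class intervals are closed on the right)."""
    b3, b5, b10 = (bounds or GenerationClassBounds()).bounds
    mb = seg.length / 1e6
    if mb > b3:
        return 4
    if mb > b5:
        return 3
    if mb > b10:
        return 2
    return 1


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _candidate_windows(is_het: np.ndarray, is_miss: np.ndarray,
                       pos: np.ndarray, p: ROHParameters):
    """Yield het/missing-maximal windows within gap-delimited blocks.

    Within a block (no adjacent gap exceeds max_gap) the rightmost valid end
    j(i) for each start i is non-decreasing, so a two-pointer sweep finds
    every window that cannot be extended in either direction.
    """
    n = len(pos)
    gaps = np.diff(pos)
    block_starts = np.concatenate(([0], np.flatnonzero(gaps > p.max_gap) + 1))
    block_ends = np.concatenate((block_starts[1:], [n]))  # half-open
    for lo, hi in zip(block_starts, block_ends):
        j = lo - 1
        het = miss = 0
        prev_j = -1
        for i in range(lo, hi):
            if j < i - 1:
                j = i - 1
                het = miss = 0
            while j + 1 < hi:
                nh = het + is_het[j + 1]
                nm = miss + is_miss[j + 1]
                if nh > p.max_het or nm > p.max_missing:
                    break
                j += 1
                het, miss = nh, nm
            if j >= i and (i == lo or j > prev_j):
                yield i, j, het, miss
            prev_j = j
            het -= is_het[i]
            miss -= is_miss[i]


def _best_window(is_het, is_miss, pos, p: ROHParameters, lo: int, hi: int):
    """Longest-then-leftmost valid window within the marker range [lo, hi)."""
    best = None
    for i, j, het, miss in _candidate_windows(is_het[lo:hi], is_miss[lo:hi],
                                              pos[lo:hi], p):
        i, j = i + lo, j + lo
        span = int(pos[j] - pos[i]) + 1
        count = j - i + 1
        if (span >= p.min_length and count >= p.min_snps
                and count / span >= p.min_density):
            if best is None or (-span, i) < (-best[0], best[1]):
                best = (span, i, j, het, miss)
    return best


def _select_windows(is_het, is_miss, pos, p: ROHParameters):
    """Greedy longest-then-leftmost non-overlapping valid windows.

    Equivalent to greedy selection over every valid contiguous window: after
    a window is taken, the flanking remainders are searched again, because a
    sub-window of a discarded overlapping candidate can itself be valid.
    """
    import heapq

    n = len(pos)
    heap = []
    first = _best_window(is_het, is_miss, pos, p, 0, n)
    if first is not None:
        heapq.heappush(heap, (-first[0], first[1], first, 0, n))
    chosen = []
    while heap:
        _negspan, _i, (span, i, j, het, miss), lo, hi = heapq.heappop(heap)
        chosen.append((i, j, het, miss))
        for sub in ((lo, i), (j + 1, hi)):
            if sub[1] - sub[0] > 0:
                b = _best_window(is_het, is_miss, pos, p, *sub)
                if b is not None:
                    heapq.heappush(heap, (-b[0], b[1], b, *sub))
    return sorted(chosen)


def detect_roh(g: GenotypeMatrix, params: ROHParameters | None = None,
               bounds: GenerationClassBounds | None = None) -> list:
    """Detect ROH for every sample; returns ROHSegment list with generation
    classes filled in. Requires markers sorted by chromosome and bp (the
    MarkerMap invariant)."""
    params = params or ROHParameters()
    bounds = bounds or GenerationClassBounds()
    segments: list = []
    tab = g.markers.table
    for chrom in g.markers.chroms:
        idx = g.markers.chrom_indices(chrom)
        pos = tab["pos"].to_numpy()[idx]
        calls_c = g.calls[:, idx]
        for i_s, sid in enumerate(g.sample_ids):
            calls = calls_c[i_s]
            is_het = (calls == 1).astype(np.int64)
            is_miss = (calls == MISSING).astype(np.int64)
            for i, j, het, miss in _select_windows(is_het, is_miss, pos, params):
                seg = ROHSegment(str(sid), str(chrom), int(pos[i]), int(pos[j]),
                                 j - i + 1, int(het), int(miss))
                seg.generation_class = classify_generation(seg, bounds)
                segments.append(seg)
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    return segments


def segments_to_frame(segments: list) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample": s.sample_id, "chrom": s.chrom, "start": s.start,
          "end": s.end, "length_bp": s.length, "n_snps": s.n_snps,
          "n_het": s.n_het, "n_missing": s.n_missing,
          "class": s.generation_class} for s in segments],
        columns=["sample", "chrom", "start", "end", "length_bp", "n_snps",
                 "n_het", "n_missing", "class"])


# ---------------------------------------------------------------------------
# F_ROH
# ---------------------------------------------------------------------------

def _check_disjoint(segs: list) -> None:
    by_key: dict = {}
    for s in segs:
        by_key.setdefault((s.sample_id, s.chrom), []).append((s.start, s.end))
    for key, ivs in by_key.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping ROH segments for {key}")


def f_roh(segments: list, sample_ids: list, scope: str = "genome",
          l_total: int = AUTOSOME_LENGTH_BP,
          chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Genomic inbreeding F_ROH = Σ L_ROH / L_total per sample.

    scope "genome": one row per sample against ``l_total``; "chromosome":
    one row per sample and chromosome against that chromosome's length;
    "class": one row per sample and generation class against ``l_total``
    (class rows sum to the genome row).
    """
    _check_disjoint(segments)
    if l_total <= 0:
        raise ValueError("l_total must be positive")
    rows = []
    if scope == "genome":
        tot = {str(s): 0 for s in sample_ids}
        for seg in segments:
            tot[seg.sample_id] += seg.length
        rows = [{"sample": s, "scope": "genome", "key": "genome",
                 "l_roh": tot[str(s)], "l_total": l_total,
                 "f_roh": tot[str(s)] / l_total} for s in sample_ids]
    elif scope == "chromosome":
        if not chrom_lengths:
            raise ValueError("chromosome scope requires chrom_lengths")
        for s in sample_ids:
            for chrom, lc in chrom_lengths.items():
                tot = sum(seg.length for seg in segments
                          if seg.sample_id == str(s) and seg.chrom == str(chrom))
                rows.append({"sample": s, "scope": "chromosome",
                             "key": str(chrom), "l_roh": tot, "l_total": lc,
                             "f_roh": tot / lc})
    elif scope == "class":
        for s in sample_ids:
            for cls in (1, 2, 3, 4):
                tot = sum(seg.length for seg in segments
                          if seg.sample_id == str(s)
                          and seg.generation_class == cls)
                rows.append({"sample": s, "scope": "class", "key": str(cls),
                             "l_roh": tot, "l_total": l_total,
                             "f_roh": tot / l_total})
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return pd.DataFrame(rows, columns=["sample", "scope", "key", "l_roh",
                                       "l_total", "f_roh"])


def snp_roh_frequency(segments: list, g: GenotypeMatrix,
                      population: str) -> np.ndarray:
    """Per-marker fraction of the population's animals whose ROH cover it."""
    samp_idx = g.samples_in(population)
    if samp_idx.size == 0:
        raise ValueError(f"population {population!r} is empty")
    members = {str(g.sample_ids[i]) for i in samp_idx}
    tab = g.markers.table
    count = np.zeros(g.n_markers, dtype=np.int64)
    pos_by_chrom = {chrom: (g.markers.chrom_indices(chrom),
                            tab["pos"].to_numpy()[g.markers.chrom_indices(chrom)])
                    for chrom in g.markers.chroms}
    for seg in segments:
        if seg.sample_id not in members:
            continue
        idx, pos = pos_by_chrom[seg.chrom]
        lo = np.searchsorted(pos, seg.start, side="left")
        hi = np.searchsorted(pos, seg.end, side="right")
        count[idx[lo:hi]] += 1
    return count / samp_idx.size
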