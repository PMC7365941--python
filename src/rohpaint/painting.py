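"""Chromosome painting by the Li–Stephens haplotype-copying model, and the
Weir–Cockerham Fst estimator.

A recipient haplotype is modelled as an imperfect mosaic of K donor
haplotypes. The hidden state at each marker is the donor being copied;
between adjacent markers at genetic distance d cM the chain stays on its
donor with probability e^(-rho*d) and otherwise re-selects uniformly among
all K donors (including the current one). Copying is imperfect: the emitted
allele matches the donor with probability 1-mu and mismatches with
probability mu, where mu = theta / (2(K + theta)) and theta defaults to
Watterson's 1 / sum_{i=1}^{K-1} 1/i. Posterior donor probabilities come from
the scaled forward-backward recursion; summing them within each donor breed
gives the per-SNP probability that the local ancestry is that breed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, HaplotypeSet, MarkerMap


@dataclass
class CopyingModelParams:
    """rho is the switch rate per cM; theta the miscopy (mutation) parameter,
    derived from the panel size when left unset; ``mu`` sets the miscopy
    probability directly (taking precedence over theta) for panels where the
    copying mismatch rate is known; self_copy admits the recipient's own
    population's other haplotypes into the donor panel."""

    rho: float = 1.0
    theta: float | None = None
    mu: float | None = None
    self_copy: bool = False

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.theta is not None and self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.mu is not None and not 0.0 <= self.mu < 0.5:
            raise ValueError("mu must lie in [0, 0.5)")


def watterson_theta(n_donors: int) -> float:
    if n_donors < 2:
        raise ValueError("need at least two donors")
    return 1.0 / sum(1.0 / i for i in range(1, n_donors))


def miscopy_probability(n_donors: int, theta: float | None = None) -> float:
    th = watterson_theta(n_donors) if theta is None else theta
    return th / (2.0 * (n_donors + th))


@dataclass
class AncestryProfile:
    """Per-SNP posterior breed-ancestry probabilities of one recipient
    haplotype; group probabilities sum to 1 at every SNP."""

    recipient_id: str
    groups: list                    # breed labels, fixed order
    probs: np.ndarray               # shape (n_markers, n_groups)
    log_likelihood: float

    def group_prob(self, group) -> np.ndarray:
        return self.probs[:, self.groups.index(group)]


def paint_haplotype(recipient: np.ndarray, donors: np.ndarray,
                    donor_groups, cm: np.ndarray,
                    params: CopyingModelParams | None = None,
                    recipient_id: str = "") -> AncestryProfile:
    """Forward-backward posterior of donor-breed ancestry along one
    chromosome.

    Parameters
    ----------
    recipient : (n,) 0/1 alleles of the haplotype to paint.
    donors : (K, n) 0/1 donor alleles on the same marker grid.
    donor_groups : length-K breed label per donor.
    cm : (n,) genetic positions in cM (non-decreasing).
    """
    params = params or CopyingModelParams()
    recipient = np.asarray(recipient)
    donors = np.asarray(donors)
    K, n = donors.shape
    if recipient.shape != (n,):
        raise ValueError("recipient and donors are on different marker grids")
    mu = params.mu if params.mu is not None else miscopy_probability(K, params.theta)
    emit = np.where(donors == recipient[None, :], 1.0 - mu, mu)  # (K, n)

    d = np.diff(np.asarray(cm, dtype=float))
    stay = np.exp(-params.rho * d)            # (n-1,)

    alpha = np.empty((n, K))
    scale = np.empty(n)
    a = np.full(K, 1.0 / K) * emit[:, 0]
    scale[0] = a.sum()
    if scale[0] == 0:
        raise ValueError("zero-probability path at marker 0 (mu = 0 with no "
                         "perfectly matching donor)")
    alpha[0] = a / scale[0]
    for t in range(1, n):
        prev = alpha[t - 1]
        a = (stay[t - 1] * prev + (1.0 - stay[t - 1]) / K) * emit[:, t]
        scale[t] = a.sum()
        if scale[t] == 0:
            raise ValueError(f"zero-probability path at marker {t}")
        alpha[t] = a / scale[t]

    beta = np.empty((n, K))
    beta[n - 1] = 1.0
    for t in range(n - 2, -1, -1):
        nxt = beta[t + 1] * emit[:, t + 1]
        beta[t] = (stay[t] * nxt + (1.0 - stay[t]) / K * nxt.sum()) / scale[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    groups = list(dict.fromkeys(donor_groups))
    donor_groups = np.asarray(list(donor_groups), dtype=object)
    probs = np.column_stack([gamma[:, donor_groups == g].sum(axis=1)
                             for g in groups])
    return AncestryProfile(recipient_id, groups, probs,
                           float(np.log(scale).sum()))


def paint_population(haps: HaplotypeSet, recipient_pop: str,
                     donor_pops: list,
                     params: CopyingModelParams | None = None) -> list:
    """Paint every haplotype of ``recipient_pop`` against donor panels drawn
    from ``donor_pops``, chromosome by chromosome; profiles are concatenated
    over chromosomes in marker order.

    With ``params.self_copy`` the other recipient-population haplotypes are
    added to the donor panel under their own group label.
    """
    params = params or CopyingModelParams()
    if haps.populations is None:
        raise ValueError("haplotype set has no population labels")
    pops2 = np.repeat(haps.populations, 2)
    donor_rows = np.flatnonzero(np.isin(pops2, donor_pops))
    recip_rows = np.flatnonzero(pops2 == recipient_pop)
    hap_ids = haps.haplotype_ids()
    cm_all = haps.markers.table["cm"].to_numpy()
    profiles = []
    for r in recip_rows:
        rows = donor_rows
        groups = pops2[donor_rows]
        if params.self_copy:
            others = recip_rows[recip_rows != r]
            rows = np.concatenate([donor_rows, others])
            groups = np.concatenate([groups, pops2[others]])
        per_chrom = []
        ll = 0.0
        for chrom in haps.markers.chroms:
            idx = haps.markers.chrom_indices(chrom)
            prof = paint_haplotype(haps.haplotypes[r, idx],
                                   haps.haplotypes[rows][:, idx],
                                   list(groups), cm_all[idx], params,
                                   recipient_id=hap_ids[r])
            per_chrom.append(prof)
            ll += prof.log_likelihood
        groups0 = per_chrom[0].groups
        probs = np.vstack([p.probs[:, [p.groups.index(g) for g in groups0]]
                           for p in per_chrom])
        profiles.append(AncestryProfile(hap_ids[r], groups0, probs, ll))
    return profiles


def average_ancestry(profiles: list, markers: MarkerMap,
                     region: tuple | None = None):
    """Mean breed probability over recipient haplotypes, per SNP.

    ``region`` = (chrom, start_bp, end_bp), 1-based inclusive; None averages
    over the whole grid. Returns (per-SNP mean DataFrame, region-mean dict).
    """
    if not profiles:
        raise ValueError("no ancestry profiles given")
    groups = profiles[0].groups
    stack = np.stack([p.probs[:, [p.groups.index(g) for g in groups]]
                      for p in profiles])
    mean = stack.mean(axis=0)
    tab = markers.table
    sel = np.ones(len(tab), dtype=bool)
    if region is not None:
        chrom, lo, hi = region
        sel = ((tab["chrom"] == str(chrom)) & (tab["pos"] >= lo)
               & (tab["pos"] <= hi)).to_numpy()
        if not sel.any():
            raise ValueError("region contains no markers")
    out = tab.loc[sel, ["chrom", "pos"]].reset_index(drop=True)
    for k, g in enumerate(groups):
        out[f"p_{g}"] = mean[sel, k]
    region_mean = {g: float(mean[sel, k].mean()) for k, g in enumerate(groups)}
    return out, region_mean


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) Fst
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    populations: tuple
    a: np.ndarray       # among-population variance component per SNP
    b: np.ndarray       # among-individual within-population
    c: np.ndarray       # within-individual
    estimate: float     # ratio-of-sums sum(a) / sum(a+b+c)


def weir_cockerham_fst(g: GenotypeMatrix, pop_pair: tuple,
                       region: tuple | None = None) -> FstResult:
    """Two-population Weir & Cockerham (1984) theta-hat.

    Per-SNP variance components a, b, c use sample sizes, allele frequencies
    and observed heterozygosity of each population; the region estimate is
    the ratio of summed components. Monomorphic SNPs (and SNPs where a
    population has fewer than two non-missing calls) contribute nothing.
    """
    sel = np.ones(g.n_markers, dtype=bool)
    if region is not None:
        chrom, lo, hi = region
        tab = g.markers.table
        sel = ((tab["chrom"] == str(chrom)) & (tab["pos"] >= lo)
               & (tab["pos"] <= hi)).to_numpy()
    idx1 = g.samples_in(pop_pair[0])
    idx2 = g.samples_in(pop_pair[1])
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError("each population needs at least two samples")

    def _stats(rows):
        calls = g.calls[rows][:, sel]
        obs = calls != MISSING
        n = obs.sum(axis=0).astype(float)             # diploid counts
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * np.maximum(n, 1e-12)), np.nan)
            h = np.where(n > 0, (calls == 1).sum(axis=0) / np.maximum(n, 1e-12),
                         np.nan)
        return n, p, h

    n1, p1, h1 = _stats(idx1)
    n2, p2, h2 = _stats(idx2)
    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        raise ValueError("no SNP with at least two informative samples per "
                         "population in the region")
    r = 2.0
    nbar = (n1 + n2) / r
    nc = ((n1 + n2) - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                     - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2.0
    mono = (pbar == 0) | (pbar == 1)
    for comp in (a, b, c):
        comp[~ok | mono] = 0.0
        comp[np.isnan(comp)] = 0.0
    denom = (a + b + c).sum()
    est = float(a.sum() / denom) if denom != 0 else float("nan")
    return FstResult(tuple(pop_pair), a, b, c, est)
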