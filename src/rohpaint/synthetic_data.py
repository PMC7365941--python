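"""Forward simulation of a two-founder composite breed with known truth.

Two founder populations diverge from a common ancestral gene pool under the
Balding–Nichols model (a single Fst parameter per founder). A composite
population is founded as haplotype mosaics with a configurable expected
founder-A fraction (default 5/8, the Angus share of Brangus), then mated at
random for a configurable number of generations with few sires per
generation so that autozygosity — and hence runs of homozygosity —
accumulates. Crossovers follow a Poisson process on the genetic map
(Haldane, no interference). True local ancestry of every haplotype is
propagated through each meiosis, and the full pedigree is recorded, so that
every downstream estimate (ROH, F_ROH, painting, drift) can be validated
against truth.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import (MISSING, GenotypeMatrix, HaplotypeSet, MarkerMap,
                          write_bed, write_genetic_map, write_ped_map,
                          write_phased_vcf)

FOUNDER_A = "founderA"
FOUNDER_B = "founderB"
COMPOSITE = "composite"


@dataclass
class SimConfig:
    """Parameters of the composite-breed simulation.

    Defaults are sized for a desk-scale genome: 3 autosomes of 50 Mb with
    2,500 evenly spaced markers each (20 kb spacing, dense enough for the
    standard ROH scanner settings), founder divergence Fst = 0.15 on each
    side (of the order of the taurine/indicine split), a composite of 50
    animals founded at 62.5% founder-A and bred for 10 generations with 5
    sires per generation.
    """

    n_markers_per_chrom: int = 2500
    n_chromosomes: int = 3
    chrom_length: int = 50_000_000          # bp
    map_rate: float = 1.282                 # cM per Mb
    fst_a: float = 0.15
    fst_b: float = 0.15
    n_founders_a: int = 30
    n_founders_b: int = 30
    n_composite: int = 50
    admix_prop_a: float = 0.625
    n_generations: int = 10
    n_sires_per_gen: int = 5
    founding_switch_rate: float = 3.0       # ancestry switches per Morgan at gen 0
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    record_all_generations: bool = False
    sweep_region: tuple | None = None       # (chrom index, start bp, end bp)
    seed: int = 0

    def __post_init__(self) -> None:
        # the endpoints are admitted as degenerate single-founder composites
        if not 0.0 <= self.admix_prop_a <= 1.0:
            raise ValueError("admix_prop_a must lie in [0, 1]")
        for name in ("fst_a", "fst_b"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("n_markers_per_chrom", "n_chromosomes", "chrom_length",
                     "n_founders_a", "n_founders_b", "n_composite",
                     "n_generations", "n_sires_per_gen"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sires_per_gen > self.n_composite / 2:
            raise ValueError("n_sires_per_gen may not exceed n_composite/2")

    @property
    def chrom_names(self) -> list:
        return [str(c + 1) for c in range(self.n_chromosomes)]

    @property
    def morgans_per_chrom(self) -> float:
        return self.chrom_length * self.map_rate / 1e6 / 100.0


@dataclass
class TrueAncestryTrack:
    """Ground-truth founder ancestry of one haplotype.

    ``segments`` holds 0-based half-open (chrom, start, end, label) intervals
    that tile each chromosome without overlap; labels are "A"/"B".
    """

    haplotype_id: str
    segments: list  # of (chrom, start, end, label)

    def validate(self, chrom_length: int) -> None:
        by_chrom: dict = {}
        for chrom, s, e, lab in self.segments:
            if lab not in ("A", "B"):
                raise ValueError(f"bad ancestry label {lab!r}")
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            if ivs[0][0] != 0 or ivs[-1][1] != chrom_length:
                raise ValueError(f"{chrom}: segments do not span the chromosome")
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if e1 != s2:
                    raise ValueError(f"{chrom}: segments do not tile ({e1} vs {s2})")

    def labels_at(self, markers: MarkerMap) -> np.ndarray:
        """Ancestry label ("A"/"B") at each marker of ``markers``."""
        out = np.empty(len(markers), dtype="U1")
        tab = markers.table
        for chrom, s, e, lab in self.segments:
            sel = ((tab["chrom"] == chrom) & (tab["pos"] - 1 >= s)
                   & (tab["pos"] - 1 < e)).to_numpy()
            out[sel] = lab
        return out


@dataclass
class SimulationResult:
    config: SimConfig
    genotypes: GenotypeMatrix           # founder panels + composite, with QC noise
    haplotypes: HaplotypeSet            # clean phased truth, same samples
    truth: list                         # TrueAncestryTrack per composite haplotype
    pedigree: pd.DataFrame              # id, sire, dam, generation
    founder_freqs: pd.DataFrame         # chrom, pos, p_ancestral, p_a, p_b


# ---------------------------------------------------------------------------
# founder allele frequencies (Balding–Nichols)
# ---------------------------------------------------------------------------

def sample_founder_frequencies(config: SimConfig,
                               rng: np.random.Generator | None = None
                               ) -> pd.DataFrame:
    """Draw per-marker allele frequencies for founder populations A and B.

    The ancestral frequency p0 is Uniform(0.05, 0.95); each founder's
    frequency is Beta(p0(1-F)/F, (1-p0)(1-F)/F) with F its Fst from the
    ancestral pool, which has mean p0 and variance F·p0(1-p0). F = 0
    degenerates to the ancestral frequency itself.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_markers_per_chrom * config.n_chromosomes
    p0 = rng.uniform(0.05, 0.95, size=n)

    def _draw(fst: float) -> np.ndarray:
        if fst == 0.0:
            return p0.copy()
        scale = (1.0 - fst) / fst
        return rng.beta(p0 * scale, (1.0 - p0) * scale)

    chroms = np.repeat(config.chrom_names, config.n_markers_per_chrom)
    spacing = config.chrom_length / config.n_markers_per_chrom
    pos = np.tile((np.arange(config.n_markers_per_chrom) * spacing
                   + spacing / 2).astype(int) + 1, config.n_chromosomes)
    return pd.DataFrame({"chrom": chroms, "pos": pos, "p_ancestral": p0,
                         "p_a": _draw(config.fst_a), "p_b": _draw(config.fst_b)})


def _marker_map(config: SimConfig, freqs: pd.DataFrame) -> MarkerMap:
    tab = freqs[["chrom", "pos"]].copy()
    tab["marker_id"] = [f"snp_{c}_{p}" for c, p in zip(tab["chrom"], tab["pos"])]
    tab["cm"] = tab["pos"] * config.map_rate / 1e6
    tab["a1"] = "A"
    tab["a2"] = "B"
    return MarkerMap(tab[["chrom", "marker_id", "pos", "cm", "a1", "a2"]])


# ---------------------------------------------------------------------------
# haplotype machinery
# ---------------------------------------------------------------------------
# One haplotype = per-chromosome (alleles, ancestry breakpoints). Ancestry is
# a list of (end_bp, label) with implicit start at the previous end; the last
# end equals the chromosome length.

def _mosaic_haplotype(config: SimConfig, chrom_idx: int, p_a: np.ndarray,
                      p_b: np.ndarray, rng: np.random.Generator):
    """Generation-0 composite haplotype: a two-state ancestry mosaic whose
    alleles are fresh Bernoulli draws from the segment's founder frequency."""
    L = config.chrom_length
    n_switch = rng.poisson(config.founding_switch_rate * config.morgans_per_chrom)
    cuts = np.unique(rng.uniform(0, L, size=n_switch).astype(int))
    ends = np.append(cuts[(cuts > 0) & (cuts < L)], L)
    labels = np.where(rng.random(len(ends)) < config.admix_prop_a, "A", "B")
    spacing = L / config.n_markers_per_chrom
    pos = (np.arange(config.n_markers_per_chrom) * spacing + spacing / 2).astype(int)
    seg_of_marker = np.searchsorted(ends, pos, side="right")
    p = np.where(labels[seg_of_marker] == "A", p_a, p_b)
    alleles = (rng.random(len(p)) < p).astype(np.int8)
    return alleles, list(zip(ends.tolist(), labels.tolist()))


def _coalesce(segs: list) -> list:
    out = []
    for end, lab in segs:
        if out and out[-1][1] == lab:
            out[-1] = (end, lab)
        else:
            out.append((end, lab))
    return out


def _slice_anc(segs: list, lo: int, hi: int) -> list:
    """Ancestry of [lo, hi) as (end, label) pairs ending at hi."""
    out = []
    i = bisect.bisect_right([e for e, _ in segs], lo)
    for end, lab in segs[i:]:
        if end >= hi:
            out.append((hi, lab))
            break
        out.append((end, lab))
    return out


def _gamete(hap_pair, config: SimConfig, chrom_idx: int,
            rng: np.random.Generator):
    """One meiosis on one chromosome: Poisson crossovers on the genetic map
    (Haldane), alternating between the parent's two haplotypes."""
    L = config.chrom_length
    n_x = rng.poisson(config.morgans_per_chrom)
    cuts = np.unique(rng.uniform(0, L, size=n_x).astype(int))
    cuts = cuts[(cuts > 0) & (cuts < L)]
    start = int(rng.integers(2))
    spacing = L / config.n_markers_per_chrom
    pos = (np.arange(config.n_markers_per_chrom) * spacing + spacing / 2).astype(int)
    src = (start + np.searchsorted(cuts, pos, side="right")) % 2
    alleles = np.where(src == 0, hap_pair[0][0], hap_pair[1][0]).astype(np.int8)
    anc = []
    bounds = np.concatenate(([0], cuts, [L]))
    for k in range(len(bounds) - 1):
        parent = (start + k) % 2
        anc.extend(_slice_anc(hap_pair[parent][1],
                              int(bounds[k]), int(bounds[k + 1])))
    return alleles, _coalesce(anc)


# ---------------------------------------------------------------------------
# the composite simulation
# ---------------------------------------------------------------------------

def simulate_composite(config: SimConfig) -> SimulationResult:
    """Run the full founder + composite simulation.

    Returns genotyped founder panels (fresh Balding–Nichols draws, distinct
    from the composite's founding stock so painting cannot cheat by exact
    donor lookup), the composite animals with phased haplotypes, true
    ancestry tracks, and the recorded pedigree.
    """
    rng = np.random.default_rng(config.seed)
    freqs = sample_founder_frequencies(config, rng)
    markers = _marker_map(config, freqs)
    n_chrom = config.n_chromosomes
    nm = config.n_markers_per_chrom
    p_a = [freqs["p_a"].to_numpy()[c * nm:(c + 1) * nm] for c in range(n_chrom)]
    p_b = [freqs["p_b"].to_numpy()[c * nm:(c + 1) * nm] for c in range(n_chrom)]

    # reference founder panels (the genotyped animals / painting donors)
    def _panel(n_ind: int, p: list) -> list:
        anims = []
        for _ in range(n_ind):
            haps = []
            for _h in range(2):
                per_chrom = []
                for c in range(n_chrom):
                    al = (rng.random(nm) < p[c]).astype(np.int8)
                    per_chrom.append((al, [(config.chrom_length, "·")]))
                haps.append(per_chrom)
            anims.append(haps)
        return anims

    panel_a = _panel(config.n_founders_a, p_a)
    panel_b = _panel(config.n_founders_b, p_b)

    # generation 0 composite: independent founding mosaics
    def _founding_animal():
        haps = []
        for _h in range(2):
            per_chrom = [
                _mosaic_haplotype(config, c, p_a[c], p_b[c], rng)
                for c in range(n_chrom)
            ]
            haps.append(per_chrom)
        return haps

    current = [_founding_animal() for _ in range(config.n_composite)]

    if config.sweep_region is not None:
        # a selective sweep fixes one founder-A haplotype in the composite;
        # that haplotype segregates in breed A, so it is drawn from the panel
        c, lo, hi = config.sweep_region
        spacing = config.chrom_length / nm
        pos = (np.arange(nm) * spacing + spacing / 2).astype(int)
        in_reg = (pos >= lo) & (pos < hi)
        src = panel_a[int(rng.integers(config.n_founders_a))][int(rng.integers(2))]
        sweep_alleles = src[c][0][in_reg].copy()
        for animal in current:
            for hap in animal:
                al, anc = hap[c]
                al[in_reg] = sweep_alleles
                new = _slice_anc(anc, 0, lo) if lo > 0 else []
                new.append((hi, "A"))
                if hi < config.chrom_length:
                    new.extend(_slice_anc(anc, hi, config.chrom_length))
                hap[c] = (al, _coalesce(new))

    ped_rows = [{"id": f"G0_{i}", "sire": "0", "dam": "0", "generation": 0}
                for i in range(config.n_composite)]
    ids = [f"G0_{i}" for i in range(config.n_composite)]
    kept = [(ids, current)] if config.record_all_generations else []

    for gen in range(1, config.n_generations + 1):
        sire_idx = rng.choice(config.n_composite, size=config.n_sires_per_gen,
                              replace=False)
        dam_idx = np.setdiff1d(np.arange(config.n_composite), sire_idx)
        nxt, nxt_ids = [], []
        for i in range(config.n_composite):
            s = int(rng.choice(sire_idx))
            d = int(rng.choice(dam_idx))
            child = []
            for parent in (s, d):
                animal = current[parent]
                gam = [
                    _gamete((animal[0][c], animal[1][c]), config, c, rng)
                    for c in range(n_chrom)
                ]
                child.append(gam)
            nxt.append(child)
            cid = f"G{gen}_{i}"
            nxt_ids.append(cid)
            ped_rows.append({"id": cid, "sire": ids[s], "dam": ids[d],
                             "generation": gen})
        current, ids = nxt, nxt_ids
        if config.record_all_generations:
            kept.append((ids, current))
    if not config.record_all_generations:
        kept = [(ids, current)]

    # assemble containers -------------------------------------------------
    sample_ids, pops, hap_rows, truth = [], [], [], []
    for i in range(config.n_founders_a):
        sample_ids.append(f"A_{i}")
        pops.append(FOUNDER_A)
        for h in range(2):
            hap_rows.append(np.concatenate([panel_a[i][h][c][0]
                                            for c in range(n_chrom)]))
    for i in range(config.n_founders_b):
        sample_ids.append(f"B_{i}")
        pops.append(FOUNDER_B)
        for h in range(2):
            hap_rows.append(np.concatenate([panel_b[i][h][c][0]
                                            for c in range(n_chrom)]))
    for gen_ids, animals in kept:
        for cid, animal in zip(gen_ids, animals):
            sample_ids.append(cid)
            pops.append(COMPOSITE)
            for h in range(2):
                hap_rows.append(np.concatenate([animal[h][c][0]
                                                for c in range(n_chrom)]))
                segs = []
                for c in range(n_chrom):
                    prev = 0
                    for end, lab in animal[h][c][1]:
                        segs.append((config.chrom_names[c], prev, end, lab))
                        prev = end
                truth.append(TrueAncestryTrack(f"{cid}_h{h + 1}", segs))

    haps = HaplotypeSet(sample_ids, np.vstack(hap_rows), markers,
                        populations=np.array(pops, dtype=object))
    calls = haps.dosages()

    # genotyping noise on the diploid calls only; phased truth stays clean
    if config.genotype_error_rate > 0:
        flip = rng.random(calls.shape) < config.genotype_error_rate
        calls = np.where(flip, rng.integers(0, 3, size=calls.shape), calls)
    if config.missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < config.missing_rate,
                         MISSING, calls)
    geno = GenotypeMatrix(sample_ids, np.array(pops, dtype=object),
                          calls.astype(np.int8), markers)
    ped = pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "generation"])
    return SimulationResult(config, geno, haps, truth, ped, freqs)


def recommended_copying_params(config: SimConfig):
    """Copying-model parameters matched to this generator.

    The founder panels carry no within-breed haplotype sharing, so copying
    from the correct breed still mismatches at the within-breed
    heterozygosity: mu = 2·(1-F)·E[p0(1-p0)], with E[p0(1-p0)] = 0.1825 for
    the Uniform(0.05, 0.95) ancestral frequencies. The switch rate rho is the
    expected density of true ancestry breakpoints, roughly
    (founding_switch_rate + n_generations) per Morgan.
    """
    from .painting import CopyingModelParams

    het0 = 0.25 - (0.95 - 0.05) ** 2 / 12.0
    fbar = (config.fst_a + config.fst_b) / 2.0
    mu = min(0.49, 2.0 * (1.0 - fbar) * het0)
    rho = (config.founding_switch_rate + config.n_generations) / 100.0
    return CopyingModelParams(rho=rho, mu=mu)


def true_ancestry_fraction(result: SimulationResult, label: str = "A") -> float:
    """Genome-wide fraction of composite haplotype length with the given
    founder label, from the truth tracks."""
    tot = hit = 0
    for track in result.truth:
        for _c, s, e, lab in track.segments:
            tot += e - s
            hit += (e - s) if lab == label else 0
    return hit / tot


# ---------------------------------------------------------------------------
# truth-track serialization (BED, 0-based half-open)
# ---------------------------------------------------------------------------

def write_truth(tracks: list, path: str) -> None:
    """Write ancestry tracks as a BED file: chrom, start, end, hap id, label."""
    with open(path, "w") as fh:
        for track in tracks:
            for chrom, s, e, lab in track.segments:
                fh.write(f"{chrom}\t{s}\t{e}\t{track.haplotype_id}\t{lab}\n")


def read_truth(path: str) -> list:
    by_hap: dict = {}
    order = []
    with open(path) as fh:
        for line in fh:
            chrom, s, e, hap, lab = line.rstrip("\n").split("\t")
            if hap not in by_hap:
                by_hap[hap] = []
                order.append(hap)
            by_hap[hap].append((chrom, int(s), int(e), lab))
    return [TrueAncestryTrack(h, by_hap[h]) for h in order]


def write_dataset(result: SimulationResult, outdir: str) -> dict:
    """Write the simulated dataset in its on-disk formats.

    Produces PLINK PED/MAP and BED/BIM/FAM, a phased VCF, a genetic-map TSV,
    a pedigree TSV and the BED truth tracks; returns the paths.
    """
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "plink": os.path.join(outdir, "genotypes"),
        "vcf": os.path.join(outdir, "haplotypes.vcf"),
        "map": os.path.join(outdir, "genetic_map.tsv"),
        "pedigree": os.path.join(outdir, "pedigree.tsv"),
        "truth": os.path.join(outdir, "truth.bed"),
    }
    write_ped_map(result.genotypes, paths["plink"])
    write_bed(result.genotypes, paths["plink"])
    write_phased_vcf(result.haplotypes, paths["vcf"])
    write_genetic_map(result.genotypes.markers, paths["map"])
    result.pedigree.to_csv(paths["pedigree"], sep="\t", index=False)
    write_truth(result.truth, paths["truth"])
    return paths
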