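"""Genotype containers, PLINK/VCF input-output and quality-control filters.

Diploid genotypes are stored as alt-allele dosage (0, 1, 2) with -1 for
missing, one row per sample, one column per marker, tied to a marker map.
Coordinates are 1-based inclusive everywhere except BED output, which is
0-based half-open per that format's convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

#: PLINK v1.00 .bed magic bytes followed by the SNP-major mode byte.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Per-marker table: chromosome, bp (1-based), cM, ref/alt alleles.

    Positions must be strictly increasing within a chromosome and cM must be
    non-decreasing with bp.
    """

    table: pd.DataFrame  # columns: chrom, marker_id, pos, cm, a1, a2

    def __post_init__(self) -> None:
        req = {"chrom", "marker_id", "pos", "cm", "a1", "a2"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            if np.any(np.diff(sub["cm"].to_numpy()) < 0):
                raise ValueError(f"cM positions decrease with bp on {chrom}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[idx].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Samples x markers diploid calls in {0,1,2,-1} with population labels."""

    sample_ids: list
    populations: np.ndarray  # str per sample, e.g. founderA/founderB/composite
    calls: np.ndarray        # int8, shape (n_samples, n_markers)
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.calls.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("population labels inconsistent with samples")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,-1}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def samples_in(self, population) -> np.ndarray:
        return np.flatnonzero(self.populations == population)

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids, self.populations,
                              self.calls[:, idx], self.markers.subset(idx))

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix([self.sample_ids[i] for i in idx],
                              self.populations[idx], self.calls[idx], self.markers)


@dataclass
class HaplotypeSet:
    """Two phased haplotypes per sample, alleles in {0,1}.

    Row 2*i and 2*i+1 hold the two haplotypes of sample i; their sum equals
    the diploid dosage at every non-missing site.
    """

    sample_ids: list
    haplotypes: np.ndarray  # int8, shape (2*n_samples, n_markers)
    markers: MarkerMap
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (2 * len(self.sample_ids), len(self.markers)):
            raise ValueError("haplotype array inconsistent with samples x markers")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def dosages(self) -> np.ndarray:
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def haplotype_ids(self) -> list:
        return [f"{s}_h{k}" for s in self.sample_ids for k in (1, 2)]

    def to_genotypes(self) -> GenotypeMatrix:
        pops = (self.populations if self.populations is not None
                else np.array(["unknown"] * self.n_samples, dtype=object))
        return GenotypeMatrix(self.sample_ids, pops, self.dosages(), self.markers)


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------

def write_ped_map(g: GenotypeMatrix, prefix: str) -> None:
    """Write PLINK PED/MAP text files; family id carries the population label."""
    m = g.markers.table
    with open(f"{prefix}.map", "w") as fh:
        for row in m.itertuples():
            fh.write(f"{row.chrom}\t{row.marker_id}\t{row.cm:.6f}\t{row.pos}\n")
    a1 = m["a1"].to_numpy()
    a2 = m["a2"].to_numpy()
    with open(f"{prefix}.ped", "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fields = [str(g.populations[i]), str(sid), "0", "0", "0", "-9"]
            row = g.calls[i]
            for j, c in enumerate(row):
                if c == MISSING:
                    fields.extend(("0", "0"))
                elif c == 0:
                    fields.extend((a1[j], a1[j]))
                elif c == 1:
                    fields.extend((a1[j], a2[j]))
                else:
                    fields.extend((a2[j], a2[j]))
            fh.write(" ".join(fields) + "\n")


def _read_map(path: str) -> MarkerMap:
    tab = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["chrom", "marker_id", "cm", "pos"],
                      dtype={"chrom": str, "marker_id": str})
    tab["a1"] = "A"
    tab["a2"] = "B"
    return MarkerMap(tab[["chrom", "marker_id", "pos", "cm", "a1", "a2"]])


def read_ped_map(prefix: str) -> GenotypeMatrix:
    """Read PED/MAP text data.

    PED carries no ref/alt designation, so dosages are oriented by a
    companion ``prefix.bim`` when one exists, else by lexicographic allele
    order (deterministic, but monomorphic markers are then coded 0).
    """
    import os
    markers = _read_map(f"{prefix}.map")
    n_markers = len(markers)
    bim_alleles = None
    if os.path.exists(f"{prefix}.bim"):
        bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                          names=["chrom", "marker_id", "cm", "pos", "a1", "a2"],
                          dtype=str)
        if len(bim) == n_markers:
            bim_alleles = list(zip(bim["a1"], bim["a2"]))
    sample_ids, pops, rows = [], [], []
    # allele identities are learned from the file: first seen = a1
    allele1 = [None] * n_markers
    allele2 = [None] * n_markers
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"PED row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * n_markers}"
                )
            pops.append(parts[0])
            sample_ids.append(parts[1])
            row = np.empty(n_markers, dtype=np.int8)
            al = parts[6:]
            for j in range(n_markers):
                x, y = al[2 * j], al[2 * j + 1]
                if x == "0" or y == "0":
                    row[j] = MISSING
                    continue
                for a in (x, y):
                    if allele1[j] is None:
                        allele1[j] = a
                    elif a != allele1[j] and allele2[j] is None:
                        allele2[j] = a
                    elif a not in (allele1[j], allele2[j]):
                        raise ValueError(f"marker {j}: more than two alleles in PED")
                row[j] = (x == allele2[j]) + (y == allele2[j])
            rows.append(row)
    geno = np.vstack(rows) if rows else np.empty((0, n_markers), np.int8)
    for j in range(n_markers):
        if bim_alleles is not None:
            b1, b2 = bim_alleles[j]
            if allele1[j] == b2:  # first-seen allele was the alt: flip codes
                nz = geno[:, j] != MISSING
                geno[nz, j] = 2 - geno[nz, j]
            allele1[j], allele2[j] = b1, b2
        elif (allele2[j] is not None and allele1[j] is not None
              and allele1[j] > allele2[j]):
            allele1[j], allele2[j] = allele2[j], allele1[j]
            nz = geno[:, j] != MISSING
            geno[nz, j] = 2 - geno[nz, j]
    tab = markers.table.copy()
    tab["a1"] = [a if a is not None else "A" for a in allele1]
    tab["a2"] = [a if a is not None else "B" for a in allele2]
    return GenotypeMatrix(sample_ids, np.array(pops, dtype=object), geno,
                          MarkerMap(tab))


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM), v1.00, SNP-major
# ---------------------------------------------------------------------------

# 2-bit codes in a .bed byte: 00 hom a1, 01 missing, 10 het, 11 hom a2.
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)


def write_bed(g: GenotypeMatrix, prefix: str) -> None:
    m = g.markers.table
    with open(f"{prefix}.bim", "w") as fh:
        for row in m.itertuples():
            fh.write(f"{row.chrom}\t{row.marker_id}\t{row.cm:.6f}\t{row.pos}"
                     f"\t{row.a1}\t{row.a2}\n")
    with open(f"{prefix}.fam", "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fh.write(f"{g.populations[i]} {sid} 0 0 0 -9\n")
    n = g.n_samples
    n_bytes = (n + 3) // 4
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(g.n_markers):
            buf = bytearray(n_bytes)
            col = g.calls[:, j]
            for i in range(n):
                buf[i >> 2] |= _BED_ENCODE[int(col[i])] << ((i & 3) * 2)
            fh.write(bytes(buf))


def read_bed(prefix: str) -> GenotypeMatrix:
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "marker_id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "marker_id": str, "a1": str, "a2": str})
    markers = MarkerMap(bim[["chrom", "marker_id", "pos", "cm", "a1", "a2"]])
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "sire", "dam", "sex", "pheno"],
                      dtype=str)
    n, p = len(fam), len(markers)
    n_bytes = (n + 3) // 4
    with open(f"{prefix}.bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK v1.00 bed file")
    if len(raw) != 3 + n_bytes * p:
        raise ValueError(
            f"{prefix}.bed: size {len(raw)} does not match "
            f"{n} samples x {p} markers (expected {3 + n_bytes * p})"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, n_bytes)
    # unpack 2-bit fields, sample-index little-endian within a byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    calls = _BED_DECODE[codes.reshape(p, n_bytes * 4)[:, :n]].T
    return GenotypeMatrix(list(fam["iid"]), fam["fid"].to_numpy(dtype=object),
                          calls, markers)


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read PLINK data from ``prefix``, preferring BED/BIM/FAM over PED/MAP."""
    import os
    if os.path.exists(f"{prefix}.bed"):
        return read_bed(prefix)
    if os.path.exists(f"{prefix}.ped"):
        return read_ped_map(prefix)
    raise FileNotFoundError(f"no {prefix}.bed or {prefix}.ped found")


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------

def write_phased_vcf(h: HaplotypeSet, path: str) -> None:
    """Write a minimal phased VCF 4.2 with pipe-separated GT fields."""
    m = h.markers.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, sub in m.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in h.sample_ids) + "\n")
        hap = h.haplotypes
        for j, row in enumerate(m.itertuples()):
            gts = "\t".join(f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}"
                            for i in range(h.n_samples))
            fh.write(f"{row.chrom}\t{row.pos}\t{row.marker_id}\t{row.a1}"
                     f"\t{row.a2}\t.\t.\t.\tGT\t{gts}\n")


def read_phased_vcf(path: str) -> HaplotypeSet:
    """Read a biallelic, fully phased VCF into a HaplotypeSet.

    Raises ValueError naming the record if any GT is unphased or missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms, ids, pos, ref, alt, rows = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} is not biallelic")
        gts = rec.genotype.array()  # (n_samples, 3): allele1, allele2, phased
        if np.any(gts[:, 2] == 0) or np.any(gts[:, :2] < 0):
            raise ValueError(f"unphased or missing GT at {rec.CHROM}:{rec.POS}")
        rows.append(gts[:, :2].astype(np.int8).reshape(-1))
        chroms.append(rec.CHROM)
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}_{rec.POS}")
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
    vcf.close()
    tab = pd.DataFrame({"chrom": chroms, "marker_id": ids, "pos": pos,
                        "cm": 0.0, "a1": ref, "a2": alt})
    haps = (np.vstack(rows).T if rows
            else np.empty((2 * len(samples), 0), np.int8))
    return HaplotypeSet(samples, haps, MarkerMap(tab))


# ---------------------------------------------------------------------------
# genetic map TSV
# ---------------------------------------------------------------------------

def write_genetic_map(m: MarkerMap, path: str) -> None:
    m.table[["chrom", "pos", "cm"]].to_csv(path, sep="\t", index=False)


def attach_genetic_map(markers: MarkerMap, path: str) -> MarkerMap:
    """Return a copy of ``markers`` with cM looked up from a chrom/pos/cm TSV."""
    gm = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    key = gm.set_index(["chrom", "pos"])["cm"]
    tab = markers.table.copy()
    tab["cm"] = [key.loc[(c, p)] for c, p in zip(tab["chrom"], tab["pos"])]
    return MarkerMap(tab)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def filter_markers(g: GenotypeMatrix, min_call_rate: float = 0.95,
                   min_maf: float = 0.01,
                   per_population_maf: bool = False) -> GenotypeMatrix:
    """Drop markers below the call-rate or minor-allele-frequency threshold.

    MAF is computed on pooled non-missing calls across all populations by
    default; with ``per_population_maf`` a marker is kept if it passes the
    MAF bound in any one population. Marker order is preserved.
    """
    obs = g.calls != MISSING
    call_rate = obs.mean(axis=0) if g.n_samples else np.ones(g.n_markers)
    keep = call_rate >= min_call_rate

    def _maf(rows: np.ndarray) -> np.ndarray:
        o = g.calls[rows] != MISSING
        n = o.sum(axis=0)
        alt = np.where(o, g.calls[rows], 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), 0.0)
        return np.minimum(p, 1 - p)

    if per_population_maf:
        pops = np.unique(g.populations)
        maf_ok = np.any([_maf(np.flatnonzero(g.populations == p)) >= min_maf
                         for p in pops], axis=0)
    else:
        maf_ok = _maf(np.arange(g.n_samples)) >= min_maf
    keep &= maf_ok
    if not keep.any():
        warnings.warn("all markers removed by QC filters", stacklevel=2)
    return g.subset_markers(np.flatnonzero(keep))


def filter_samples(g: GenotypeMatrix, min_call_rate: float = 0.90) -> GenotypeMatrix:
    """Drop samples whose genotype call rate falls below the threshold."""
    obs = g.calls != MISSING
    rate = obs.mean(axis=1) if g.n_markers else np.ones(g.n_samples)
    keep = np.flatnonzero(rate >= min_call_rate)
    if keep.size == 0:
        warnings.warn("all samples removed by QC filter", stacklevel=2)
    return g.subset_samples(keep)


def drop_non_autosomes(g: GenotypeMatrix,
                       non_autosomal=("X", "Y", "MT", "M")) -> GenotypeMatrix:
    """Remove markers on sex chromosomes / mitochondria; logs the count."""
    chrom = g.markers.table["chrom"].astype(str).str.upper()
    keep = ~chrom.isin(non_autosomal)
    n_drop = int((~keep).sum())
    if n_drop:
        import logging
        logging.getLogger(__name__).info("dropped %d non-autosomal markers", n_drop)
    return g.subset_markers(np.flatnonzero(keep.to_numpy()))
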