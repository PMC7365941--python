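"""End-to-end orchestration: QC → ROH → F_ROH → islands → painting + Fst →
drift envelope → enrichment labels, with TSV reports.

The report table mirrors the usual published layout for composite-breed
selection signatures: one row per ROH island with its coordinates (Mb),
SNP count, founder-A ancestry percentage from painting, Fst of the
composite against each founder in the region, and the drift-null
enrichment label for founder-B ancestry.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import drift_null, genotype_io, islands, painting, pedigree, roh
from .genotype_io import GenotypeMatrix, HaplotypeSet
from .synthetic_data import (COMPOSITE, FOUNDER_A, FOUNDER_B, SimConfig,
                             recommended_copying_params, simulate_composite,
                             write_dataset)

log = logging.getLogger("rohpaint")


@dataclass
class RunConfig:
    """Parameters of a full run; file paths may be omitted when the run
    starts from a simulation."""

    outdir: str = "rohpaint_out"
    seed: int = 0
    # input paths (ignored when simulate is set)
    plink_prefix: str | None = None
    phased_vcf: str | None = None
    genetic_map: str | None = None
    pedigree_file: str | None = None
    simulate: SimConfig | None = None
    # population labels
    composite: str = COMPOSITE
    founder_a: str = FOUNDER_A
    founder_b: str = FOUNDER_B
    # stage parameters
    marker_call_rate: float = 0.95
    min_maf: float = 0.01
    sample_call_rate: float = 0.90
    roh_params: roh.ROHParameters = field(default_factory=roh.ROHParameters)
    class_bounds: roh.GenerationClassBounds = field(
        default_factory=roh.GenerationClassBounds)
    l_total: int | None = None          # None: summed chromosome spans
    merge_gap: int = 500_000
    # None: generator-matched parameters for simulated runs, plain defaults
    # for real inputs
    paint_params: painting.CopyingModelParams | None = None
    drift: drift_null.DriftConfig = field(default_factory=drift_null.DriftConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            kwargs["simulate"] = SimConfig(**kwargs["simulate"])
        if "roh_params" in kwargs:
            kwargs["roh_params"] = roh.ROHParameters(**kwargs["roh_params"])
        if "class_bounds" in kwargs:
            kwargs["class_bounds"] = roh.GenerationClassBounds(
                **kwargs["class_bounds"])
        if "paint_params" in kwargs:
            kwargs["paint_params"] = painting.CopyingModelParams(
                **kwargs["paint_params"])
        if "drift" in kwargs:
            kwargs["drift"] = drift_null.DriftConfig(**kwargs["drift"])
        return cls(**kwargs)

    def validate_inputs(self) -> None:
        if self.simulate is not None:
            return
        for name in ("plink_prefix", "phased_vcf", "genetic_map"):
            if getattr(self, name) is None:
                raise ValueError(f"config missing required input {name!r}")
        for path in (f"{self.plink_prefix}.bed", f"{self.plink_prefix}.ped"):
            if os.path.exists(path):
                break
        else:
            raise FileNotFoundError(f"no PLINK files at {self.plink_prefix}")
        for path in (self.phased_vcf, self.genetic_map):
            if not os.path.exists(path):
                raise FileNotFoundError(path)
        if self.pedigree_file and not os.path.exists(self.pedigree_file):
            raise FileNotFoundError(self.pedigree_file)


def _chrom_lengths(markers) -> dict:
    """Per-chromosome span (bp of last marker) used as the F_ROH denominator
    when no assembly length is supplied."""
    tab = markers.table
    return {str(c): int(tab.loc[tab["chrom"] == c, "pos"].max())
            for c in markers.chroms}


@dataclass
class RunResult:
    config: RunConfig
    genotypes: GenotypeMatrix
    segments: list
    froh: pd.DataFrame
    snp_freq: dict           # population -> per-SNP ROH frequency
    thresholds: dict         # population -> island threshold
    island_regions: dict     # population -> IslandRegion list
    report: pd.DataFrame
    envelope: drift_null.DriftEnvelope
    pedigree_report: pd.DataFrame | None


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage and write the report bundle under
    ``config.outdir``. Deterministic given the seed."""
    config.validate_inputs()
    os.makedirs(config.outdir, exist_ok=True)

    # ---- inputs ---------------------------------------------------------
    if config.simulate is not None:
        sim_cfg = replace(config.simulate, seed=config.simulate.seed or config.seed)
        log.info("simulating composite dataset (seed %d)", sim_cfg.seed)
        sim = simulate_composite(sim_cfg)
        write_dataset(sim, os.path.join(config.outdir, "simulated"))
        geno, haps, ped_tab = sim.genotypes, sim.haplotypes, sim.pedigree
    else:
        geno = genotype_io.read_plink(config.plink_prefix)
        haps = genotype_io.read_phased_vcf(config.phased_vcf)
        haps = HaplotypeSet(
            haps.sample_ids, haps.haplotypes,
            genotype_io.attach_genetic_map(haps.markers, config.genetic_map),
            populations=np.array(
                [geno.populations[geno.sample_ids.index(s)]
                 for s in haps.sample_ids], dtype=object))
        geno.markers = genotype_io.attach_genetic_map(geno.markers,
                                                      config.genetic_map)
        ped_tab = (pd.read_csv(config.pedigree_file, sep="\t", dtype=str)
                   if config.pedigree_file else None)

    # ---- QC -------------------------------------------------------------
    n0 = geno.n_markers
    geno = genotype_io.drop_non_autosomes(geno)
    geno = genotype_io.filter_markers(geno, config.marker_call_rate,
                                      config.min_maf)
    log.info("QC markers: %d -> %d", n0, geno.n_markers)
    s0 = geno.n_samples
    geno = genotype_io.filter_samples(geno, config.sample_call_rate)
    log.info("QC samples: %d -> %d", s0, geno.n_samples)

    # ---- ROH and F_ROH --------------------------------------------------
    segments = roh.detect_roh(geno, config.roh_params, config.class_bounds)
    chrom_lengths = _chrom_lengths(geno.markers)
    l_total = config.l_total or sum(chrom_lengths.values())
    froh = roh.f_roh(segments, geno.sample_ids, "genome", l_total=l_total)
    froh = froh.merge(
        pd.DataFrame({"sample": geno.sample_ids,
                      "population": geno.populations}), on="sample")

    # ---- islands per population ----------------------------------------
    pops = [p for p in (config.composite, config.founder_a, config.founder_b)
            if (geno.populations == p).any()]
    snp_freq, thresholds, island_regions = {}, {}, {}
    for pop in pops:
        freq = roh.snp_roh_frequency(segments, geno, pop)
        thr = islands.island_threshold(freq)
        snp_freq[pop] = freq
        thresholds[pop] = thr
        # a population without any ROH has no islands (threshold 0 would
        # otherwise select the whole genome)
        island_regions[pop] = ([] if thr == 0 else islands.extract_islands(
            freq, thr, geno.markers, pop, config.merge_gap))
        log.info("island threshold %s: %.4f (%d regions)", pop, thr,
                 len(island_regions[pop]))
    focal_regions = []
    if config.composite in island_regions and len(pops) >= 2:
        focal_regions = islands.cross_population_overlap(
            island_regions, config.composite)

    # ---- painting + Fst on composite islands ----------------------------
    have_founders = ((geno.populations == config.founder_a).any()
                     and (geno.populations == config.founder_b).any())
    paint_params = config.paint_params
    if paint_params is None:
        paint_params = (recommended_copying_params(config.simulate)
                        if config.simulate is not None
                        else painting.CopyingModelParams())
    profiles = []
    if focal_regions and have_founders:
        # align haplotypes to the post-QC marker grid
        keep = haps.markers.table["marker_id"].isin(
            geno.markers.table["marker_id"]).to_numpy()
        haps = HaplotypeSet(haps.sample_ids, haps.haplotypes[:, keep],
                            haps.markers.subset(np.flatnonzero(keep)),
                            populations=haps.populations)
        profiles = painting.paint_population(
            haps, config.composite, [config.founder_a, config.founder_b],
            paint_params)

    # ---- drift envelope -------------------------------------------------
    drift_cfg = replace(config.drift, seed=config.drift.seed or config.seed)
    env = drift_null.build_envelope(
        drift_null.simulate_trajectories(drift_cfg))
    env_b = drift_null.mirror_envelope(env)
    env.table.to_csv(os.path.join(config.outdir, "drift_envelope.tsv"),
                     sep="\t", index=False, float_format="%.6f")

    # ---- report ---------------------------------------------------------
    report = make_report(focal_regions, geno, haps if profiles else None,
                         profiles, env_b, config)
    report.to_csv(os.path.join(config.outdir, "islands_report.tsv"),
                  sep="\t", index=False)
    islands.islands_to_frame(
        [r for pop in pops for r in island_regions[pop]]).to_csv(
        os.path.join(config.outdir, "islands_all_populations.tsv"),
        sep="\t", index=False, float_format="%.4f")
    roh.segments_to_frame(segments).to_csv(
        os.path.join(config.outdir, "roh_segments.tsv"), sep="\t", index=False)
    froh.to_csv(os.path.join(config.outdir, "froh.tsv"), sep="\t",
                index=False, float_format="%.6f")
    freq_tab = geno.markers.table[["chrom", "pos"]].copy()
    for pop in pops:
        freq_tab[f"freq_{pop}"] = snp_freq[pop]
    freq_tab.to_csv(os.path.join(config.outdir, "snp_roh_frequency.tsv"),
                    sep="\t", index=False, float_format="%.6f")

    # ---- pedigree -------------------------------------------------------
    ped_report = None
    if ped_tab is not None:
        ped = pedigree.Pedigree(ped_tab)
        g = pedigree.equivalent_generations(ped)
        f = pedigree.inbreeding(ped)
        pci = pd.Series({i: pedigree.pedigree_completeness(ped, i)
                         for i in ped.ids}, name="pci")
        ped_report = pd.DataFrame({"id": ped.ids,
                                   "equiv_generations": g.values,
                                   "pci": pci.values, "F": f.values})
        merged = froh.merge(ped_report, left_on="sample", right_on="id")
        if len(merged) >= 3 and merged["equiv_generations"].nunique() > 1:
            reg = pedigree.froh_regression(
                merged["f_roh"].to_numpy(),
                merged["equiv_generations"].to_numpy())
            log.info("F_ROH = %.4f + %.4f*generation (Ne = %.2f)",
                     reg.intercept, reg.slope, reg.ne.ne)
            ped_report.attrs["froh_regression"] = reg
        ped_report.to_csv(os.path.join(config.outdir, "pedigree_report.tsv"),
                          sep="\t", index=False, float_format="%.6f")

    return RunResult(config, geno, segments, froh, snp_freq, thresholds,
                     island_regions, report, env, ped_report)


def make_report(regions: list, geno: GenotypeMatrix,
                haps: HaplotypeSet | None, profiles: list,
                envelope_b: drift_null.DriftEnvelope,
                config: RunConfig) -> pd.DataFrame:
    """One row per composite island: coordinates (Mb, length = end − start),
    SNP count, founder-A % from painting, Fst vs each founder, and the
    drift-null label of the region-mean founder-B ancestry."""
    rows = []
    for reg in regions:
        row = {"chrom": reg.chrom,
               "start_mb": round(reg.start / 1e6, 2),
               "end_mb": round(reg.end / 1e6, 2),
               "length_mb": round((reg.end - reg.start) / 1e6, 2),
               "n_snps": reg.n_snps,
               "founder_a_pct": np.nan, "fst_vs_a": np.nan,
               "fst_vs_b": np.nan, "enrichment": "",
               "founder_overlap": ",".join(sorted(reg.founder_overlap))}
        where = (reg.chrom, reg.start, reg.end)
        if profiles and haps is not None:
            try:
                _snp, mean = painting.average_ancestry(profiles, haps.markers,
                                                       where)
                row["founder_a_pct"] = round(100 * mean[config.founder_a], 1)
                label = drift_null.classify_enrichment(
                    np.array([mean[config.founder_b]]), envelope_b)[0]
                row["enrichment"] = label
            except ValueError:
                pass
        for founder, col in ((config.founder_a, "fst_vs_a"),
                             (config.founder_b, "fst_vs_b")):
            try:
                row[col] = round(painting.weir_cockerham_fst(
                    geno, (founder, config.composite), where).estimate, 3)
            except ValueError:
                pass
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start_mb", "end_mb",
                                       "length_mb", "n_snps",
                                       "founder_a_pct", "fst_vs_a",
                                       "fst_vs_b", "enrichment",
                                       "founder_overlap"])
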