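import numpy as np
import pandas as pd
import pytest

from rohpaint.genotype_io import GenotypeMatrix, MarkerMap
from rohpaint.synthetic_data import SimConfig, simulate_composite


def toy_marker_map(pos, chrom="1", cm_per_mb=1.282):
    pos = np.asarray(pos)
    tab = pd.DataFrame({
        "chrom": str(chrom), "marker_id": [f"m{i}" for i in range(len(pos))],
        "pos": pos, "cm": pos * cm_per_mb / 1e6, "a1": "A", "a2": "B"})
    return MarkerMap(tab[["chrom", "marker_id", "pos", "cm", "a1", "a2"]])


def toy_genotypes(calls, pos, pops=None, chrom="1"):
    calls = np.atleast_2d(np.asarray(calls, dtype=np.int8))
    n = calls.shape[0]
    pops = pops if pops is not None else ["composite"] * n
    return GenotypeMatrix([f"s{i}" for i in range(n)],
                          np.array(pops, dtype=object), calls,
                          toy_marker_map(pos, chrom))


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured composite simulation shared across tests."""
    cfg = SimConfig(n_chromosomes=2, n_markers_per_chrom=1000,
                    chrom_length=40_000_000, n_founders_a=20, n_founders_b=20,
                    n_composite=30, seed=11)
    return simulate_composite(cfg)
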