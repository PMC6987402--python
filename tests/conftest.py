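import numpy as np
import pytest

import sweepscan as ss


def make_gm(geno, chrom=None, pos=None, samples=None):
    """Small GenotypeMatrix from a plain nested list / array of dosages."""
    geno = np.asarray(geno, dtype=np.int8)
    n_var, n_samp = geno.shape
    chrom = chrom if chrom is not None else ["chr1"] * n_var
    pos = pos if pos is not None else list(range(1, n_var + 1))
    samples = samples if samples is not None else [f"s{i + 1}" for i in range(n_samp)]
    gm = ss.GenotypeMatrix(
        np.array(chrom, dtype=object), np.array(pos, dtype=np.int64),
        np.array(["A"] * n_var, dtype=object), np.array(["G"] * n_var, dtype=object),
        geno, samples,
    )
    gm.validate()
    return gm


def single_pop_map(gm, name="P"):
    return ss.PopulationMap({s: name for s in gm.samples})


@pytest.fixture(scope="session")
def sweep_sim():
    """The default synthetic genome: 10 populations, 3 x 10 Mb, five 200-kb
    sweeps injected into DPL; shared across tests (read-only)."""
    gm, pm, ct, truth = ss.simulate(ss.default_config(seed=20260924))
    pm.pools["DLY"] = {"DD", "LL", "YY"}
    return gm, pm, ct, truth


@pytest.fixture(scope="session")
def two_pop_sim():
    """Two populations at F = 0.3, no LD structure, for separation checks."""
    cfg = ss.SimConfig(
        pop_names=["A", "B"], samples_per_pop=15, pop_F=0.3,
        chrom_lengths={"chr1": 3_000_000}, snp_density=1e-3,
        founder_haplotypes=None, missing_rate=0.05, seed=11,
    )
    return ss.simulate(cfg)
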