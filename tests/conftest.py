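import numpy as np
import pandas as pd
import pytest

from hapweave.containers import GenotypeMatrix, PhasedHaplotypes


def make_gm(calls, chrom=None, pos=None, panel=None):
    """Small GenotypeMatrix from a sites x accessions list of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_acc = calls.shape
    chrom = chrom if chrom is not None else ["chr1"] * n_sites
    pos = pos if pos is not None else np.arange(1, n_sites + 1) * 100
    ref = ["A"] * n_sites
    alt = ["G"] * n_sites
    acc = [f"acc{i}" for i in range(n_acc)]
    return GenotypeMatrix(chrom, pos, ref, alt, calls, acc, panel or {})


def make_haps(haps, chrom=None, pos=None, panel=None, acc=None):
    """PhasedHaplotypes from a sites x (2*n_acc) allele array."""
    haps = np.asarray(haps, dtype=np.int8)
    n_sites, n2 = haps.shape
    chrom = chrom if chrom is not None else ["chr1"] * n_sites
    pos = pos if pos is not None else np.arange(1, n_sites + 1) * 100
    acc = acc or [f"acc{i}" for i in range(n2 // 2)]
    return PhasedHaplotypes(chrom, pos, ["A"] * n_sites, ["G"] * n_sites,
                            haps, acc, panel or {})


@pytest.fixture
def toy_gm():
    return make_gm(
        [
            [0, 0, 1, 1, 2, 2],
            [0, 0, 0, 0, 0, 2],
            [1, 1, 1, 1, 1, 1],
            [0, -9, 2, 2, -9, 0],
        ]
    )


@pytest.fixture(scope="session")
def small_panel():
    """A deterministic 3-group panel shared by read-only tests."""
    from hapweave.simulate import SimConfig, sim_group_panel

    cfg = SimConfig(n_chrom=1, chrom_len_bp=2_000_000, n_sites=300,
                    n_groups=3, group_sizes=(10, 10, 10), group_fst=0.3, seed=11)
    return sim_group_panel(cfg)
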