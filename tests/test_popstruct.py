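"""Geo-genetic filtering, IBS distance, diversity and 4DTv extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

from hapweave.containers import MISSING
from hapweave.popstruct import (
    extract_4dtv_sites,
    filter_snps_by_geo_correlation,
    geographic_distance,
    pairwise_ibs_distance,
    window_diversity,
    window_genetic_distance,
    window_geo_correlation,
)
from .conftest import make_gm


def test_p_distance_worked_example():
    gm = make_gm(np.array([[0, 2, 0], [1, 1, 0]]).T.reshape(3, 2))
    # accessions with codes (0,1), (2,1), (0,0) over two sites
    gm = make_gm(np.array([[0, 2, 0], [1, 1, 0]]))
    d = window_genetic_distance(gm, {"chr1": 1000}, 1000)
    vec = list(d.values())[0]
    # pairs (a0,a1): (|0-2|/2 + |1-1|/2)/2 = 0.5 ; (a0,a2): (0+0.5)/2=0.25 ...
    assert vec[0] == pytest.approx((1.0 + 0.0) / 2)
    assert vec[1] == pytest.approx((0.0 + 0.5) / 2)
    assert vec[2] == pytest.approx((1.0 + 0.5) / 2)


def test_p_distance_limits():
    ident = make_gm(np.array([[0, 0], [2, 2], [1, 1]]))
    d = list(window_genetic_distance(ident, {"chr1": 1000}, 1000).values())[0]
    assert d[0] == 0.0
    opposite = make_gm(np.array([[0, 2], [2, 0]]))
    d = list(window_genetic_distance(opposite, {"chr1": 1000}, 1000).values())[0]
    assert d[0] == 1.0


def test_haversine_values():
    meta = pd.DataFrame({"latitude": [0.0, 0.0, 52.628], "longitude": [0.0, 180.0, 1.171]})
    d = squareform(geographic_distance(meta))
    assert d[0, 0] == 0.0
    assert d[0, 1] == pytest.approx(np.pi * 6371.0088, rel=1e-6)  # half circumference
    assert np.allclose(d, d.T)
    with pytest.raises(ValueError):
        geographic_distance(pd.DataFrame({"latitude": [95.0], "longitude": [0.0]}))


def test_correlation_limits():
    geo = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    r = window_geo_correlation({"w": geo * 0.01}, geo)
    assert r["w"] == pytest.approx(1.0)
    r = window_geo_correlation({"w": np.full(6, 0.3)}, geo)
    assert np.isnan(r["w"])  # zero variance flagged undefined


def test_correlation_permutation_near_zero():
    rng = np.random.default_rng(5)
    geo = rng.uniform(0, 1000, 300)
    gen = rng.permutation(geo) * 1e-3
    r = window_geo_correlation({"w": gen}, geo)
    assert abs(r["w"]) < 0.15


def test_filter_threshold_strict_and_monotone():
    gm = make_gm(np.zeros((4, 3)), pos=[100, 200, 1_000_100, 1_000_200])
    corr = pd.Series({"chr1:0-1000000": 0.06, "chr1:1000000-2000000": 0.07})
    keep = filter_snps_by_geo_correlation(gm, corr, {"chr1": 2_000_000}, 1_000_000)
    assert keep.tolist() == [False, False, True, True]
    for lo, hi in [(0.0, 0.07), (0.07, 0.5)]:
        k_lo = filter_snps_by_geo_correlation(gm, corr, {"chr1": 2_000_000}, 1_000_000, lo)
        k_hi = filter_snps_by_geo_correlation(gm, corr, {"chr1": 2_000_000}, 1_000_000, hi)
        assert (k_hi <= k_lo).all()  # higher threshold never keeps more


def test_introgression_windows_filtered_background_retained():
    """Windows with geography-decoupled genotypes fall below the 0.07 cut."""
    from hapweave.simulate import SimConfig, sim_group_panel

    cfg = SimConfig(n_chrom=1, chrom_len_bp=10_000_000, n_sites=400,
                    n_groups=4, group_sizes=(12, 12, 12, 12), group_fst=0.25,
                    introgression_fraction=0.2, introgression_window_bp=1_000_000,
                    seed=17)
    panel = sim_group_panel(cfg)
    gm = panel.genotypes
    wd = window_genetic_distance(gm, {"chr1": cfg.chrom_len_bp}, 1_000_000)
    geo = geographic_distance(panel.metadata)
    corr = window_geo_correlation(wd, geo)
    intro = set(panel.introgression_windows["window"])
    r_intro = corr[corr.index.isin(intro)]
    r_back = corr[~corr.index.isin(intro)]
    assert (r_intro < 0.07).mean() >= 0.9
    assert (r_back >= 0.07).mean() >= 0.9


def test_ibs_distance_examples_and_bounds():
    gm = make_gm(np.array([[0, 1], [0, 0]]))
    d = pairwise_ibs_distance(gm)
    # site0 shares 1 of 2 alleles, site1 shares 2 of 2 -> 1 - 3/4
    assert d[0] == pytest.approx(0.25)
    single = make_gm(np.array([[0, 1]]))
    assert pairwise_ibs_distance(single)[0] == pytest.approx(0.5)
    rng = np.random.default_rng(3)
    gm = make_gm(rng.choice([0, 1, 2, MISSING], size=(50, 8)))
    d = pairwise_ibs_distance(gm)
    assert np.nanmin(d) >= 0 and np.nanmax(d) <= 1


def test_diversity_worked_example_and_invariance():
    gm = make_gm(np.array([[0, 2]]), pos=[500])
    df = window_diversity(gm, {"chr1": 1000}, 1000)
    # single site p=0.5, n=2 accessions (4 alleles): 2*0.25*(4/3)/1000
    assert df["pi"].iloc[0] == pytest.approx(2 * 0.25 * (4 / 3) / 1000)
    assert df["n_snp"].iloc[0] == 1
    swapped = make_gm(np.array([[2, 0]]), pos=[500])
    df2 = window_diversity(swapped, {"chr1": 1000}, 1000)
    assert df2["pi"].iloc[0] == pytest.approx(df["pi"].iloc[0])


def test_diversity_monomorphic_zero():
    gm = make_gm(np.zeros((5, 6)), pos=[10, 20, 30, 40, 50])
    df = window_diversity(gm, {"chr1": 1000}, 1000)
    assert df["pi"].iloc[0] == 0.0 and df["n_snp"].iloc[0] == 0


def test_diversity_equals_mean_pairwise_differences():
    """pi equals the average per-bp pairwise difference (brute force, n<=6)."""
    rng = np.random.default_rng(11)
    calls = rng.choice([0, 2], size=(30, 6))  # phased-equivalent homozygous panel
    gm = make_gm(calls, pos=np.sort(rng.choice(np.arange(1, 1000), 30, replace=False)))
    df = window_diversity(gm, {"chr1": 1000}, 1000)
    # brute force over haplotypes (each accession contributes 2 identical)
    haps = np.repeat(calls // 2, 2, axis=1)
    n = haps.shape[1]
    tot = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            tot += (haps[:, a] != haps[:, b]).sum()
    brute = tot / (n * (n - 1) / 2) / 1000
    assert df["pi"].iloc[0] == pytest.approx(brute)


# --- 4DTv ------------------------------------------------------------------


def test_4dtv_codon_examples():
    #         0123456789
    ref = {"c": "GGAAAATTTGGG"}  # codons GGA AAA TTT GGG on + strand
    cds = pd.DataFrame({"gene": ["g"], "chrom": ["c"], "start": [0], "end": [12],
                        "strand": ["+"]})
    sites = extract_4dtv_sites(ref, cds)
    pos = set(sites["pos"])
    assert 3 in pos       # GGA third base (glycine GGN), 1-based pos 3
    assert 6 not in pos   # AAA is not fourfold degenerate
    assert 12 in pos      # GGG


def test_4dtv_minus_strand_maps_to_forward_coordinates():
    # forward 'TCC' at 0..3 is 'GGA' on the minus strand; codon third base on
    # the minus strand is forward position 1 (1-based)
    ref = {"c": "TCCTTT"}
    cds = pd.DataFrame({"gene": ["g"], "chrom": ["c"], "start": [0], "end": [6],
                        "strand": ["-"]})
    sites = extract_4dtv_sites(ref, cds)
    # minus strand sequence: AAAGGA -> codons AAA, GGA; GGA third base is
    # minus-strand index 5 == forward index 0 -> 1-based pos 1
    assert set(sites["pos"]) == {1}


def test_4dtv_skips_partial_codons():
    ref = {"c": "GGAAA"}
    cds = pd.DataFrame({"gene": ["g"], "chrom": ["c"], "start": [0], "end": [5],
                        "strand": ["+"]})
    sites = extract_4dtv_sites(ref, cds)
    assert len(sites) == 0


def test_4dtv_matches_exhaustive_scan():
    """Strand-aware extraction equals a direct per-codon table scan."""
    from Bio.Data.CodonTable import standard_dna_table

    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list("ACGT"), 300))
    ref = {"c": seq}
    cds = pd.DataFrame({
        "gene": ["p", "m"], "chrom": ["c", "c"], "start": [0, 150],
        "end": [99, 249], "strand": ["+", "-"],
    })
    got = set(extract_4dtv_sites(ref, cds)["pos"])
    fwd = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        fwd[stop] = "*"

    def four_fold(codon):
        return len({fwd[codon[:2] + b] for b in "ACGT"}) == 1

    expect = set()
    for i in range(0, 99, 3):
        if four_fold(seq[i : i + 3]):
            expect.add(i + 3)
    rc = seq[150:249].translate(str.maketrans("ACGT", "TGCA"))[::-1]
    for i in range(0, 99, 3):
        if four_fold(rc[i : i + 3]):
            expect.add(150 + (99 - 1 - (i + 2)) + 1)  # map back to forward, 1-based
    assert got == expect
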