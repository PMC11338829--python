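"""k-mer sets, window variation scores, clustering, tiling paths, cover."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hapweave.containers import tile_windows
from hapweave.ibs import (
    KmerSet,
    assign_window_haplotypes,
    build_kmer_set,
    donor_contributions,
    genotype_window_variations,
    index_reference,
    kmer_genotype,
    kmer_window_matrix,
    min_donor_cover,
    reconstruct_mosaic,
    window_variations,
)

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(RC)[::-1]


def test_single_kmer_sequence():
    ks = build_kmer_set({"c": "A" * 31}, k=31)
    assert len(ks) == 1


def test_canonicalization_reverse_complement_invariant():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), 200))
    a = build_kmer_set({"c": seq})
    b = build_kmer_set({"c": revcomp(seq)})
    assert np.array_equal(a.codes, b.codes)


def test_kmer_count_on_unique_sequence():
    rng = np.random.default_rng(2)
    L = 5000
    seq = "".join(rng.choice(list("ACGT"), L))
    ks = build_kmer_set({"c": seq}, k=31)
    # random 5-kb sequence: k-mers virtually all unique
    assert len(ks) == L - 31 + 1


def test_ambiguous_bases_skip_covering_kmers():
    seq = "A" * 40 + "N" + "C" * 40
    ks = build_kmer_set({"c": seq}, k=31)
    direct = set()
    for i in range(len(seq) - 30):
        kmer = seq[i : i + 31]
        if "N" not in kmer:
            direct.add(min(kmer, revcomp(kmer)))
    assert len(ks) == len(direct)


def test_even_k_rejected_and_empty_fasta_rejected():
    with pytest.raises(ValueError):
        build_kmer_set({"c": "ACGT" * 20}, k=30)
    with pytest.raises(ValueError):
        build_kmer_set({}, k=31)


def _random_ref(L=4000, seed=3):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(rng.choice(list("ACGT"), L))}


def test_window_variations_self_is_zero():
    ref = _random_ref()
    rk = index_reference(ref)
    wt = tile_windows({"chr1": 4000}, 1000)
    v = window_variations(rk, wt, build_kmer_set(ref, "self"))
    assert (v == 0).all()


def test_window_variations_substitutions():
    ref = _random_ref(seed=4)
    s = list(ref["chr1"])
    # one substitution mid-window 0; two substitutions >= k apart in window 2
    s[500] = "A" if s[500] != "A" else "C"
    s[2100] = "A" if s[2100] != "A" else "C"
    s[2600] = "A" if s[2600] != "A" else "C"
    query = build_kmer_set({"chr1": "".join(s)}, "q")
    rk = index_reference(ref)
    wt = tile_windows({"chr1": 4000}, 1000)
    v = window_variations(rk, wt, query)
    assert v.iloc[0] == 1
    assert v.iloc[1] == 0
    assert v.iloc[2] == 2


def test_window_shorter_than_k_flagged():
    ref = {"chr1": "ACGTACGTACGTACGTACGT"}  # 20 bp < k
    rk = index_reference(ref)
    wt = tile_windows({"chr1": 20}, 20)
    v = window_variations(rk, wt, build_kmer_set(_random_ref(), "q"))
    assert np.isnan(v.iloc[0])


def _label_matrix(rows, accs):
    """WindowHaplotypes-like fixture from a windows x accession label array."""
    from hapweave.ibs import WindowHaplotypes

    n = len(rows)
    wdf = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * 10,
        "end": np.arange(1, n + 1) * 10,
        "window": [f"w{i}" for i in range(n)],
    })
    ldf = pd.DataFrame(rows, index=wdf["window"], columns=accs)
    return WindowHaplotypes(wdf, ldf)


def test_cluster_identical_groups():
    from hapweave.ibs import KmerWindowMatrix

    wt = tile_windows({"chr1": 1_000_000}, 50_000)
    vals = pd.DataFrame(
        np.array([[0.0] * 20, [0.0] * 20, [5.0] * 20, [5.0] * 20]).T,
        index=wt.table["window"], columns=["a", "b", "c", "d"],
    )
    wh = assign_window_haplotypes(KmerWindowMatrix(wt.table, vals))
    lab = wh.labels.iloc[0]
    assert lab["a"] == lab["b"]
    assert lab["c"] == lab["d"]
    assert lab["a"] != lab["c"]


def test_cluster_all_identical_single_cluster():
    from hapweave.ibs import KmerWindowMatrix

    wt = tile_windows({"chr1": 1_000_000}, 50_000)
    vals = pd.DataFrame(np.ones((20, 5)) * 3.0, index=wt.table["window"],
                        columns=list("abcde"))
    wh = assign_window_haplotypes(KmerWindowMatrix(wt.table, vals))
    assert wh.labels.iloc[0].nunique() == 1


def test_reconstruct_exact_copy_single_segment():
    rows = [[0, 0, 1]] * 10  # query == donor A everywhere, donor B differs
    wh = _label_matrix(rows, ["query", "A", "B"])
    path = reconstruct_mosaic(wh, "query", ["A", "B"])
    assert len(path.segments) == 1
    assert path.segments.iloc[0]["donor"] == "A"
    assert path.segments.iloc[0]["n_windows"] == 10


def test_reconstruct_two_donor_concatenation():
    rows = [[0, 0, 1]] * 5 + [[2, 0, 2]] * 5
    wh = _label_matrix(rows, ["query", "A", "B"])
    path = reconstruct_mosaic(wh, "query", ["A", "B"])
    assert path.segments["donor"].tolist() == ["A", "B"]
    assert path.segments["n_windows"].tolist() == [5, 5]


def test_reconstruct_gap_when_nothing_matches():
    rows = [[0, 1, 2]] * 4
    wh = _label_matrix(rows, ["query", "A", "B"])
    path = reconstruct_mosaic(wh, "query", ["A", "B"])
    assert path.segments["donor"].tolist() == ["none"]


def test_reconstruct_longest_run_wins_with_tie_break():
    # at window 0 both donors match; A's run is longer
    rows = [[0, 0, 0], [0, 0, 1], [0, 0, 1]]
    wh = _label_matrix(rows, ["query", "A", "B"])
    path = reconstruct_mosaic(wh, "query", ["A", "B"])
    assert path.segments.iloc[0]["donor"] == "A"
    # exact tie everywhere: lexicographically smaller id wins
    rows = [[0, 0, 0]] * 3
    wh = _label_matrix(rows, ["query", "B", "A"])
    path = reconstruct_mosaic(wh, "query", ["B", "A"])
    assert path.segments.iloc[0]["donor"] == "A"


def test_donor_contributions_partition():
    rows = [[0, 0, 1]] * 3 + [[2, 0, 2]] * 2 + [[5, 1, 2]] * 1
    wh = _label_matrix(rows, ["query", "A", "B"])
    path = reconstruct_mosaic(wh, "query", ["A", "B"])
    contrib = donor_contributions(path)
    gap = path.segments[path.segments["donor"] == "none"]["n_windows"].sum()
    assert sum(contrib.values()) + gap / path.n_windows == pytest.approx(1.0)
    assert contrib["A"] == pytest.approx(3 / 6)
    assert contrib["B"] == pytest.approx(2 / 6)


def _exhaustive_cover(paths, target):
    donors = set()
    cells = {}
    universe = 0
    for qi, p in enumerate(paths):
        universe += p.n_windows
        for row in p.segments.itertuples(index=False):
            if row.donor == "none":
                continue
            donors.add(row.donor)
            cells.setdefault(row.donor, set()).update(
                (qi, row.chrom, w) for w in range(row.first_window, row.last_window + 1)
            )
    donors = sorted(donors)
    for size in range(0, len(donors) + 1):
        for comb in itertools.combinations(donors, size):
            got = set().union(*(cells[d] for d in comb)) if comb else set()
            if len(got) / universe >= target:
                return size
    return None


def test_greedy_cover_matches_exhaustive_optimum():
    rng = np.random.default_rng(7)
    for trial in range(10):
        n_donors = int(rng.integers(3, 9))
        donors = [f"d{i}" for i in range(n_donors)]
        paths = []
        for q in range(3):
            n = 12
            lab = rng.integers(0, n_donors, n)
            rows = []
            w = 0
            while w < n:
                run = 1
                while w + run < n and lab[w + run] == lab[w]:
                    run += 1
                rows.append(("chr1", w, w + run - 1, run, donors[lab[w]]))
                w += run
            from hapweave.ibs import TilingPath

            paths.append(TilingPath(f"q{q}", pd.DataFrame(
                rows, columns=["chrom", "first_window", "last_window", "n_windows", "donor"]
            ), n))
        chosen, frac, reached = min_donor_cover(paths, coverage_target=0.6)
        assert reached and frac >= 0.6
        gains = [g for _, g in chosen]
        assert all(a >= b for a, b in zip(gains, gains[1:]))  # non-increasing
        opt = _exhaustive_cover(paths, 0.6)
        assert len(chosen) == opt


def test_cover_single_donor_explains_everything():
    from hapweave.ibs import TilingPath

    seg = pd.DataFrame([("chr1", 0, 9, 10, "d0")],
                       columns=["chrom", "first_window", "last_window", "n_windows", "donor"])
    paths = [TilingPath("q0", seg, 10), TilingPath("q1", seg, 10)]
    chosen, frac, reached = min_donor_cover(paths, coverage_target=1.0)
    assert [d for d, _ in chosen] == ["d0"] and reached


def test_kmer_genotyping_calls():
    acc = KmerSet("a", np.array([5, 10, 20], dtype=np.int64))
    markers = {
        "m1": (np.array([5]), np.array([6])),     # allele1 present
        "m2": (np.array([10]), np.array([20])),   # both -> het
        "m3": (np.array([7]), np.array([8])),     # neither -> missing
        "m4": (np.array([5, 9]), np.array([9])),  # overlapping sets
    }
    calls = kmer_genotype(markers, acc)
    assert calls == {"m1": "allele1", "m2": "het", "m3": "missing", "m4": "unusable"}


def test_kmer_genotyping_reproduces_simulated_alleles():
    """Allele-specific 31-mers from flanks call simulated sequences exactly."""
    from hapweave.simulate import SimConfig, sim_group_panel, sim_sequences

    cfg = SimConfig(n_chrom=1, chrom_len_bp=60_000, n_sites=20, n_groups=2,
                    group_sizes=(3, 3), seed=13)
    panel = sim_group_panel(cfg)
    ref, accs, haps = sim_sequences(panel.haps, cfg.chrom_len_bp, seed=14)
    markers = {}
    for s in range(haps.n_sites):
        p = int(haps.pos[s]) - 1
        flank = ref["chr1"][p - 15 : p + 16]
        a1 = flank[:15] + haps.ref[s] + flank[16:]
        a2 = flank[:15] + haps.alt[s] + flank[16:]
        markers[f"s{s}"] = (
            build_kmer_set({"m": a1}).codes,
            build_kmer_set({"m": a2}).codes,
        )
    for i, acc in enumerate(haps.accession_ids[:3]):
        ks = build_kmer_set(accs[acc], acc)
        calls = kmer_genotype(markers, ks)
        for s in range(haps.n_sites):
            allele = haps.haps[s, 2 * i]  # haploid consensus uses haplotype 0
            want = "allele2" if allele == 1 else "allele1"
            # a ref-allele k-mer may also occur elsewhere in the genome;
            # accept het only if the genotype allele is present
            assert calls[f"s{s}"] in (want, "het")
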