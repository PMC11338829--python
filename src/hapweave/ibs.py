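"""k-mer identity-by-state long-range haplotyping and mosaic reconstruction.

An accession's canonical 31-mer set is compared with a reference genome in
non-overlapping 50-kb windows; reference k-mers absent from the accession
are grouped into maximal runs and the run count is the window's variation
score (zero iff the window is identical by state).  Accessions are then
clustered per 1-Mb window (20 consecutive 50-kb scores) by affinity
propagation; a query genome is reconstructed as a minimum tiling path of
donor segments, each donor chosen as the panel accession with the longest
run of matched haplotype windows (MHW).  A greedy maximum-coverage step
finds the smallest donor subset explaining a target fraction of a set of
query genomes, and allele-specific k-mer genotyping supports concordance
checks against array data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import warnings

import numpy as np
import pandas as pd

from .containers import MISSING, PhasedHaplotypes, WindowTable, tile_windows

logger = logging.getLogger("hapweave.ibs")

__all__ = [
    "KmerSet",
    "build_kmer_set",
    "ReferenceKmers",
    "index_reference",
    "KmerWindowMatrix",
    "window_variations",
    "kmer_window_matrix",
    "genotype_window_variations",
    "WindowHaplotypes",
    "assign_window_haplotypes",
    "TilingPath",
    "reconstruct_mosaic",
    "donor_contributions",
    "min_donor_cover",
    "kmer_genotype",
]

_CODE = np.full(256, -1, dtype=np.int8)
for _b, _v in zip("ACGT", range(4)):
    _CODE[ord(_b)] = _v
    _CODE[ord(_b.lower())] = _v


def _base_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(b: np.ndarray, k: int) -> tuple:
    """(codes, valid) for all k-mer start positions of a base-code array."""
    L = len(b)
    n = L - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    bb = np.where(b < 0, 0, b).astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes += bb[j : j + n] << (2 * (k - 1 - j))
    bad = (b < 0).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


def _canonical_from_seq(seq: str, k: int) -> tuple:
    """Canonical k-mer code per start position plus validity mask."""
    b = _base_codes(seq)
    codes, valid = _kmer_codes(b, k)
    rc_b = (3 - b)[::-1]
    rc_b[b[::-1] < 0] = -1
    rc_codes, _ = _kmer_codes(rc_b, k)
    # rc of the k-mer starting at i is the k-mer starting at L-k-i of the rc strand
    rc_aligned = rc_codes[::-1]
    return np.minimum(codes, rc_aligned), valid


@dataclass
class KmerSet:
    """Canonical k-mer set of one accession (sorted integer codes)."""

    accession_id: str
    codes: np.ndarray
    k: int = 31

    def __contains__(self, code: int) -> bool:
        i = np.searchsorted(self.codes, code)
        return bool(i < len(self.codes) and self.codes[i] == code)

    def contains(self, codes: np.ndarray) -> np.ndarray:
        if len(self.codes) == 0:
            return np.zeros(len(codes), dtype=bool)
        idx = np.searchsorted(self.codes, codes)
        idx = np.clip(idx, 0, len(self.codes) - 1)
        return self.codes[idx] == codes

    def __len__(self) -> int:
        return len(self.codes)


def build_kmer_set(seqs, accession_id: str = "query", k: int = 31) -> KmerSet:
    """Canonical k-mer set from sequences.

    ``seqs`` is a mapping chrom -> sequence string or a FASTA path.  k must
    be odd (a canonical k-mer cannot equal its own reverse complement);
    k-mers covering ambiguous bases are skipped.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if isinstance(seqs, (str,)):
        from Bio import SeqIO

        seqs = {r.id: str(r.seq) for r in SeqIO.parse(seqs, "fasta")}
    if not seqs or all(len(s) < k for s in seqs.values()):
        raise ValueError("no sequence of length >= k")
    all_codes = []
    for s in seqs.values():
        if len(s) < k:
            continue
        codes, valid = _canonical_from_seq(s, k)
        all_codes.append(codes[valid])
    codes = np.unique(np.concatenate(all_codes))
    return KmerSet(accession_id, codes, k)


@dataclass
class ReferenceKmers:
    """Per-chromosome canonical k-mer codes of a reference, by start position."""

    codes: dict          # chrom -> int64 array (per k-mer start)
    valid: dict          # chrom -> bool array
    chrom_lengths: dict
    k: int = 31


def index_reference(ref_seqs: dict, k: int = 31) -> ReferenceKmers:
    codes, valid, lens = {}, {}, {}
    for c, s in ref_seqs.items():
        codes[c], valid[c] = _canonical_from_seq(s, k)
        lens[c] = len(s)
    return ReferenceKmers(codes, valid, lens, k)


@dataclass
class KmerWindowMatrix:
    """Variation counts per (window x accession); NaN where undefined."""

    windows: pd.DataFrame          # chrom, start, end, window
    values: pd.DataFrame           # index = window id, columns = accessions


def window_variations(ref: ReferenceKmers, windows: WindowTable, query: KmerSet) -> pd.Series:
    """Variation count per window for one accession.

    Reference k-mer start positions absent from the query are grouped into
    maximal runs; the count of runs is the score (one substitution knocks
    out a run of <= k consecutive k-mers, hence one variation).  Windows
    shorter than k are undefined (NaN).
    """
    out = {}
    for w in windows:
        codes = ref.codes[w.chrom]
        valid = ref.valid[w.chrom]
        lo, hi = int(w.start), min(int(w.end), ref.chrom_lengths[w.chrom]) - ref.k + 1
        if hi <= lo:
            out[w.window] = np.nan
            continue
        c = codes[lo:hi]
        v = valid[lo:hi]
        absent = np.zeros(len(c), dtype=bool)
        absent[v] = ~query.contains(c[v])
        if not absent.any():
            out[w.window] = 0.0
        else:
            starts = absent & ~np.concatenate([[False], absent[:-1]])
            out[w.window] = float(starts.sum())
    return pd.Series(out, name=query.accession_id)


def kmer_window_matrix(ref: ReferenceKmers, queries: list, window_bp: int = 50_000) -> KmerWindowMatrix:
    """Variation matrix over non-overlapping windows for many accessions."""
    wt = tile_windows(ref.chrom_lengths, window_bp)
    vals = pd.DataFrame({q.accession_id: window_variations(ref, wt, q) for q in queries})
    vals = vals.loc[wt.table["window"]]
    return KmerWindowMatrix(wt.table, vals)


def genotype_window_variations(haps: PhasedHaplotypes, chrom_lengths: dict,
                               window_bp: int = 50_000) -> KmerWindowMatrix:
    """Window variation scores computed from genotypes instead of k-mers.

    The score is the count of non-reference alleles (both haplotypes) in
    the window — zero iff the accession is identical by state with the
    reference there, the same semantics the k-mer route provides.
    """
    wt = tile_windows(chrom_lengths, window_bp)
    alt = (haps.haps == 1).astype(np.int16)
    acc_alt = alt[:, 0::2] + alt[:, 1::2]
    rows = []
    for w in wt.table.itertuples(index=False):
        in_w = (haps.chrom == w.chrom) & (haps.pos - 1 >= w.start) & (haps.pos - 1 < w.end)
        rows.append(acc_alt[in_w].sum(axis=0))
    vals = pd.DataFrame(np.array(rows, dtype=float), index=wt.table["window"],
                        columns=haps.accession_ids)
    return KmerWindowMatrix(wt.table, vals)


@dataclass
class WindowHaplotypes:
    """Per 1-Mb window cluster labels for every accession."""

    windows: pd.DataFrame          # chrom, start, end, window (1-Mb)
    labels: pd.DataFrame           # index = window id, columns = accessions


def _cluster_vectors(X: np.ndarray, seed: int = 0) -> np.ndarray:
    """Cluster rows of X; identical rows always co-cluster.

    Exact-duplicate rows are collapsed first; affinity propagation
    (damping 0.9, preference = median similarity) runs on the unique rows
    when there are at least three; on non-convergence a deterministic
    average-linkage fallback with silhouette-chosen k (1..5) is used.
    """
    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    nu = len(uniq)
    if nu <= 2:
        return inverse
    from sklearn.cluster import AffinityPropagation
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap = AffinityPropagation(damping=0.9, max_iter=200, random_state=seed)
            lab_u = ap.fit_predict(uniq)
            if (lab_u < 0).any():
                raise RuntimeError("affinity propagation produced unassigned points")
        except (ConvergenceWarning, RuntimeError):
            logger.info("affinity propagation did not converge; hierarchical fallback")
            lab_u = _fallback_cluster(uniq)
    return lab_u[inverse]


def _fallback_cluster(uniq: np.ndarray) -> np.ndarray:
    from sklearn.cluster import AgglomerativeClustering
    from sklearn.metrics import silhouette_score

    best_lab, best_score = np.zeros(len(uniq), dtype=int), -np.inf
    for k in range(2, min(5, len(uniq)) + 1):
        lab = AgglomerativeClustering(n_clusters=k).fit_predict(uniq)
        score = silhouette_score(uniq, lab)
        if score > best_score:
            best_lab, best_score = lab, score
    return best_lab


def assign_window_haplotypes(mat: KmerWindowMatrix, sub_per_window: int = 20,
                             seed: int = 0) -> WindowHaplotypes:
    """Cluster accessions per 1-Mb window on their 20-vector of scores.

    Undefined sub-window scores are filled with the accession's window mean
    (all-undefined windows get label -1 for everyone).
    """
    accs = list(mat.values.columns)
    if len(accs) < 2:
        raise ValueError("need >= 2 accessions to cluster")
    rows, labels = [], []
    for chrom, sub in mat.windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        ids = sub["window"].tolist()
        for off in range(0, len(ids), sub_per_window):
            grp = ids[off : off + sub_per_window]
            start = int(sub["start"].iloc[off])
            end = int(sub["end"].iloc[min(off + sub_per_window, len(ids)) - 1])
            X = mat.values.loc[grp, accs].to_numpy().T  # accessions x sub-windows
            if np.isnan(X).all():
                lab = np.full(len(accs), -1)
            else:
                col_mean = np.nanmean(X, axis=0)
                X = np.where(np.isnan(X), col_mean[None, :], X)
                lab = _cluster_vectors(X, seed=seed)
            wid = f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, wid))
            labels.append(lab)
    wdf = pd.DataFrame(rows, columns=["chrom", "start", "end", "window"])
    ldf = pd.DataFrame(np.array(labels), index=wdf["window"], columns=accs)
    return WindowHaplotypes(wdf, ldf)


@dataclass
class TilingPath:
    """Ordered donor segments reconstructing one query genome."""

    query: str
    segments: pd.DataFrame   # chrom, first_window, last_window, n_windows, donor
    n_windows: int           # total genome windows considered


def reconstruct_mosaic(wh: WindowHaplotypes, query: str, donors: list) -> TilingPath:
    """Minimum tiling path of donor segments for a query accession.

    Per chromosome, starting at the first uncovered window: among donors
    sharing the query's cluster label there, each candidate's matched
    haplotype window run (MHW) is extended; the donor with the longest run
    wins (ties to the lexicographically smallest id), its segment is
    recorded, and scanning resumes after the segment — overlapping
    candidate runs are thereby discarded.  Windows where no donor matches
    become gap segments with donor ``none``.
    """
    donors = [d for d in donors if d != query]
    segs = []
    total = 0
    for chrom, sub in wh.windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        ids = sub["window"].tolist()
        qlab = wh.labels.loc[ids, query].to_numpy()
        dlab = wh.labels.loc[ids, donors].to_numpy()
        n = len(ids)
        total += n
        match = (dlab == qlab[:, None]) & (qlab[:, None] >= 0)
        w = 0
        while w < n:
            cand = np.flatnonzero(match[w])
            if len(cand) == 0:
                run_end = w
                while run_end < n and not match[run_end].any():
                    run_end += 1
                segs.append((chrom, w, run_end - 1, run_end - w, "none"))
                w = run_end
                continue
            best_len, best_donor = 0, None
            for ci in cand:
                run = 0
                while w + run < n and match[w + run, ci]:
                    run += 1
                name = donors[ci]
                if run > best_len or (run == best_len and (best_donor is None or name < best_donor)):
                    best_len, best_donor = run, name
            segs.append((chrom, w, w + best_len - 1, best_len, best_donor))
            w += best_len
    df = pd.DataFrame(segs, columns=["chrom", "first_window", "last_window", "n_windows", "donor"])
    return TilingPath(query, df, total)


def donor_contributions(path: TilingPath) -> dict:
    """Fraction of genome windows contributed by each donor (gaps excluded)."""
    out = {}
    for row in path.segments.itertuples(index=False):
        if row.donor == "none":
            continue
        out[row.donor] = out.get(row.donor, 0) + row.n_windows
    return {d: n / path.n_windows for d, n in sorted(out.items())}


def min_donor_cover(paths: list, coverage_target: float = 0.5):
    """Greedy maximum-coverage donor subset across many query genomes.

    Repeatedly adds the donor whose segments cover the most yet-uncovered
    (query, window) cells until the covered fraction of all query windows
    reaches ``coverage_target``.  Returns (ordered [(donor, marginal gain in
    cells)], achieved fraction, reached flag).
    """
    donor_cells: dict = {}
    universe = 0
    for qi, p in enumerate(paths):
        universe += p.n_windows
        for row in p.segments.itertuples(index=False):
            if row.donor == "none":
                continue
            cells = {(qi, row.chrom, w) for w in range(row.first_window, row.last_window + 1)}
            donor_cells.setdefault(row.donor, set()).update(cells)
    covered: set = set()
    chosen = []
    frac = 0.0
    while frac < coverage_target:
        best, gain = None, 0
        for d in sorted(donor_cells):
            g = len(donor_cells[d] - covered)
            if g > gain:
                best, gain = d, g
        if best is None:
            return chosen, frac, False
        covered |= donor_cells[best]
        chosen.append((best, gain))
        frac = len(covered) / universe
    return chosen, frac, True


def kmer_genotype(markers: dict, acc: KmerSet) -> dict:
    """Allele calls from allele-specific k-mer presence.

    ``markers`` maps marker id -> (allele1 codes, allele2 codes) as integer
    arrays.  A marker whose allele sets intersect is flagged ``unusable``;
    otherwise the call is ``allele1``/``allele2``/``het`` (both present) or
    ``missing`` (neither).
    """
    calls = {}
    for m, (a1, a2) in markers.items():
        a1 = np.asarray(a1, dtype=np.int64)
        a2 = np.asarray(a2, dtype=np.int64)
        if len(np.intersect1d(a1, a2)) > 0:
            calls[m] = "unusable"
            continue
        has1 = bool(acc.contains(a1).any())
        has2 = bool(acc.contains(a2).any())
        if has1 and has2:
            calls[m] = "het"
        elif has1:
            calls[m] = "allele1"
        elif has2:
            calls[m] = "allele2"
        else:
            calls[m] = "missing"
    return calls
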