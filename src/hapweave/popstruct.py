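"""Population-structure support computations.

The introgression-aware SNP exclusion pipeline: per 5-Mb window, pairwise
genetic p-distance between accessions is correlated with pairwise
geographic (haversine) distance; windows where r < 0.07 carry genotypes
decoupled from geography (typical of shared introgressions) and their SNPs
are discarded.  Also here: pairwise IBS distance, windowed nucleotide
diversity, and fourfold-degenerate (4DTv) site extraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .containers import MISSING, GenotypeMatrix, tile_windows

__all__ = [
    "window_genetic_distance",
    "geographic_distance",
    "window_geo_correlation",
    "filter_snps_by_geo_correlation",
    "pairwise_ibs_distance",
    "window_diversity",
    "extract_4dtv_sites",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0088


def _p_distance(calls: np.ndarray) -> np.ndarray:
    """Condensed pairwise p-distance over sites (rows) x accessions (cols).

    Per shared non-missing site the contribution is |code_a - code_b| / 2
    (0 identical homozygotes, 0.5 het vs hom, 1 opposite homozygotes); the
    distance is the mean over shared sites, NaN when none are shared.
    """
    n = calls.shape[1]
    out = np.full(n * (n - 1) // 2, np.nan)
    k = 0
    for a in range(n):
        for b in range(a + 1, n):
            ok = (calls[:, a] != MISSING) & (calls[:, b] != MISSING)
            if ok.any():
                out[k] = np.abs(calls[ok, a].astype(float) - calls[ok, b]).mean() / 2.0
            k += 1
    return out


def window_genetic_distance(gm: GenotypeMatrix, chrom_lengths: dict,
                            window_bp: int = 5_000_000) -> dict:
    """Condensed p-distance per genomic window (windows with sites only)."""
    wt = tile_windows(chrom_lengths, window_bp)
    out = {}
    for w in wt.table.itertuples(index=False):
        in_w = (gm.chrom == w.chrom) & (gm.pos - 1 >= w.start) & (gm.pos - 1 < w.end)
        if in_w.any():
            out[w.window] = _p_distance(gm.calls[in_w])
    return out


def geographic_distance(metadata: pd.DataFrame) -> np.ndarray:
    """Condensed haversine distance (km) from decimal latitude/longitude."""
    lat = metadata["latitude"].to_numpy(float)
    lon = metadata["longitude"].to_numpy(float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise ValueError("coordinates outside [-90, 90] x [-180, 180]")
    la = np.radians(lat)
    lo = np.radians(lon)
    dla = la[:, None] - la[None, :]
    dlo = lo[:, None] - lo[None, :]
    h = np.sin(dla / 2) ** 2 + np.cos(la)[:, None] * np.cos(la)[None, :] * np.sin(dlo / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def window_geo_correlation(window_dist: dict, geo: np.ndarray) -> pd.Series:
    """Pearson r between genetic and geographic pair distances per window.

    Pairs with missing genetic distance are dropped; windows with fewer
    than three pairs or zero variance in either vector are NaN (flagged
    undefined).
    """
    out = {}
    for w, gd in window_dist.items():
        ok = ~np.isnan(gd)
        if ok.sum() < 3 or gd[ok].std() == 0 or geo[ok].std() == 0:
            out[w] = np.nan
            continue
        out[w] = float(np.corrcoef(gd[ok], geo[ok])[0, 1])
    return pd.Series(out, name="r")


def filter_snps_by_geo_correlation(gm: GenotypeMatrix, corr: pd.Series,
                                   chrom_lengths: dict, window_bp: int = 5_000_000,
                                   threshold: float = 0.07) -> np.ndarray:
    """Keep mask over sites: drop SNPs in windows with r < threshold (strict)
    or with undefined r.  Sites outside any scored window are kept."""
    wt = tile_windows(chrom_lengths, window_bp)
    keep = np.ones(gm.n_sites, dtype=bool)
    for w in wt.table.itertuples(index=False):
        if w.window not in corr.index:
            continue
        r = corr[w.window]
        if np.isnan(r) or r < threshold:
            in_w = (gm.chrom == w.chrom) & (gm.pos - 1 >= w.start) & (gm.pos - 1 < w.end)
            keep[in_w] = False
    return keep


def pairwise_ibs_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Condensed IBS distance = 1 - shared alleles / (2 x shared sites).

    Allele sharing per site: 2 for identical genotypes, 1 when one allele
    is shared (het vs hom, i.e. |code difference| = 1), 0 for opposite
    homozygotes.
    """
    if gm.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    calls = gm.calls
    n = calls.shape[1]
    out = np.full(n * (n - 1) // 2, np.nan)
    k = 0
    for a in range(n):
        for b in range(a + 1, n):
            ok = (calls[:, a] != MISSING) & (calls[:, b] != MISSING)
            if ok.any():
                diff = np.abs(calls[ok, a].astype(int) - calls[ok, b])
                shared = (2 - diff).sum()
                out[k] = 1.0 - shared / (2.0 * ok.sum())
            k += 1
    return out


def window_diversity(gm: GenotypeMatrix, chrom_lengths: dict,
                     window_bp: int = 2_000_000,
                     accessions: list | None = None) -> pd.DataFrame:
    """Per-window polymorphic-site count and nucleotide diversity pi.

    pi per window = sum over sites of 2 p(1-p) n/(n-1) divided by window
    length in bp (the unbiased per-site estimator, averaged per bp), with
    p and the called count n per site.  Windows with no called site get
    pi = 0 and count 0; sites with n < 2 are skipped.
    """
    if accessions is not None:
        gm = gm.take_accessions(accessions)
    wt = tile_windows(chrom_lengths, window_bp)
    rows = []
    for w in wt.table.itertuples(index=False):
        in_w = (gm.chrom == w.chrom) & (gm.pos - 1 >= w.start) & (gm.pos - 1 < w.end)
        calls = gm.calls[in_w]
        pi_sum = 0.0
        n_snp = 0
        for site in calls:
            ok = site != MISSING
            n = int(ok.sum())
            if n < 2:
                continue
            p = (2.0 * (site[ok] == 2).sum() + (site[ok] == 1).sum()) / (2.0 * n)
            if 0.0 < p < 1.0:
                n_snp += 1
            nn = 2 * n  # allele count
            pi_sum += 2.0 * p * (1.0 - p) * nn / (nn - 1)
        rows.append((w.chrom, w.start, w.end, w.window, n_snp, pi_sum / (w.end - w.start)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "window", "n_snp", "pi"])


_STANDARD = {}


def _fourfold_prefixes():
    """Two-base codon prefixes whose third position is fourfold degenerate."""
    global _STANDARD
    if _STANDARD:
        return _STANDARD
    from Bio.Data.CodonTable import standard_dna_table

    fwd = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        fwd[stop] = "*"
    pre = {}
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = {fwd[b1 + b2 + b3] for b3 in "ACGT"}
            pre[b1 + b2] = len(aas) == 1
    _STANDARD = pre
    return pre


_COMP = str.maketrans("ACGT", "TGCA")


def extract_4dtv_sites(reference: dict, cds_table: pd.DataFrame) -> pd.DataFrame:
    """Fourfold-degenerate codon third positions, strand-aware.

    ``cds_table`` columns: gene, chrom, start, end (0-based half-open),
    strand (+/-); multi-exon genes list one row per exon and are
    concatenated in genomic order (reverse order for minus strand).  CDS
    whose concatenated length is not divisible by 3 are skipped with a
    warning.  Returns forward-strand positions (chrom, pos 1-based).
    """
    import logging

    log = logging.getLogger("hapweave.popstruct")
    pre = _fourfold_prefixes()
    rows = []
    for gene, sub in cds_table.groupby("gene", sort=False):
        sub = sub.sort_values("start")
        strand = sub["strand"].iloc[0]
        chrom = sub["chrom"].iloc[0]
        parts, coords = [], []
        for r in sub.itertuples(index=False):
            parts.append(reference[chrom][int(r.start) : int(r.end)].upper())
            coords.extend(range(int(r.start), int(r.end)))
        seq = "".join(parts)
        if strand == "-":
            seq = seq.translate(_COMP)[::-1]
            coords = coords[::-1]
        if len(seq) % 3 != 0:
            log.warning("extract_4dtv_sites: CDS %s length %d not divisible by 3; skipped",
                        gene, len(seq))
            continue
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if any(b not in "ACGT" for b in codon):
                continue
            if pre[codon[:2]]:
                rows.append((chrom, coords[i + 2] + 1, gene))  # 1-based forward pos
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene"]).drop_duplicates(
        subset=["chrom", "pos"]
    ).reset_index(drop=True)
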