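"""Site-level quality control for inbred-panel SNP data.

Highly inbred panels (selfing crops) should show almost no heterozygosity;
sites with excess heterozygote calls are usually collapsed paralogues rather
than true variants.  The ladder implemented here is:

1. bi-allelic restriction (done at VCF read time),
2. an optional upstream keep list (hard-filter pass-through hook),
3. heterozygosity-excess filtering via the per-site inbreeding coefficient
   F = 1 - Hobs/Hexp against a per-chromosome ceiling
   Hobs_max = multiplier * (1 - F_median) * Hexp, with F_median the median F
   over sites with F > 0 and MAF > 0.05,
4. missingness/MAF filtering (drop when missing rate > 0.20 or MAF < 0.01,
   strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "SiteStats",
    "site_stats",
    "chromosome_f_median",
    "het_excess_filter",
    "maf_missing_filter",
    "qc_pipeline",
]


@dataclass
class SiteStats:
    """Per-site allele/genotype statistics (arrays over sites).

    ``defined`` is False where no accession was called or where Hexp = 0,
    in which case F is NaN.
    """

    p: np.ndarray          # non-reference allele frequency
    hobs: np.ndarray       # heterozygote call frequency
    hexp: np.ndarray       # 2 p (1-p)
    f: np.ndarray          # inbreeding coefficient 1 - Hobs/Hexp
    maf: np.ndarray
    missing_rate: np.ndarray
    called: np.ndarray     # number of called accessions per site

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p": self.p,
                "hobs": self.hobs,
                "hexp": self.hexp,
                "f": self.f,
                "maf": self.maf,
                "missing_rate": self.missing_rate,
                "called": self.called,
            }
        )


def site_stats(gm: GenotypeMatrix) -> SiteStats:
    """Compute per-site frequencies over non-missing calls.

    Heterozygotes contribute one reference and one alternate allele to the
    allele frequency.  Sites with zero called accessions get NaN statistics
    (downstream filters drop them).
    """
    calls = gm.calls
    miss = calls == MISSING
    called = (~miss).sum(axis=1)
    n_het = (calls == 1).sum(axis=1)
    n_alt_hom = (calls == 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2.0 * n_alt_hom + n_het) / (2.0 * called)
        hobs = n_het / called
        hexp = 2.0 * p * (1.0 - p)
        f = 1.0 - hobs / hexp
    p[called == 0] = np.nan
    maf = np.minimum(p, 1.0 - p)
    missing_rate = miss.sum(axis=1) / calls.shape[1]
    return SiteStats(p, hobs, hexp, f, maf, missing_rate, called)


def chromosome_f_median(
    stats: SiteStats,
    chrom: np.ndarray,
    maf_for_median: float = 0.05,
) -> dict:
    """Median inbreeding coefficient per chromosome.

    Only sites with F > 0 and MAF > ``maf_for_median`` qualify.  Even counts
    take the mean of the two middle order statistics.  A chromosome with no
    qualifying site raises, naming it.
    """
    chrom = np.asarray(chrom, dtype=object)
    qual = (stats.f > 0) & (stats.maf > maf_for_median)
    out = {}
    for c in dict.fromkeys(chrom.tolist()):
        vals = stats.f[qual & (chrom == c)]
        if len(vals) == 0:
            raise ValueError(
                f"chromosome {c}: no site with F > 0 and MAF > {maf_for_median}; "
                "panel may be too small for the heterozygosity-excess filter"
            )
        out[c] = float(np.median(vals))
    return out


def het_excess_filter(
    stats: SiteStats,
    chrom: np.ndarray,
    f_median: dict,
    multiplier: float = 10.0,
) -> np.ndarray:
    """Keep mask for the heterozygosity-excess filter.

    A site is dropped iff Hobs > multiplier * (1 - F_median[chrom]) * Hexp,
    with Hexp the site's own expected heterozygosity.  Monomorphic sites
    (Hexp = 0) are kept: bi-allelic coding means Hobs = 0 there.  Sites with
    zero called accessions are dropped.
    """
    chrom = np.asarray(chrom, dtype=object)
    fmed = np.array([f_median[c] for c in chrom], dtype=float)
    hobs_max = multiplier * (1.0 - fmed) * stats.hexp
    with np.errstate(invalid="ignore"):
        drop = stats.hobs > hobs_max
    keep = ~drop
    keep[stats.called == 0] = False
    keep[np.nan_to_num(stats.hexp) == 0] = True
    keep &= stats.called > 0
    return keep


def maf_missing_filter(
    stats: SiteStats,
    max_missing: float = 0.20,
    min_maf: float = 0.01,
) -> np.ndarray:
    """Keep mask: drop iff missing rate > max_missing OR MAF < min_maf.

    Inequalities are strict: a site at exactly the threshold is kept.
    Sites with undefined frequencies (nothing called) are dropped.
    """
    with np.errstate(invalid="ignore"):
        drop = (stats.missing_rate > max_missing) | (stats.maf < min_maf)
    drop |= stats.called == 0
    return ~drop


def qc_pipeline(
    gm: GenotypeMatrix,
    upstream_keep: np.ndarray | None = None,
    multiplier: float = 10.0,
    max_missing: float = 0.20,
    min_maf: float = 0.01,
    maf_for_median: float = 0.05,
):
    """Run the full site-QC ladder; returns (filtered gm, report frame).

    ``upstream_keep`` is the pass-through hook for hard filters applied
    before this package (a boolean mask over sites).  The report has one row
    per input site with all statistics and the drop reason (empty if kept).
    """
    stats = site_stats(gm)
    n = gm.n_sites
    reason = np.array([""] * n, dtype=object)
    keep = np.ones(n, dtype=bool)
    if upstream_keep is not None:
        upstream_keep = np.asarray(upstream_keep, dtype=bool)
        reason[~upstream_keep & keep] = "upstream"
        keep &= upstream_keep
    fmed = chromosome_f_median(stats, gm.chrom, maf_for_median)
    het_keep = het_excess_filter(stats, gm.chrom, fmed, multiplier)
    reason[~het_keep & keep] = "het_excess"
    keep &= het_keep
    mm_keep = maf_missing_filter(stats, max_missing, min_maf)
    reason[~mm_keep & keep] = "maf_missing"
    keep &= mm_keep
    report = stats.to_frame()
    report.insert(0, "pos", gm.pos)
    report.insert(0, "chrom", gm.chrom)
    report["kept"] = keep
    report["drop_reason"] = reason
    return gm.take_sites(keep), report
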