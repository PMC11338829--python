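"""Linkage-disequilibrium haplotype map construction.

Stages: pairwise LD statistics (D, D', r^2) from phased haplotypes;
two-step greedy LD pruning (10-kb then 50-SNP windows, r^2 > 0.8);
Gabriel-style haploblock detection from D' confidence intervals; merging of
adjacent blocks whose inter-block |D'| lower quartile exceeds 0.98;
haplogroup clustering within blocks; and landrace/modern sharing
classification of haplogroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, PhasedHaplotypes

__all__ = [
    "LDStat",
    "Haploblock",
    "ld_pair",
    "genotype_r2",
    "ld_prune",
    "two_step_prune",
    "find_blocks",
    "merge_blocks",
    "cluster_haplogroups",
    "classify_sharing",
]


@dataclass
class LDStat:
    """Pairwise LD between two sites (alt-allele convention)."""

    i: int
    j: int
    d: float
    d_prime: float
    r2: float
    counts: tuple  # haplotype counts (n11, n10, n01, n00) over alt/ref
    defined: bool = True


def ld_pair(haps: PhasedHaplotypes, i: int, j: int) -> LDStat:
    """D, D' and r^2 from direct phased haplotype counts.

    D = p11 - p1. p.1; D' = D/Dmax with Dmax = min(pA pb, pa pB) for D > 0
    and min(pA pB, pa pb) for D < 0.  A monomorphic site yields an
    undefined-LD result (``defined=False``), not an exception.
    """
    a = haps.haps[i]
    b = haps.haps[j]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(int), b[ok].astype(int)
    n = len(a)
    n11 = int(((a == 1) & (b == 1)).sum())
    n10 = int(((a == 1) & (b == 0)).sum())
    n01 = int(((a == 0) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    counts = (n11, n10, n01, n00)
    if n == 0:
        return LDStat(i, j, np.nan, np.nan, np.nan, counts, False)
    pa = (n11 + n10) / n
    pb = (n11 + n01) / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return LDStat(i, j, np.nan, np.nan, np.nan, counts, False)
    d = n11 / n - pa * pb
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        dmax = 1.0
    d_prime = d / dmax if dmax > 0 else 0.0
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return LDStat(i, j, d, d_prime, r2, counts)


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of genotype dosages over shared calls.

    Undefined (monomorphic among shared calls) pairs return 0.0, so they
    never trigger pruning.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = x[ok].astype(float)
    y = y[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    mode: str,
    window: float,
    r2_max: float = 0.8,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns kept site indices.

    ``mode='kb'``: a candidate site is dropped if any *kept* site within
    ``window`` kb on the same chromosome has r^2 > ``r2_max`` with it.
    ``mode='snp'``: the window is the last ``window - 1`` kept sites of the
    chromosome.  Keeping the earlier member of an offending pair makes the
    procedure idempotent.
    """
    if mode not in ("kb", "snp"):
        raise ValueError("mode must be 'kb' or 'snp'")
    kept: list = []
    kept_by_chrom: dict = {}
    for s in range(gm.n_sites):
        c = gm.chrom[s]
        prior = kept_by_chrom.get(c, [])
        if mode == "kb":
            lo = gm.pos[s] - window * 1000.0
            cand = [t for t in prior if gm.pos[t] >= lo]
        else:
            cand = prior[-(int(window) - 1):] if int(window) > 1 else []
        drop = any(genotype_r2(gm.calls[s], gm.calls[t]) > r2_max for t in cand)
        if not drop:
            kept.append(s)
            kept_by_chrom.setdefault(c, []).append(s)
    return np.array(kept, dtype=int)


def two_step_prune(gm: GenotypeMatrix, kb_window: float = 10.0,
                   snp_window: int = 50, r2_max: float = 0.8) -> np.ndarray:
    """The two-round pruning schedule (10-kb window, then 50-SNP window)."""
    k1 = ld_prune(gm, "kb", kb_window, r2_max)
    gm2 = gm.take_sites(k1)
    k2 = ld_prune(gm2, "snp", snp_window, r2_max)
    return k1[k2]


# ---------------------------------------------------------------------------
# Gabriel-style blocks


def dprime_ci(counts: tuple, grid_step: float = 0.01) -> tuple:
    """(lower, upper) 90% confidence bounds on |D'| from haplotype counts.

    Likelihood over a |D'| grid at the observed allele frequencies with the
    observed sign of D, normalized to a posterior under a flat prior; bounds
    at cumulative 0.05 and 0.95.
    """
    n11, n10, n01, n00 = counts
    n = n11 + n10 + n01 + n00
    if n == 0:
        return (0.0, 1.0)
    pa = (n11 + n10) / n
    pb = (n11 + n01) / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return (0.0, 1.0)
    d_obs = n11 / n - pa * pb
    if d_obs >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
        sign = 1.0
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
        sign = -1.0
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    d = sign * grid * dmax
    f11 = np.clip(pa * pb + d, 1e-12, 1.0)
    f10 = np.clip(pa * (1 - pb) - d, 1e-12, 1.0)
    f01 = np.clip((1 - pa) * pb - d, 1e-12, 1.0)
    f00 = np.clip((1 - pa) * (1 - pb) + d, 1e-12, 1.0)
    ll = n11 * np.log(f11) + n10 * np.log(f10) + n01 * np.log(f01) + n00 * np.log(f00)
    post = np.exp(ll - ll.max())
    cdf = np.cumsum(post)
    cdf /= cdf[-1]
    low = grid[int(np.argmax(cdf >= 0.05))]
    high = grid[int(np.argmax(cdf >= 0.95))]
    return (float(low), float(high))


@dataclass
class Haploblock:
    """A strong-LD block: a contiguous run of sites on one chromosome."""

    chrom: str
    sites: np.ndarray            # indices into the site table, contiguous
    start_bp: int                # position of first member SNP (1-based)
    end_bp: int                  # position of last member SNP (1-based)
    merged_from: list = field(default_factory=list)

    @property
    def span_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


def find_blocks(
    haps: PhasedHaplotypes,
    max_kb: float = 1000.0,
    min_maf: float = 0.05,
    max_missing: float = 0.10,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    informative_frac: float = 0.95,
) -> list:
    """Gabriel-style haploblock detection on phased haplotypes.

    Pairs are classified from the |D'| confidence interval: strong LD when
    lower >= ``strong_low`` and upper >= ``strong_high``; evidence of
    recombination when upper < ``recomb_high``; otherwise uninformative.  A
    block is a span whose endpoint pair is strong LD and in which at least
    ``informative_frac`` of informative pairs are strong LD; candidate spans
    are ranked by bp length and accepted greedily without overlap.  Sites are
    pre-filtered at MAF >= ``min_maf`` and missingness <= ``max_missing``;
    no block exceeds ``max_kb``.
    """
    n_acc2 = haps.haps.shape[1]
    miss = haps.haps == MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        called = (~miss).sum(axis=1)
        p = np.where(called > 0, (haps.haps == 1).sum(axis=1) / np.maximum(called, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    usable = (maf >= min_maf) & (miss.sum(axis=1) / n_acc2 <= max_missing)
    idx = np.flatnonzero(usable)

    cls_cache: dict = {}

    def classify(i: int, j: int) -> int:
        """1 strong, -1 recombination, 0 uninformative."""
        key = (i, j)
        if key not in cls_cache:
            st = ld_pair(haps, i, j)
            if not st.defined:
                cls_cache[key] = 0
            else:
                low, high = dprime_ci(st.counts)
                if low >= strong_low and high >= strong_high:
                    cls_cache[key] = 1
                elif high < recomb_high:
                    cls_cache[key] = -1
                else:
                    cls_cache[key] = 0
        return cls_cache[key]

    blocks = []
    for c in haps.chromosomes:
        cidx = idx[haps.chrom[idx] == c]
        m = len(cidx)
        cand = []
        for a in range(m):
            for b in range(a + 1, m):
                if (haps.pos[cidx[b]] - haps.pos[cidx[a]]) / 1000.0 > max_kb:
                    break
                if classify(cidx[a], cidx[b]) != 1:
                    continue
                strong = rec = 0
                for u in range(a, b + 1):
                    for v in range(u + 1, b + 1):
                        k = classify(cidx[u], cidx[v])
                        if k == 1:
                            strong += 1
                        elif k == -1:
                            rec += 1
                if strong + rec == 0 or strong / (strong + rec) < informative_frac:
                    continue
                cand.append((a, b))
        cand.sort(key=lambda ab: (-(haps.pos[cidx[ab[1]]] - haps.pos[cidx[ab[0]]]), ab[0]))
        taken = np.zeros(m, dtype=bool)
        chosen = []
        for a, b in cand:
            if taken[a : b + 1].any():
                continue
            taken[a : b + 1] = True
            chosen.append((a, b))
        for a, b in sorted(chosen):
            sites = cidx[a : b + 1]
            blocks.append(
                Haploblock(c, sites, int(haps.pos[sites[0]]), int(haps.pos[sites[-1]]))
            )
    return blocks


def merge_blocks(blocks: list, haps: PhasedHaplotypes, q1_threshold: float = 0.98) -> list:
    """Merge adjacent blocks whose inter-block |D'| lower quartile > 0.98.

    For each adjacent pair of blocks on a chromosome, |D'| is computed for
    every inter-block SNP pair; if Q1 (type-7 linear interpolation) exceeds
    the threshold, the blocks merge.  Passes repeat left-to-right until no
    merge occurs.  Merging never shrinks spans and terminates because the
    block count strictly decreases.
    """
    blocks = [
        Haploblock(b.chrom, b.sites.copy(), b.start_bp, b.end_bp, list(b.merged_from) or [b])
        for b in blocks
    ]
    changed = True
    while changed:
        changed = False
        out = []
        i = 0
        while i < len(blocks):
            cur = blocks[i]
            if i + 1 < len(blocks) and blocks[i + 1].chrom == cur.chrom:
                nxt = blocks[i + 1]
                vals = [
                    abs(ld_pair(haps, int(u), int(v)).d_prime)
                    for u in cur.sites
                    for v in nxt.sites
                    if ld_pair(haps, int(u), int(v)).defined
                ]
                if vals and float(np.quantile(vals, 0.25)) > q1_threshold:
                    merged = Haploblock(
                        cur.chrom,
                        np.concatenate([cur.sites, nxt.sites]),
                        cur.start_bp,
                        nxt.end_bp,
                        cur.merged_from + nxt.merged_from,
                    )
                    out.append(merged)
                    i += 2
                    changed = True
                    continue
            out.append(cur)
            i += 1
        blocks = out
    return blocks


def cluster_haplogroups(gm: GenotypeMatrix, block: Haploblock) -> np.ndarray:
    """Haplogroup label per accession for one block.

    Accessions with identical complete genotype strings over the member
    sites share a label; labels are dense integers ordered by descending
    carrier count (ties by first occurrence).  Strings with missing data
    join the nearest complete group by normalized Hamming distance over
    jointly observed sites (ties to the lower label).  All-missing
    accessions get label -1.
    """
    sub = gm.calls[block.sites]  # sites x accessions
    n_acc = sub.shape[1]
    complete = ~(sub == MISSING).any(axis=0)
    groups: dict = {}
    order: list = []
    for a in range(n_acc):
        if complete[a]:
            key = tuple(sub[:, a].tolist())
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(a)
    keys = sorted(order, key=lambda k: (-len(groups[k]), order.index(k)))
    labels = np.full(n_acc, -1, dtype=int)
    reps = []
    for lab, k in enumerate(keys):
        for a in groups[k]:
            labels[a] = lab
        reps.append(np.array(k))
    for a in range(n_acc):
        if complete[a] or not reps:
            continue
        col = sub[:, a]
        obs = col != MISSING
        if not obs.any():
            continue  # all-missing stays -1
        best, best_d = -1, np.inf
        for lab, rep in enumerate(reps):
            d = float((col[obs] != rep[obs]).mean())
            if d < best_d - 1e-12:
                best, best_d = lab, d
        labels[a] = best
    return labels


def classify_sharing(
    hg: dict,
    panel: dict,
    panel_a: str = "landrace",
    panel_b: str = "modern",
    ratio: float = 3.0,
) -> pd.DataFrame:
    """Classify each block haplogroup by panel sharing.

    ``hg`` maps block id -> {accession: label}.  A haplogroup with zero
    carriers in the other panel is that panel's unique haplotype; one whose
    carrier-frequency ratio is >= ``ratio`` is enriched; otherwise shared.
    """
    rows = []
    for block_id, labels in hg.items():
        acc_a = [a for a in labels if panel.get(a) == panel_a]
        acc_b = [a for a in labels if panel.get(a) == panel_b]
        if not acc_a or not acc_b:
            raise ValueError("classify_sharing needs accessions in both panels")
        for lab in sorted({v for v in labels.values() if v is not None and v >= 0}):
            na = sum(1 for a in acc_a if labels[a] == lab)
            nb = sum(1 for a in acc_b if labels[a] == lab)
            fa, fb = na / len(acc_a), nb / len(acc_b)
            if na > 0 and nb == 0:
                cat = f"{panel_a}-unique"
            elif nb > 0 and na == 0:
                cat = f"{panel_b}-unique"
            elif fb > 0 and fa / fb >= ratio:
                cat = f"{panel_a}-enriched"
            elif fa > 0 and fb / fa >= ratio:
                cat = f"{panel_b}-enriched"
            else:
                cat = "shared"
            rows.append((block_id, lab, na, nb, fa, fb, cat))
    return pd.DataFrame(
        rows,
        columns=["block", "haplogroup", f"n_{panel_a}", f"n_{panel_b}",
                 f"freq_{panel_a}", f"freq_{panel_b}", "category"],
    )
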