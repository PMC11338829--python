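"""Haplotype-diagnostic (tag) SNP selection.

Genotypes are re-encoded as -1 (hom-ref), 0 (het), +1 (hom-alt), NaN
(missing).  For every unordered haplogroup pair within a block, each site's
discriminating power is d = (s_h1 - s_h2)^2 — the squared difference of the
mean encoded state over each group's carriers — quadrupled when the site
lies in a coding region.  The max-d site per pair is the pair's tagSNP; the
union over pairs is the block's tagSNP set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .ld import Haploblock

__all__ = [
    "encode_tag",
    "group_state",
    "pair_distance",
    "select_tagsnps",
    "evaluate_tagsnps",
    "TagSNP",
]

_ENC = {0: -1.0, 1: 0.0, 2: 1.0, MISSING: np.nan}


def encode_tag(calls: np.ndarray) -> np.ndarray:
    """Map genotype codes {0,1,2,-9} to tag codes {-1,0,+1,NaN}."""
    out = calls.astype(float)
    out[calls == 0] = -1.0
    out[calls == 1] = 0.0
    out[calls == 2] = 1.0
    out[calls == MISSING] = np.nan
    return out


def group_state(enc: np.ndarray, carriers: np.ndarray, site: int) -> float:
    """Mean encoded state of a haplogroup's carriers at one site.

    NaN entries (missing genotypes) are dropped from the mean; if every
    carrier is missing the state is NaN and the site is skipped for the
    pair.
    """
    v = enc[site, carriers]
    v = v[~np.isnan(v)]
    return float(v.mean()) if len(v) else np.nan


def pair_distance(s1: float, s2: float, coding: bool = False) -> float:
    """d = (s1 - s2)^2, quadrupled for coding-region sites."""
    d = (s1 - s2) ** 2
    return 4.0 * d if coding else d


@dataclass
class TagSNP:
    block: str
    pair: tuple       # (haplogroup1, haplogroup2)
    site: int         # site index into the genotype matrix
    chrom: str
    pos: int
    d: float
    coding: bool


def select_tagsnps(
    gm: GenotypeMatrix,
    block: Haploblock,
    labels: np.ndarray,
    coding_mask: np.ndarray,
    block_id: str = "block",
) -> list:
    """Max-distance tagSNP per haplogroup pair; union over pairs.

    ``labels`` is the per-accession haplogroup label for the block (-1 for
    missing); ``coding_mask`` is a boolean per site of the matrix.  Ties at
    equal d go to the leftmost genomic position.  A block with a single
    haplogroup yields an empty set.
    """
    enc = encode_tag(gm.calls)
    groups = sorted({int(l) for l in labels if l >= 0})
    out = []
    seen = set()
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            h1 = np.flatnonzero(labels == groups[gi])
            h2 = np.flatnonzero(labels == groups[gj])
            best_site, best_d = None, -1.0
            for s in block.sites:
                s = int(s)
                s1 = group_state(enc, h1, s)
                s2 = group_state(enc, h2, s)
                if np.isnan(s1) or np.isnan(s2):
                    continue
                d = pair_distance(s1, s2, bool(coding_mask[s]))
                if d > best_d + 1e-15:
                    best_site, best_d = s, d
            if best_site is not None:
                key = (groups[gi], groups[gj])
                out.append(
                    TagSNP(block_id, key, best_site, str(gm.chrom[best_site]),
                           int(gm.pos[best_site]), best_d, bool(coding_mask[best_site]))
                )
                seen.add(best_site)
    return out


def evaluate_tagsnps(
    gm: GenotypeMatrix,
    tags: list,
    labels: np.ndarray,
    test_accessions: np.ndarray,
    train_accessions: np.ndarray | None = None,
) -> float:
    """Accuracy of nearest-group haplogroup classification from tag genotypes.

    Group mean vectors over the tag sites are computed from the training
    accessions (all labelled accessions by default); each test accession is
    assigned the group with minimal Euclidean distance of its encoded tag
    vector (over its non-missing tags).  Accessions missing at every tag are
    excluded from the denominator.  Returns the fraction correct.
    """
    sites = sorted({t.site for t in tags})
    if not sites:
        return np.nan
    enc = encode_tag(gm.calls)[sites, :]  # tags x accessions
    if train_accessions is None:
        train_accessions = np.flatnonzero(labels >= 0)
    groups = sorted({int(labels[a]) for a in train_accessions if labels[a] >= 0})
    centroids = {}
    for g in groups:
        cols = [a for a in train_accessions if labels[a] == g]
        centroids[g] = np.nanmean(enc[:, cols], axis=1)
    n_ok = n_correct = 0
    for a in test_accessions:
        v = enc[:, a]
        obs = ~np.isnan(v)
        if not obs.any() or labels[a] < 0:
            continue
        best, best_d = None, np.inf
        for g in groups:
            c = centroids[g]
            use = obs & ~np.isnan(c)
            if not use.any():
                continue
            d = float(((v[use] - c[use]) ** 2).sum())
            if d < best_d:
                best, best_d = g, d
        if best is None:
            continue
        n_ok += 1
        n_correct += int(best == labels[a])
    return n_correct / n_ok if n_ok else np.nan
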