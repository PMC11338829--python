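"""Projection of parental whole-genome SNPs onto RIL skeleton genotypes.

Array-derived skeleton markers (calls A/B/H/- per RIL: A = parent-1 allele,
B = parent-2, H heterozygous, - missing) govern the imputation of every
parental SNP site: a site inside a haploblock is governed by the nearest
skeleton marker within the block (bp distance), any other site by the
nearest marker on the chromosome.  Populations are merged over the union
of sites, pruned with the two-step LD schedule, and phenotypes are
standardized as percentage of the environmental mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .ld import two_step_prune

logger = logging.getLogger("hapweave.nam")

__all__ = [
    "preprocess_skeleton",
    "impute_ril",
    "merge_populations",
    "nam_prune",
    "percent_env_mean",
]


def preprocess_skeleton(skeleton: pd.DataFrame, parents: GenotypeMatrix,
                        parent1: str, parent2: str):
    """Validate skeleton markers against the parental sequence calls.

    Markers are dropped when (a) their position is absent from the parental
    SNP matrix, (b) the parents are not both homozygous and polymorphic
    between each other there, or (c) the marker's declared alleles disagree
    with the parental sequence genotypes.  ``skeleton`` needs columns
    marker, chrom, pos, allele_a, allele_b plus one column per RIL.
    Returns (kept skeleton frame, drop-report frame).
    """
    i1 = parents.accession_index(parent1)
    i2 = parents.accession_index(parent2)
    site_of = {(c, int(p)): s for s, (c, p) in enumerate(zip(parents.chrom, parents.pos))}
    reasons = []
    for row in skeleton.itertuples(index=False):
        key = (row.chrom, int(row.pos))
        if key not in site_of:
            reasons.append((row.marker, "unmapped"))
            continue
        s = site_of[key]
        g1, g2 = parents.calls[s, i1], parents.calls[s, i2]
        if g1 == MISSING or g2 == MISSING or g1 == 1 or g2 == 1:
            reasons.append((row.marker, "parent_not_homozygous"))
            continue
        if g1 == g2:
            reasons.append((row.marker, "monomorphic"))
            continue
        seq_a = parents.ref[s] if g1 == 0 else parents.alt[s]
        seq_b = parents.ref[s] if g2 == 0 else parents.alt[s]
        if row.allele_a != seq_a or row.allele_b != seq_b:
            reasons.append((row.marker, "inconsistent"))
            continue
        reasons.append((row.marker, "kept"))
    kept_names = {m for m, r in reasons if r == "kept"}
    if not kept_names:
        raise ValueError("no skeleton marker survived pre-processing")
    report = pd.DataFrame(reasons, columns=["marker", "status"])
    return skeleton[skeleton["marker"].isin(kept_names)].reset_index(drop=True), report


def _combine_parent_calls(g1: int, g2: int, call: str) -> int:
    """Imputed genotype at one site from the governing marker's call."""
    if call == "A":
        return int(g1)
    if call == "B":
        return int(g2)
    if call == "H":
        if g1 == MISSING or g2 == MISSING or g1 == 1 or g2 == 1:
            return MISSING  # ambiguous inheritance through a het parent
        return (g1 + g2) // 2  # one allele from each homozygous parent
    return MISSING


def impute_ril(skeleton: pd.DataFrame, parents: GenotypeMatrix,
               parent1: str, parent2: str, blocks: list,
               ril_ids: list | None = None) -> GenotypeMatrix:
    """Impute every parental SNP site for every RIL from its skeleton calls.

    Governing marker: nearest (bp) skeleton marker inside the site's
    haploblock when the block holds one, otherwise the nearest marker on
    the chromosome; equidistant ties go to the lower coordinate.  When a
    RIL is missing ('-') at the governing marker, the next-nearest
    non-missing marker in the same scope is used.  A chromosome without any
    skeleton marker imputes as missing with a warning.
    """
    if ril_ids is None:
        meta = {"marker", "chrom", "pos", "allele_a", "allele_b"}
        ril_ids = [c for c in skeleton.columns if c not in meta]
    i1 = parents.accession_index(parent1)
    i2 = parents.accession_index(parent2)
    n_sites = parents.n_sites
    out = np.full((n_sites, len(ril_ids)), MISSING, dtype=np.int8)

    mk_by_chrom = {
        c: sub.sort_values("pos").reset_index(drop=True)
        for c, sub in skeleton.groupby("chrom")
    }
    # block membership per site (blocks carry 1-based inclusive SNP spans)
    block_of = np.full(n_sites, -1, dtype=int)
    for bi, b in enumerate(blocks):
        in_b = (parents.chrom == b.chrom) & (parents.pos >= b.start_bp) & (parents.pos <= b.end_bp)
        block_of[in_b] = bi

    calls_matrix = skeleton[ril_ids].to_numpy(dtype=object)
    marker_row = {m: i for i, m in enumerate(skeleton["marker"])}

    for s in range(n_sites):
        c = parents.chrom[s]
        if c not in mk_by_chrom:
            logger.warning("impute_ril: chromosome %s has no skeleton marker", c)
            continue
        mk = mk_by_chrom[c]
        scope = mk
        bi = block_of[s]
        if bi >= 0:
            b = blocks[bi]
            in_b = mk[(mk["pos"] >= b.start_bp) & (mk["pos"] <= b.end_bp)]
            if len(in_b):
                scope = in_b
        dist = np.abs(scope["pos"].to_numpy() - parents.pos[s])
        order = np.lexsort((scope["pos"].to_numpy(), dist))  # dist, then lower pos
        g1, g2 = int(parents.calls[s, i1]), int(parents.calls[s, i2])
        ordered_rows = [marker_row[scope["marker"].iloc[int(o)]] for o in order]
        for r in range(len(ril_ids)):
            for mrow in ordered_rows:
                call = calls_matrix[mrow, r]
                if call in ("A", "B", "H"):
                    out[s, r] = _combine_parent_calls(g1, g2, call)
                    break
    return GenotypeMatrix(parents.chrom, parents.pos, parents.ref, parents.alt,
                          out, list(ril_ids))


def merge_populations(pops: dict) -> GenotypeMatrix:
    """Merge imputed populations over the union of sites.

    ``pops`` maps population name -> GenotypeMatrix; accession ids become
    ``pop:ril``.  Sites absent from a population are missing for its RILs.
    """
    key_order: list = []
    seen = set()
    site_info = {}
    for name, gm in pops.items():
        for s in range(gm.n_sites):
            key = (gm.chrom[s], int(gm.pos[s]))
            if key not in seen:
                seen.add(key)
                key_order.append(key)
                site_info[key] = (gm.ref[s], gm.alt[s])
    key_order.sort(key=lambda k: (k[0], k[1]))
    index = {k: i for i, k in enumerate(key_order)}
    acc_ids: list = []
    cols = []
    for name, gm in pops.items():
        ids = [f"{name}:{a}" for a in gm.accession_ids]
        dup = {i for i in ids if ids.count(i) > 1} | (set(ids) & set(acc_ids))
        if dup:
            raise ValueError(f"duplicate RIL ids after namespacing: {sorted(dup)}")
        acc_ids.extend(ids)
        block = np.full((len(key_order), gm.n_accessions), MISSING, dtype=np.int8)
        rows = [index[(gm.chrom[s], int(gm.pos[s]))] for s in range(gm.n_sites)]
        block[rows, :] = gm.calls
        cols.append(block)
    chrom = np.array([k[0] for k in key_order], dtype=object)
    pos = np.array([k[1] for k in key_order], dtype=np.int64)
    ref = np.array([site_info[k][0] for k in key_order], dtype=object)
    alt = np.array([site_info[k][1] for k in key_order], dtype=object)
    return GenotypeMatrix(chrom, pos, ref, alt, np.concatenate(cols, axis=1), acc_ids)


def nam_prune(gm: GenotypeMatrix, kb_window: float = 10.0, snp_window: int = 50,
              r2_max: float = 0.8) -> np.ndarray:
    """Two-round LD pruning of the merged matrix (kept site indices)."""
    return two_step_prune(gm, kb_window, snp_window, r2_max)


def percent_env_mean(traits: pd.DataFrame, controls: list | None = None,
                     outlier_mad: float | None = 5.0) -> pd.DataFrame:
    """Standardize trait values as percentage of the environmental mean.

    Control lines are removed first; within each (trait, environment),
    values with |value - median| > ``outlier_mad`` x MAD are removed
    (skipped when MAD = 0 or ``outlier_mad`` is None); remaining values are
    divided by the post-exclusion environment mean and multiplied by 100.
    """
    df = traits.copy()
    if controls:
        df = df[~df["line"].isin(controls)]
    out = []
    for (trait, env), sub in df.groupby(["trait", "environment"], sort=False):
        v = sub["value"].to_numpy(float)
        if outlier_mad is not None:
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            if mad > 0:
                sub = sub[np.abs(v - med) <= outlier_mad * mad]
        mean = sub["value"].mean()
        if mean == 0 or not np.isfinite(mean):
            raise ValueError(f"environment mean is zero for trait {trait!r} in {env!r}")
        sub = sub.copy()
        sub["value"] = sub["value"] / mean * 100.0
        out.append(sub)
    return pd.concat(out, ignore_index=True)
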