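"""Gene copy-number estimation from read depth.

Pipeline: collapse recently duplicated genes (CDS alignments with fewer
than five gaps and fewer than five mismatches) summing member depths onto a
representative; normalize by per-accession mean sequencing depth to a
relative depth value (RDV); correct GC bias against a 1,000-bp-window depth
profile; bin RDVs into copy-number classes [0, 0.25), [0.25, 0.75),
[0.75, 1.25), ...; and classify per-gene CNVs as panel-unique or shared.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "collapse_duplicates",
    "normalize_depth",
    "gc_correction_factors",
    "gc_correction",
    "bin_copy_number",
    "bin_label",
    "classify_population_cnv",
    "cnv_pipeline",
]


def collapse_duplicates(cds_pairs: pd.DataFrame, genes: list) -> dict:
    """Partition genes into recent-duplicate groups via union-find.

    A pair joins one group iff gaps < 5 AND mismatches < 5 (strict).  The
    partition is the transitive closure; each group's representative is its
    smallest gene id.  Returns gene -> representative.
    """
    genes = list(genes)
    known = set(genes)
    in_pairs = set(cds_pairs["gene_a"]) | set(cds_pairs["gene_b"])
    unknown = sorted(in_pairs - known)
    if unknown:
        raise ValueError(f"genes in CDS pair table absent from depth table: {unknown}")
    parent = {g: g for g in genes}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    hits = cds_pairs[(cds_pairs["gaps"] < 5) & (cds_pairs["mismatches"] < 5)]
    for a, b in zip(hits["gene_a"], hits["gene_b"]):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    return {g: find(g) for g in genes}


def _collapse_depths(depths: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Sum per-accession depths of duplicate-group members onto the representative."""
    d = depths.copy()
    d["gene"] = d["gene"].map(groups)
    return d.groupby(["gene", "accession"], as_index=False)["depth"].sum()


def normalize_depth(depths: pd.DataFrame, accession_coverage: dict) -> pd.DataFrame:
    """RDV = summed gene depth / accession mean sequencing depth."""
    bad = [a for a, c in accession_coverage.items() if c <= 0]
    if bad:
        raise ValueError(f"non-positive mean coverage for accessions {bad}")
    out = depths.copy()
    out["rdv"] = out["depth"] / out["accession"].map(accession_coverage)
    return out


def gc_correction_factors(gc_profile: pd.DataFrame) -> np.ndarray:
    """Per-GC-bin correction factors from a 1,000-bp-window depth profile.

    ``gc_profile`` has columns ``gc_bin`` (integer percent 0..100) and
    ``mean_depth``.  factor(bin) = mean window depth in the bin / overall
    mean window depth; empty bins borrow the nearest non-empty bin.
    """
    depth = np.full(101, np.nan)
    for _, row in gc_profile.iterrows():
        depth[int(row["gc_bin"])] = row["mean_depth"]
    filled = ~np.isnan(depth)
    if not filled.any():
        raise ValueError("GC profile is entirely empty")
    overall = depth[filled].mean()  # mean over observed windows only
    idx = np.flatnonzero(filled)
    nearest = idx[np.argmin(np.abs(np.arange(101)[:, None] - idx[None, :]), axis=1)]
    depth = depth[nearest]
    return depth / overall


def gc_correction(rdv: pd.DataFrame, gene_gc: dict, gc_profile: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene's RDV by its GC bin's correction factor."""
    factors = gc_correction_factors(gc_profile)
    out = rdv.copy()
    bins = out["gene"].map(gene_gc).round().astype(int).clip(0, 100)
    out["rdv"] = out["rdv"] / factors[bins.values]
    return out


def bin_copy_number(rdv: float) -> int:
    """Copy-number bin index for one RDV.

    Bin 0 is [0, 0.25); bin k >= 1 is [0.25 + 0.5(k-1), 0.25 + 0.5k) — the
    printed grid [0.25-0.75), [0.75-1.25), ... extended upward.
    """
    if rdv < 0:
        raise ValueError("negative RDV")
    if rdv < 0.25:
        return 0
    return int((rdv - 0.25) // 0.5) + 1


def bin_label(k: int) -> str:
    if k == 0:
        return "[0-0.25)"
    lo = 0.25 + 0.5 * (k - 1)
    return f"[{lo:g}-{lo + 0.5:g})"


def classify_population_cnv(bins: pd.DataFrame, panel: dict,
                            reference_bin: int = 2) -> pd.DataFrame:
    """Per-gene, per-bin sharing classes across panels.

    ``bins`` has columns gene, accession, bin.  For each gene and each
    non-reference bin (the reference single-copy bin is [0.75-1.25), index
    2), carriers are counted per panel; a bin carried in exactly one panel
    is that panel's unique CNV, otherwise shared.
    """
    panels = sorted(set(panel.values()))
    if len(panels) < 2:
        raise ValueError("classify_population_cnv needs >= 2 panels")
    rows = []
    b = bins.copy()
    b["panel"] = b["accession"].map(panel)
    for (gene, k), sub in b.groupby(["gene", "bin"]):
        if k == reference_bin:
            continue
        counts = {p: int((sub["panel"] == p).sum()) for p in panels}
        carriers = [p for p in panels if counts[p] > 0]
        cat = f"{carriers[0]}-unique" if len(carriers) == 1 else "shared"
        rows.append((gene, int(k), bin_label(int(k)), *[counts[p] for p in panels], cat))
    return pd.DataFrame(rows, columns=["gene", "bin", "bin_label", *[f"n_{p}" for p in panels], "category"])


def cnv_pipeline(
    depths: pd.DataFrame,
    cds_pairs: pd.DataFrame,
    accession_coverage: dict,
    gene_gc: dict,
    gc_profile: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Depths -> collapsed, normalized, GC-corrected, binned copy numbers."""
    groups = collapse_duplicates(cds_pairs, sorted(depths["gene"].unique()))
    collapsed = _collapse_depths(depths, groups)
    rdv = normalize_depth(collapsed, accession_coverage)
    if gc_profile is not None:
        rdv = gc_correction(rdv, gene_gc, gc_profile)
    rdv["bin"] = [bin_copy_number(v) for v in rdv["rdv"]]
    rdv["bin_label"] = [bin_label(k) for k in rdv["bin"]]
    return rdv
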