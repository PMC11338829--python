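"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`GenotypeMatrix`, a sites x accessions table of
diploid bi-allelic genotype codes (0 hom-ref, 1 het, 2 hom-alt, -9 missing)
with per-site chromosome/position/allele annotation and an optional panel
label (e.g. ``landrace`` vs ``modern``) per accession.  Phase is deliberately
not part of it; :class:`PhasedHaplotypes` is the explicitly phased companion.

Coordinate conventions: SNP positions are 1-based base-pair coordinates (VCF
convention); window and block spans are 0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -9

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PhasedHaplotypes",
    "WindowTable",
    "tile_windows",
]


@dataclass
class GenotypeMatrix:
    """Bi-allelic SNP genotypes for a panel of accessions.

    Parameters
    ----------
    chrom : array of str, one per site
    pos : array of int, 1-based positions, strictly increasing per chromosome
    ref, alt : arrays of single-base allele strings
    calls : int array, shape (n_sites, n_accessions), codes {0, 1, 2, -9}
    accession_ids : list of str
    panel : mapping accession id -> panel label (optional)
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    accession_ids: list
    panel: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.accession_ids = list(self.accession_ids)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (sites x accessions)")
        if self.calls.shape != (len(self.pos), len(self.accession_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.pos)} sites x {len(self.accession_ids)} accessions"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[1]

    @property
    def chromosomes(self) -> list:
        """Chromosome ids in order of first appearance."""
        return list(dict.fromkeys(self.chrom.tolist()))

    def take_sites(self, index) -> "GenotypeMatrix":
        """Subset sites by integer index or boolean mask (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.chrom[index],
            self.pos[index],
            self.ref[index],
            self.alt[index],
            self.calls[index],
            self.accession_ids,
            dict(self.panel),
        )

    def take_accessions(self, ids) -> "GenotypeMatrix":
        idx = [self.accession_ids.index(a) for a in ids]
        return GenotypeMatrix(
            self.chrom,
            self.pos,
            self.ref,
            self.alt,
            self.calls[:, idx],
            list(ids),
            {a: self.panel[a] for a in ids if a in self.panel},
        )

    def accession_index(self, acc: str) -> int:
        return self.accession_ids.index(acc)

    def panel_accessions(self, label: str) -> list:
        return [a for a in self.accession_ids if self.panel.get(a) == label]

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.calls, other.calls)
            and self.accession_ids == other.accession_ids
        )


@dataclass
class PhasedHaplotypes:
    """Phased 0/1 haplotypes over the same site index as a GenotypeMatrix.

    ``haps`` has shape (n_sites, 2 * n_accessions); columns 2i and 2i+1 are
    the two haplotypes of accession i.  Missing haplotype alleles are -9.
    Collapsing the two haplotypes of an accession reproduces its genotype
    code at every non-missing site.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haps: np.ndarray
    accession_ids: list
    panel: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.haps = np.asarray(self.haps, dtype=np.int8)
        self.accession_ids = list(self.accession_ids)
        if self.haps.shape != (len(self.pos), 2 * len(self.accession_ids)):
            raise ValueError("haps must be (n_sites, 2*n_accessions)")

    @property
    def n_sites(self) -> int:
        return self.haps.shape[0]

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.chrom.tolist()))

    def accession_haplotypes(self, i: int) -> np.ndarray:
        """The (n_sites, 2) haplotype pair of accession number ``i``."""
        return self.haps[:, 2 * i : 2 * i + 2]

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse phase into diploid genotype codes."""
        a = self.haps[:, 0::2].astype(np.int16)
        b = self.haps[:, 1::2].astype(np.int16)
        calls = a + b
        calls[(a == MISSING) | (b == MISSING)] = MISSING
        return GenotypeMatrix(
            self.chrom, self.pos, self.ref, self.alt,
            calls.astype(np.int8), self.accession_ids, dict(self.panel),
        )

    def take_sites(self, index) -> "PhasedHaplotypes":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return PhasedHaplotypes(
            self.chrom[index], self.pos[index], self.ref[index],
            self.alt[index], self.haps[index], self.accession_ids,
            dict(self.panel),
        )


@dataclass
class WindowTable:
    """Non-overlapping genomic windows, 0-based half-open."""

    table: pd.DataFrame  # columns: chrom, start, end, window

    def __post_init__(self):
        req = {"chrom", "start", "end", "window"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"window table missing columns {sorted(missing)}")
        if (self.table["end"] <= self.table["start"]).any():
            raise ValueError("window with end <= start")
        for _, sub in self.table.groupby("chrom"):
            sub = sub.sort_values("start")
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                raise ValueError("overlapping windows within a chromosome")

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return self.table.itertuples(index=False)


def tile_windows(chrom_lengths: dict, size: int) -> WindowTable:
    """Tile each chromosome with consecutive windows of ``size`` bp.

    The final window of a chromosome is truncated at the chromosome end.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        k = 0
        while start < length:
            end = min(start + size, length)
            rows.append((chrom, start, end, f"{chrom}:{start}-{end}"))
            start = end
            k += 1
    return WindowTable(pd.DataFrame(rows, columns=["chrom", "start", "end", "window"]))
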