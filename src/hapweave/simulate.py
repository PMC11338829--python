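"""Synthetic wheat-like panels, populations, sequences, depths and traits.

The generators emulate the statistical structure the downstream stages
assume, at desk scale:

* a landrace panel of seven ancestral groups (``AG1``..``AG7``) with
  Balding--Nichols group-structured allele frequencies, geographic
  coordinates correlated with genetic distance except inside designated
  introgression windows;
* a "modern" panel founded as long identity-by-state mosaics of two of the
  groups (default AG2 and AG5);
* biparental recombinant inbred lines (RILs) by single-seed descent and
  BC2-derived near-isogenic families, with a Haldane (no-interference)
  crossover model throughout;
* gene read depths with GC bias, lognormal noise and recently duplicated
  gene groups; and
* plot-level traits with line/environment main effects, a rank-limited
  genotype-by-environment interaction and replicate noise.

Every generator is deterministic under a fixed seed and returns
machine-readable truth alongside the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, PhasedHaplotypes, WindowTable, tile_windows

logger = logging.getLogger("hapweave.simulate")

__all__ = [
    "SimConfig",
    "PanelSim",
    "MosaicGenome",
    "RILPopulation",
    "NILFamily",
    "sim_group_panel",
    "sim_modern_mosaics",
    "combine_mosaics",
    "sim_rils",
    "sim_bc_nils",
    "sim_sequences",
    "sim_gene_depths",
    "sim_traits",
    "meiosis",
]

_BASE = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the structured landrace panel generator."""

    n_chrom: int = 2
    chrom_len_bp: int = 5_000_000
    n_sites: int = 400                     # per chromosome
    n_groups: int = 7
    group_fst: float = 0.15                # Balding-Nichols differentiation
    group_sizes: tuple | None = None       # default 12 accessions per group
    modern_founder_groups: tuple = ("AG2", "AG5")
    recomb_rate: float = 1.0               # cM per Mb
    introgression_fraction: float = 0.0    # fraction of windows decoupled
    introgression_window_bp: int = 1_000_000
    geo_noise_deg: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2 per chromosome")
        if not 0.0 <= self.group_fst < 1.0:
            raise ValueError("group_fst must be in [0, 1)")
        if self.group_sizes is None:
            self.group_sizes = tuple([12] * self.n_groups)
        if len(self.group_sizes) != self.n_groups:
            raise ValueError("group_sizes length must equal n_groups")

    @property
    def group_names(self) -> list:
        return [f"AG{i + 1}" for i in range(self.n_groups)]


@dataclass
class PanelSim:
    """A simulated structured panel plus its truth."""

    haps: PhasedHaplotypes
    metadata: pd.DataFrame           # accession, group, panel, latitude, longitude
    introgression_windows: pd.DataFrame  # chrom, start, end, window (may be empty)
    group_freqs: np.ndarray          # sites x groups allele frequencies
    config: SimConfig

    @property
    def genotypes(self) -> GenotypeMatrix:
        return self.haps.to_genotypes()


def sim_group_panel(cfg: SimConfig) -> PanelSim:
    """Simulate a landrace panel of differentiated ancestral groups.

    Ancestral allele frequencies are Uniform(0.05, 0.95); each group's
    frequencies follow a Balding--Nichols Beta distribution at the group's
    Fst; haplotypes are Bernoulli draws from the group frequency.
    Geographic coordinates are the group centroid plus Gaussian noise.  In
    designated introgression windows every accession's genotypes are drawn
    from a random *other* group's frequencies, decoupling genotype from
    geography there.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    chroms, pos = [], []
    for c in chrom_names:
        # keep sites away from chromosome ends so k-mer windows stay valid
        p = np.sort(
            rng.choice(
                np.arange(200, cfg.chrom_len_bp - 200), size=cfg.n_sites, replace=False
            )
        )
        chroms.extend([c] * cfg.n_sites)
        pos.extend((p + 1).tolist())  # 1-based
    chroms = np.array(chroms, dtype=object)
    pos = np.array(pos, dtype=np.int64)
    n_sites = len(pos)

    anc = rng.uniform(0.05, 0.95, size=n_sites)
    fst = cfg.group_fst
    if fst > 0:
        a = anc * (1 - fst) / fst
        b = (1 - anc) * (1 - fst) / fst
        gfreq = rng.beta(a[:, None], b[:, None], size=(n_sites, cfg.n_groups))
    else:
        gfreq = np.repeat(anc[:, None], cfg.n_groups, axis=1)

    acc_ids, acc_group = [], []
    for g, name in enumerate(cfg.group_names):
        for j in range(cfg.group_sizes[g]):
            acc_ids.append(f"{name}_{j:03d}")
            acc_group.append(g)
    acc_group = np.array(acc_group)
    n_acc = len(acc_ids)

    freq_per_hap = gfreq[:, np.repeat(acc_group, 2)]
    haps = (rng.random((n_sites, 2 * n_acc)) < freq_per_hap).astype(np.int8)

    # introgression windows: per-accession genotypes redrawn from another group
    intro_rows = []
    if cfg.introgression_fraction > 0:
        wt = tile_windows({c: cfg.chrom_len_bp for c in chrom_names}, cfg.introgression_window_bp)
        wdf = wt.table
        n_pick = max(1, int(round(cfg.introgression_fraction * len(wdf))))
        pick = rng.choice(len(wdf), size=n_pick, replace=False)
        for k in sorted(pick):
            row = wdf.iloc[k]
            intro_rows.append((row.chrom, int(row.start), int(row.end), row.window))
            in_w = (chroms == row.chrom) & (pos - 1 >= row.start) & (pos - 1 < row.end)
            idx = np.flatnonzero(in_w)
            if len(idx) == 0:
                continue
            for a in range(n_acc):
                # donor group independent of the accession's own group: the
                # foreign haplotype's presence carries no geographic signal
                donor = int(rng.integers(0, cfg.n_groups))
                f = gfreq[idx, donor]
                haps[idx, 2 * a] = (rng.random(len(idx)) < f).astype(np.int8)
                haps[idx, 2 * a + 1] = (rng.random(len(idx)) < f).astype(np.int8)
    intro = pd.DataFrame(intro_rows, columns=["chrom", "start", "end", "window"])

    # geography: group centroids on a circle, Gaussian scatter around them
    theta = 2 * np.pi * np.arange(cfg.n_groups) / cfg.n_groups
    cent_lat = 40.0 + 12.0 * np.sin(theta)
    cent_lon = 30.0 + 25.0 * np.cos(theta)
    lat = cent_lat[acc_group] + rng.normal(0, cfg.geo_noise_deg, n_acc)
    lon = cent_lon[acc_group] + rng.normal(0, cfg.geo_noise_deg, n_acc)

    ref = np.array(["A"] * n_sites, dtype=object)
    alt = np.array(["C"] * n_sites, dtype=object)
    meta = pd.DataFrame(
        {
            "accession": acc_ids,
            "group": [cfg.group_names[g] for g in acc_group],
            "panel": "landrace",
            "latitude": lat,
            "longitude": lon,
        }
    )
    panel = dict(zip(acc_ids, meta["panel"]))
    hp = PhasedHaplotypes(chroms, pos, ref, alt, haps, acc_ids, panel)
    return PanelSim(hp, meta, intro, gfreq, cfg)


@dataclass
class MosaicGenome:
    """A modern accession built as an IBS mosaic of landrace donors."""

    accession_id: str
    segments: pd.DataFrame  # chrom, start, end (bp, 0-based half-open), donor
    haps: np.ndarray        # n_sites x 2


def sim_modern_mosaics(
    panel: PanelSim,
    n_modern: int = 10,
    seg_len_mean: float = 1_500_000.0,
    founder_groups: tuple | None = None,
    seed: int | None = None,
    donors: list | None = None,
) -> list:
    """Build modern accessions as segment-wise copies of founder-group donors.

    Segment lengths are Exponential(``seg_len_mean``) bp; each segment copies
    the haplotype pair of one donor accession; adjacent segments have
    distinct donors.  ``donors`` restricts the donor pool explicitly (used to
    force a single-donor mosaic).
    """
    if seg_len_mean <= 0:
        raise ValueError("seg_len_mean must be positive")
    cfg = panel.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    founder_groups = founder_groups or cfg.modern_founder_groups
    if donors is None:
        donors = panel.metadata.loc[
            panel.metadata["group"].isin(founder_groups), "accession"
        ].tolist()
    if not donors:
        raise ValueError("no donor accessions in the founder groups")
    hp = panel.haps
    out = []
    for m in range(n_modern):
        name = f"MOD_{m:03d}"
        haps = np.zeros((hp.n_sites, 2), dtype=np.int8)
        rows = []
        for c in hp.chromosomes:
            in_c = hp.chrom == c
            start = 0
            prev = None
            while start < cfg.chrom_len_bp:
                length = max(1, int(rng.exponential(seg_len_mean)))
                end = min(start + length, cfg.chrom_len_bp)
                choices = [d for d in donors if d != prev] or donors
                donor = choices[rng.integers(len(choices))]
                di = hp.accession_ids.index(donor)
                seg_sites = in_c & (hp.pos - 1 >= start) & (hp.pos - 1 < end)
                haps[seg_sites] = hp.haps[np.ix_(seg_sites, [2 * di, 2 * di + 1])]
                rows.append((c, start, end, donor))
                prev = donor
                start = end
        out.append(MosaicGenome(name, pd.DataFrame(rows, columns=["chrom", "start", "end", "donor"]), haps))
    return out


def combine_mosaics(panel: PanelSim, mosaics: list) -> PhasedHaplotypes:
    """Stack landrace panel and modern mosaics into one phased container."""
    hp = panel.haps
    mod_haps = np.concatenate([m.haps for m in mosaics], axis=1)
    ids = hp.accession_ids + [m.accession_id for m in mosaics]
    panel_map = dict(hp.panel)
    panel_map.update({m.accession_id: "modern" for m in mosaics})
    return PhasedHaplotypes(
        hp.chrom, hp.pos, hp.ref, hp.alt,
        np.concatenate([hp.haps, mod_haps], axis=1), ids, panel_map,
    )


# ---------------------------------------------------------------------------
# meiosis machinery (Haldane model: Poisson crossovers, no interference)


def meiosis(pair: np.ndarray, cm: np.ndarray, chrom_index: np.ndarray,
            chrom_len_cm: np.ndarray, rng) -> np.ndarray:
    """One gamete from a pair of chromosome sets.

    ``pair`` is (2, n_loci); ``cm`` the genetic position of each locus on its
    chromosome; ``chrom_index`` maps each locus to 0..n_chrom-1;
    ``chrom_len_cm`` the map length per chromosome.  Crossover counts are
    Poisson(L/100) per chromosome with uniform positions.
    """
    n_chrom = len(chrom_len_cm)
    counts = rng.poisson(chrom_len_cm / 100.0)
    offsets = 1000.0 * np.arange(n_chrom)  # separate chromosomes on one axis
    xo = []
    for c in range(n_chrom):
        if counts[c]:
            xo.append(offsets[c] + rng.uniform(0, chrom_len_cm[c], counts[c]))
    xo = np.sort(np.concatenate(xo)) if xo else np.empty(0)
    glob = offsets[chrom_index] + cm
    n_before = np.searchsorted(xo, glob)
    start = rng.integers(0, 2, n_chrom)  # independent start strand per chromosome
    strand = (start[chrom_index] + n_before) % 2
    return pair[strand, np.arange(pair.shape[1])]


@dataclass
class RILPopulation:
    """Recombinant inbred lines plus founder-origin truth."""

    haps: np.ndarray            # n_sites x 2*n_ril alleles (0/1)
    origins: np.ndarray         # n_sites x 2*n_ril parental origin (0/1)
    chrom: np.ndarray
    pos: np.ndarray
    cm: np.ndarray              # genetic position per site
    ril_ids: list

    @property
    def n_ril(self) -> int:
        return len(self.ril_ids)

    def genotypes(self, ref, alt, panel: dict | None = None) -> GenotypeMatrix:
        a = self.haps[:, 0::2].astype(np.int16)
        b = self.haps[:, 1::2].astype(np.int16)
        return GenotypeMatrix(self.chrom, self.pos, ref, alt,
                              (a + b).astype(np.int8), self.ril_ids, panel or {})


def _prepare_map(chrom: np.ndarray, cm: np.ndarray):
    chrom = np.asarray(chrom, dtype=object)
    cm = np.asarray(cm, dtype=float)
    names = list(dict.fromkeys(chrom.tolist()))
    chrom_index = np.array([names.index(c) for c in chrom])
    lens = np.zeros(len(names))
    for i, c in enumerate(names):
        v = cm[chrom == c]
        if len(v) > 1 and not (np.diff(v) >= 0).all():
            raise ValueError(f"genetic map not monotone on {c}")
        lens[i] = v.max() if len(v) else 0.0
    return chrom_index, lens


def sim_rils(
    parent1: np.ndarray,
    parent2: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    cm: np.ndarray,
    n_ril: int = 100,
    n_selfing: int = 3,
    seed: int = 0,
) -> RILPopulation:
    """Biparental RILs by single-seed descent (F1 selfed ``n_selfing`` times).

    ``parent1``/``parent2`` are (n_sites, 2) phased parental haplotypes.
    Residual heterozygosity halves each selfing generation (12.5% expected
    at F4, i.e. three selfings).  Truth ``origins`` gives, per RIL haplotype
    and site, which parent the allele descends from.
    """
    chrom_index, lens = _prepare_map(chrom, cm)
    rng = np.random.default_rng(seed)
    n = len(pos)
    founder = np.stack([parent1.T, parent2.T])  # (2 parents, 2 haps, n)
    haps = np.zeros((n, 2 * n_ril), dtype=np.int8)
    origins = np.zeros((n, 2 * n_ril), dtype=np.int8)
    for r in range(n_ril):
        # founder-haplotype labels 0,1 (parent1) / 2,3 (parent2)
        g1 = meiosis(np.array([np.zeros(n, int), np.ones(n, int)]), cm, chrom_index, lens, rng)
        g2 = meiosis(np.array([2 * np.ones(n, int), 3 * np.ones(n, int)]), cm, chrom_index, lens, rng)
        ind = np.stack([g1, g2])
        for _ in range(n_selfing):
            a = meiosis(ind, cm, chrom_index, lens, rng)
            b = meiosis(ind, cm, chrom_index, lens, rng)
            ind = np.stack([a, b])
        for h in range(2):
            lab = ind[h]
            allele = founder[lab // 2, lab % 2, np.arange(n)]
            haps[:, 2 * r + h] = allele
            origins[:, 2 * r + h] = lab // 2
    ids = [f"RIL_{r:04d}" for r in range(n_ril)]
    return RILPopulation(haps, origins,
                         np.asarray(chrom, dtype=object), np.asarray(pos, np.int64),
                         np.asarray(cm, float), ids)


@dataclass
class NILFamily:
    """One BC2F2 near-isogenic derivation with its genome-wide truth."""

    target_chrom: int
    target_cm: float
    recurrent_fraction: float        # excluding the target interval
    recurrent_fraction_unlinked: float  # excluding the whole carrier chromosome
    donor_sib: np.ndarray            # (2, n_loci) origins, 0 recurrent / 1 donor


def _gametes_batch(pairs: np.ndarray, cm_one: np.ndarray, n_chrom: int, chrom_len_cm: float, rng) -> np.ndarray:
    """One gamete per individual for a batch (R, 2, n_loci) of genomes.

    Haldane model on ``n_chrom`` chromosomes that all share the locus grid
    ``cm_one``.  Vectorized over individuals and loci.
    """
    R = pairs.shape[0]
    L = len(cm_one)
    out = np.empty((R, n_chrom * L), dtype=pairs.dtype)
    for c in range(n_chrom):
        counts = rng.poisson(chrom_len_cm / 100.0, R)
        K = int(counts.max())
        if K > 0:
            pos = rng.uniform(0, chrom_len_cm, (R, K))
            pos[np.arange(K)[None, :] >= counts[:, None]] = np.inf
            n_before = (pos[:, :, None] <= cm_one[None, None, :]).sum(axis=1)
        else:
            n_before = np.zeros((R, L), dtype=int)
        start = rng.integers(0, 2, R)
        strand = (start[:, None] + n_before) % 2
        seg = pairs[:, :, c * L : (c + 1) * L]
        out[:, c * L : (c + 1) * L] = np.where(strand == 0, seg[:, 0, :], seg[:, 1, :])
    return out


def sim_bc_nils(
    n_chrom: int = 21,
    chrom_len_cm: float = 150.0,
    loci_per_chrom: int = 151,
    n_families: int = 100,
    n_backcross: int = 2,
    target_interval_cm: float = 20.0,
    ril_selfing: int = 3,
    ril_pool: int = 24,
    seed: int = 0,
) -> list:
    """Simulate BC2F2 NIL families from selected F4 RIL donors.

    The derivation mirrors the crossing scheme: per family, F4 RILs
    (donor x recurrent, advanced by single-seed descent) are screened until
    ``ril_pool`` candidates homozygous for the donor allele at the target
    locus are found, and the candidate carrying the most recurrent-parent
    alleles outside the target interval is selected.  That RIL is crossed
    to the recurrent parent ``n_backcross`` times with marker-assisted
    retention of the donor allele at the target, selfed once, and a sib
    homozygous donor at the target is kept.  Genome-wide recurrent-parent
    fraction is recorded, both excluding the marker-selected target
    interval and excluding the whole carrier chromosome (the unlinked
    genome).  ``ril_pool=1`` disables background selection (a random
    donor-carrying RIL).  Origins: 0 = recurrent parent, 1 = donor parent.
    """
    if n_backcross < 0:
        raise ValueError("n_backcross must be >= 0")
    if ril_pool < 1:
        raise ValueError("ril_pool must be >= 1")
    rng = np.random.default_rng(seed)
    cm_one = np.linspace(0.0, chrom_len_cm, loci_per_chrom)
    n = n_chrom * loci_per_chrom
    chrom_index = np.repeat(np.arange(n_chrom), loci_per_chrom)
    target_chrom = 0
    target_cm = chrom_len_cm / 2.0
    target_idx = int(np.argmin(np.abs(cm_one - target_cm)))  # locus on chrom 0
    half = target_interval_cm / 2.0
    in_interval = (chrom_index == target_chrom) & (np.abs(np.tile(cm_one, n_chrom) - target_cm) <= half)
    in_interval &= chrom_index == target_chrom
    on_carrier = chrom_index == target_chrom
    if not in_interval.any():
        raise ValueError("target interval contains no locus")

    def gb(pairs):
        return _gametes_batch(pairs, cm_one, n_chrom, chrom_len_cm, rng)

    out = []
    batch = max(1, min(n_families, 4000 // max(ril_pool, 1)))
    done = 0
    while done < n_families:
        nb = min(batch, n_families - done)
        # --- candidate F4 RILs, homozygous donor at target
        need = nb * ril_pool
        cand = np.empty((need, 2, n), dtype=np.int8)
        got = 0
        while got < need:
            draw = int((need - got) * 2.6) + 8
            ind = np.broadcast_to(
                np.stack([np.ones(n, np.int8), np.zeros(n, np.int8)]), (draw, 2, n)
            ).copy()
            for _ in range(ril_selfing):
                ind = np.stack([gb(ind), gb(ind)], axis=1)
            ok = (ind[:, 0, target_idx] == 1) & (ind[:, 1, target_idx] == 1)
            take = min(int(ok.sum()), need - got)
            cand[got : got + take] = ind[ok][:take]
            got += take
        # per family, pick the candidate with max recurrent background
        cand = cand.reshape(nb, ril_pool, 2, n)
        donor_frac = cand[:, :, :, ~in_interval].astype(np.float32).mean(axis=(2, 3))
        best = donor_frac.argmin(axis=1)
        ril = cand[np.arange(nb), best]  # (nb, 2, n)
        # --- backcrosses with marker-assisted retention of the donor allele
        ind = ril
        for _ in range(n_backcross):
            g = gb(ind)
            bad = g[:, target_idx] != 1
            while bad.any():
                g[bad] = gb(ind[bad])
                bad = g[:, target_idx] != 1
            ind = np.stack([g, np.zeros_like(g)], axis=1)
        # --- self once; select sibs homozygous donor at the target
        sib = np.empty_like(ind)
        for h in range(2):
            g = gb(ind)
            bad = g[:, target_idx] != 1
            while bad.any():
                g[bad] = gb(ind[bad])
                bad = g[:, target_idx] != 1
            sib[:, h] = g
        rec = 1.0 - sib.astype(np.float32).mean(axis=1)  # (nb, n) recurrent fraction
        frac = rec[:, ~in_interval].mean(axis=1)
        frac_unlinked = rec[:, ~on_carrier].mean(axis=1)
        for i in range(nb):
            out.append(NILFamily(target_chrom, target_cm, float(frac[i]),
                                 float(frac_unlinked[i]), sib[i]))
        done += nb
    return out


def sim_sequences(
    haps: PhasedHaplotypes,
    chrom_len_bp: int,
    gc: float = 0.46,
    seed: int = 0,
    k: int = 31,
):
    """Reference and per-accession sequences realizing the panel's alleles.

    The reference is random non-repetitive-ish sequence at the target GC;
    per-site REF is the reference base and ALT a different base (the
    returned PhasedHaplotypes carries the consistent alleles).  Accession
    sequences are a haploid consensus applying haplotype 0's alleles.  Sites
    closer than ``k`` bp to a chromosome end are relocated inward with a
    warning so every k-mer window stays well formed.

    Returns (reference: {chrom: str}, accessions: {acc: {chrom: str}},
    haps with updated ref/alt and possibly relocated positions).
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    reference = {}
    for c in haps.chromosomes:
        reference[c] = "".join(rng.choice(_BASE, size=chrom_len_bp, p=p))
    pos = haps.pos.copy()
    for c in haps.chromosomes:
        in_c = haps.chrom == c
        bad = in_c & ((pos < k) | (pos > chrom_len_bp - k))
        if bad.any():
            logger.warning("sim_sequences: relocating %d sites near %s ends", bad.sum(), c)
            pos[bad] = np.clip(pos[bad], k, chrom_len_bp - k)
            pos[in_c] = np.sort(pos[in_c])
    ref = np.array([reference[c][int(q) - 1] for c, q in zip(haps.chrom, pos)], dtype=object)
    alt = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in ref], dtype=object
    )
    out_haps = PhasedHaplotypes(haps.chrom, pos, ref, alt, haps.haps,
                                haps.accession_ids, dict(haps.panel))
    accessions = {}
    for i, acc in enumerate(haps.accession_ids):
        seqs = {}
        h0 = haps.haps[:, 2 * i]
        for c in haps.chromosomes:
            in_c = haps.chrom == c
            s = list(reference[c])
            for q, a, alt_b in zip(pos[in_c], h0[in_c], alt[in_c]):
                if a == 1:
                    s[int(q) - 1] = alt_b
            seqs[c] = "".join(s)
        accessions[acc] = seqs
    return reference, accessions, out_haps


def sim_gene_depths(
    genes: pd.DataFrame,
    copy_numbers: pd.DataFrame,
    gc_bias,
    acc_depth,
    duplicate_groups: list | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene, per-accession read depths with GC bias and lognormal noise.

    depth = acc_depth x copy_number x gc_bias(gene GC) x LogNormal(0, sd).
    ``genes`` needs columns gene, gc; ``copy_numbers`` is gene x accession
    (true copies relative to single copy = 1).  Genes in a duplicate group
    share reads: the group's summed true depth is split evenly between
    members, so only the collapsed group total is well defined.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(acc_depth):
        acc_depth = {a: float(acc_depth) for a in copy_numbers.columns}
    if any(v < 0 for v in acc_depth.values()):
        raise ValueError("negative mean coverage")
    gc = genes.set_index("gene")["gc"]
    rows = []
    depth = {}
    for acc in copy_numbers.columns:
        d = (
            acc_depth[acc]
            * copy_numbers[acc].astype(float)
            * np.array([gc_bias(gc[g]) for g in copy_numbers.index])
        )
        depth[acc] = d * rng.lognormal(0.0, noise_sd, len(d))
    depth = pd.DataFrame(depth, index=copy_numbers.index)
    for grp in duplicate_groups or []:
        total = depth.loc[grp].sum(axis=0)
        for g in grp:
            depth.loc[g] = total / len(grp)
    for g in depth.index:
        for acc in depth.columns:
            rows.append((g, acc, float(depth.loc[g, acc])))
    return pd.DataFrame(rows, columns=["gene", "accession", "depth"])


def sim_traits(
    lines: list,
    environments: list,
    line_effects: dict | None = None,
    interaction_rank: int = 1,
    interaction_scale: float = 1.0,
    error_sd: float = 0.5,
    n_rep: int = 3,
    grand_mean: float = 100.0,
    env_effect_sd: float = 2.0,
    trait: str = "trait",
    seed: int = 0,
):
    """Plot-level trait values with additive structure plus G x E interaction.

    value = grand mean + line effect + environment effect + rank-limited
    interaction + replicate noise.  Returns (long-format trait table, truth
    dict with the generating components).
    """
    if interaction_rank >= min(len(lines), len(environments)):
        raise ValueError("interaction_rank must be < min(#lines, #environments)")
    if n_rep < 2:
        logger.warning("sim_traits: <2 replicates limits ANOVA use")
    rng = np.random.default_rng(seed)
    nl, ne = len(lines), len(environments)
    if line_effects is None:
        le = rng.normal(0, 3.0, nl)
        le -= le.mean()
        line_effects = dict(zip(lines, le))
    le = np.array([line_effects[l] for l in lines])
    ee = rng.normal(0, env_effect_sd, ne)
    ee -= ee.mean()
    inter = np.zeros((nl, ne))
    for _ in range(interaction_rank):
        u = rng.normal(0, 1, nl)
        v = rng.normal(0, 1, ne)
        u -= u.mean()
        v -= v.mean()
        inter += interaction_scale * np.outer(u, v)
    rows = []
    for i, l in enumerate(lines):
        for j, e in enumerate(environments):
            mu = grand_mean + le[i] + ee[j] + inter[i, j]
            for r in range(n_rep):
                rows.append((l, e, r + 1, trait, mu + rng.normal(0, error_sd)))
    table = pd.DataFrame(rows, columns=["line", "environment", "replicate", "trait", "value"])
    truth = {
        "grand_mean": grand_mean,
        "line_effects": dict(zip(lines, le)),
        "env_effects": dict(zip(environments, ee)),
        "interaction": pd.DataFrame(inter, index=lines, columns=environments),
    }
    return table, truth
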