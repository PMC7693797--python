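"""Ground-truth simulators: founder panels, Wright-Fisher drift, pedigrees,
gene-dropping with recorded IBD tracts, and planted selective sweeps.

Everything is deterministic under the configured seed. Truth (pedigree F,
IBD-homozygous tracts, sweep coordinates) is recorded before any missingness
or genotyping error is injected, so recovery tests can separate algorithmic
error from simulated noise. Crossovers follow a Poisson process with no
interference; there is no mutation during transmission.

Desk-scale defaults: 2 chromosomes x 50 Mb carrying 5,000 SNPs in total,
an effective size of 100 diploids drifting for 200 generations, founder
allele frequencies uniform on [0.05, 0.5].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, SampleRecord, SNPRecord
from .selection import HaplotypePanel


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_snps: int = 5_000
    n_chrom: int = 2
    chrom_length_bp: int = 50_000_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    ne_true: int = 100
    n_generations: int = 200
    recomb_cM_per_Mb: float = 1.0
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0

    def __post_init__(self):
        for rate in (self.missing_rate, self.genotype_error_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def morgans_per_chrom(self) -> float:
        return self.chrom_length_bp * self.recomb_cM_per_Mb / 1e8


@dataclass
class SweepTruth:
    chrom: str
    start_bp: int
    end_bp: int
    carrier_fraction: float
    carrier_haplotypes: list[int]
    core_snp_id: str


@dataclass
class TruthRecord:
    f_pedigree: dict[str, float] = field(default_factory=dict)
    ibd_tracts: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    sweep: SweepTruth | None = None

    def to_json(self, path) -> None:
        payload = {
            "f_pedigree": self.f_pedigree,
            "ibd_tracts": self.ibd_tracts,
            "sweep": None if self.sweep is None else vars(self.sweep),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def snp_map(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[SNPRecord]:
    """Evenly sized per-chromosome SNP maps with uniform random positions."""
    rng = rng or np.random.default_rng(cfg.seed)
    per_chrom = np.full(cfg.n_chrom, cfg.n_snps // cfg.n_chrom)
    per_chrom[: cfg.n_snps % cfg.n_chrom] += 1
    snps: list[SNPRecord] = []
    k = 0
    for c in range(cfg.n_chrom):
        m = per_chrom[c]
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp + 1, size=m))
        while pos.size < m:  # top up rare duplicate draws
            extra = rng.integers(1, cfg.chrom_length_bp + 1, size=m - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        for p in pos:
            snps.append(SNPRecord(f"rs{k}", str(c + 1), int(p), "A", "G"))
            k += 1
    return snps


def sim_founder_haplotypes(cfg: SimConfig, n_haplotypes: int) -> HaplotypePanel:
    """Independent sites with allele frequencies drawn from the MAF law."""
    rng = np.random.default_rng(cfg.seed)
    snps = snp_map(cfg, rng)
    freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=len(snps))
    hap = (rng.random((n_haplotypes, len(snps))) < freqs).astype(np.uint8)
    return HaplotypePanel(snps, hap)


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulation
# ---------------------------------------------------------------------------

def _gamete_mask(
    positions: np.ndarray, length_bp: int, morgans: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask choosing parental haplotype A (False) or B (True) per SNP."""
    n_x = rng.poisson(morgans)
    phase = rng.integers(0, 2)
    if n_x == 0:
        return np.full(positions.size, bool(phase))
    breaks = np.sort(rng.integers(1, length_bp + 1, size=n_x))
    crossings = np.searchsorted(breaks, positions, side="left")
    return ((crossings + phase) % 2).astype(bool)


def sim_wright_fisher(
    founders: HaplotypePanel,
    cfg: SimConfig,
    n_sample_haplotypes: int | None = None,
) -> HaplotypePanel:
    """Random-mating diploid population of size ne_true for n_generations.

    The founder panel seeds the initial 2*Ne haplotypes (recycled if short);
    each offspring draws two distinct parents and one recombinant gamete from
    each. Returns a sample of the final generation's haplotypes.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    chroms = founders.chromosomes()
    positions = founders.positions()
    blocks = [
        (np.flatnonzero(chroms == c)) for c in dict.fromkeys(chroms)
    ]
    n_hap = 2 * cfg.ne_true
    idx = np.resize(np.arange(founders.n_haplotypes), n_hap)
    pop = founders.haplotypes[idx].copy()
    for _ in range(cfg.n_generations):
        new = np.empty_like(pop)
        for child in range(cfg.ne_true):
            sire, dam = rng.choice(cfg.ne_true, size=2, replace=False)
            for h, parent in enumerate((sire, dam)):
                gamete = np.empty(positions.size, dtype=np.uint8)
                for block in blocks:
                    mask = _gamete_mask(
                        positions[block], cfg.chrom_length_bp,
                        cfg.morgans_per_chrom, rng,
                    )
                    a = pop[2 * parent, block]
                    b = pop[2 * parent + 1, block]
                    gamete[block] = np.where(mask, b, a)
                new[2 * child + h] = gamete
        pop = new
    if n_sample_haplotypes is not None:
        take = rng.choice(n_hap, size=n_sample_haplotypes, replace=False)
        # keep haplotype pairs together when an even sample is requested
        if n_sample_haplotypes % 2 == 0:
            inds = rng.choice(cfg.ne_true, size=n_sample_haplotypes // 2, replace=False)
            take = np.stack([2 * inds, 2 * inds + 1], axis=1).reshape(-1)
        pop = pop[take]
    return HaplotypePanel(founders.snps, pop)


# ---------------------------------------------------------------------------
# Pedigree designs
# ---------------------------------------------------------------------------

def _kinship_f(ids, sire, dam) -> dict[str, float]:
    """Independent path-counting truth: F_i = coancestry(sire_i, dam_i)."""
    index = {ind: k for k, ind in enumerate(ids)}
    memo: dict[tuple[int, int], float] = {}

    def kin(a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        if a < b:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        if a == b:
            val = 0.5 * (1 + kin(sire[a], dam[a]))
        else:  # a is the younger (larger topological index)
            val = 0.5 * (kin(sire[a], b) + kin(dam[a], b))
        memo[key] = val
        return val

    return {ids[i]: kin(sire[i], dam[i]) for i in range(len(ids))}


def _design_rows(design: str, rng: np.random.Generator, **kw):
    if design == "full_sib":
        n_families = kw.get("n_families", 1)
        if n_families == 1:
            return [
                ("A", None, None, "male"), ("B", None, None, "female"),
                ("S1", "A", "B", "male"), ("S2", "A", "B", "female"),
                ("P", "S1", "S2", "unknown"),
            ]
        rows = []
        for f in range(n_families):
            rows += [
                (f"A{f}", None, None, "male"), (f"B{f}", None, None, "female"),
                (f"S1_{f}", f"A{f}", f"B{f}", "male"),
                (f"S2_{f}", f"A{f}", f"B{f}", "female"),
                (f"P{f}", f"S1_{f}", f"S2_{f}", "unknown"),
            ]
        return rows
    if design == "half_sib":
        return [
            ("A", None, None, "male"),
            ("B", None, None, "female"), ("C", None, None, "female"),
            ("H1", "A", "B", "male"), ("H2", "A", "C", "female"),
            ("P", "H1", "H2", "unknown"),
        ]
    if design == "parent_offspring":
        return [
            ("A", None, None, "male"), ("B", None, None, "female"),
            ("C", "A", "B", "female"), ("P", "A", "C", "unknown"),
        ]
    if design == "random":
        n_sires = kw.get("n_sires", 2)
        n_dams = kw.get("n_dams", 10)
        n_gen = kw.get("n_gen", 4)
        rows = [(f"s0_{k}", None, None, "male") for k in range(n_sires)]
        rows += [(f"d0_{k}", None, None, "female") for k in range(n_dams)]
        males = [r[0] for r in rows if r[3] == "male"]
        females = [r[0] for r in rows if r[3] == "female"]
        for g in range(1, n_gen + 1):
            new_m, new_f = [], []
            for k in range(n_sires):
                name = f"s{g}_{k}"
                rows.append((name, rng.choice(males), rng.choice(females), "male"))
                new_m.append(name)
            for k in range(n_dams):
                name = f"d{g}_{k}"
                rows.append((name, rng.choice(males), rng.choice(females), "female"))
                new_f.append(name)
            males, females = new_m, new_f
        return rows
    raise ValueError(f"unknown design {design!r}")


def sim_pedigree(design: str, seed: int = 0, **kw):
    """Named pedigree designs with analytically known truth F.

    Returns (DataFrame with id/sire/dam/sex/birthdate, TruthRecord). The
    full_sib and parent_offspring probands have F = 0.25, half_sib 0.125;
    random designs carry F from the module's own path-counting oracle.
    """
    rng = np.random.default_rng(seed)
    rows = _design_rows(design, rng, **kw)
    ids = [r[0] for r in rows]
    index = {ind: k for k, ind in enumerate(ids)}
    sire = np.array([index.get(r[1], -1) if r[1] else -1 for r in rows])
    dam = np.array([index.get(r[2], -1) if r[2] else -1 for r in rows])
    truth = TruthRecord(f_pedigree=_kinship_f(ids, sire, dam))
    year0 = 2000
    depth = np.zeros(len(ids), dtype=int)
    for i in range(len(ids)):
        ps = [p for p in (sire[i], dam[i]) if p >= 0]
        depth[i] = 1 + max((depth[p] for p in ps), default=-1)
    df = pd.DataFrame(
        {
            "id": ids,
            "sire": [r[1] or "" for r in rows],
            "dam": [r[2] or "" for r in rows],
            "sex": [r[3] for r in rows],
            "birthdate": [f"{year0 + int(d)}-01-01" for d in depth],
        }
    )
    return df, truth


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def _transmit(
    track_a: list[tuple[int, int]],
    track_b: list[tuple[int, int]],
    length_bp: int,
    morgans: float,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """One gamete from a pair of labelled tracks: Poisson crossovers, no
    interference. Tracks are [(start_bp, founder_hap_label), ...]."""
    n_x = rng.poisson(morgans)
    cuts = sorted(int(c) for c in rng.integers(1, length_bp + 1, size=n_x)) if n_x else []
    phase = int(rng.integers(0, 2))
    bounds = [1] + [c for c in cuts if 1 < c <= length_bp] + [length_bp + 1]
    out: list[tuple[int, int]] = []
    tracks = (track_a, track_b)
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if lo >= hi:
            continue
        track = tracks[(phase + k) % 2]
        for idx, (start, label) in enumerate(track):
            seg_end = track[idx + 1][0] if idx + 1 < len(track) else length_bp + 1
            s = max(start, lo)
            if s < min(seg_end, hi):
                out.append((s, label))
    # consecutive entries tile the chromosome in order; collapse equal labels
    merged: list[tuple[int, int]] = []
    for start, label in out:
        if merged and merged[-1][1] == label:
            continue
        merged.append((start, label))
    return merged


def _track_labels_at(track: list[tuple[int, int]], positions: np.ndarray) -> np.ndarray:
    starts = np.array([s for s, _ in track])
    labels = np.array([lab for _, lab in track])
    idx = np.searchsorted(starts, positions, side="right") - 1
    return labels[idx]


def _ibd_tracts(
    track_a: list[tuple[int, int]],
    track_b: list[tuple[int, int]],
    length_bp: int,
) -> list[tuple[int, int]]:
    """Maximal intervals where both tracks carry the same founder label."""
    bounds = sorted({s for s, _ in track_a} | {s for s, _ in track_b} | {length_bp + 1})
    out: list[tuple[int, int]] = []
    pos = np.array(bounds[:-1])
    la = _track_labels_at(track_a, pos)
    lb = _track_labels_at(track_b, pos)
    for k in range(len(pos)):
        lo, hi = bounds[k], bounds[k + 1] - 1
        if la[k] == lb[k]:
            if out and out[-1][1] == lo - 1:
                out[-1] = (out[-1][0], hi)
            else:
                out.append((lo, hi))
    return out


def gene_drop(
    pedigree: pd.DataFrame,
    founder_panel: HaplotypePanel,
    cfg: SimConfig,
) -> tuple[GenotypeDataset, TruthRecord]:
    """Drop uniquely labelled founder chromosomes down a pedigree.

    Every unknown-parent slot consumes one fresh founder haplotype from the
    panel. Mendelian transmission uses Poisson crossovers; IBD-homozygous
    tracts (both chromosomes carrying the same founder label) are recorded
    as truth before missingness/error are applied to the emitted dosages.
    """
    from .pedigree import validate_pedigree

    ped = validate_pedigree(pedigree)
    rng = np.random.default_rng(cfg.seed + 2)
    chroms = founder_panel.chromosomes()
    positions = founder_panel.positions()
    chrom_names = list(dict.fromkeys(chroms))
    blocks = {c: np.flatnonzero(chroms == c) for c in chrom_names}
    n_slots = int(np.sum(ped.sire == -1) + np.sum(ped.dam == -1))
    if founder_panel.n_haplotypes < n_slots:
        raise ValueError(
            f"founder panel has {founder_panel.n_haplotypes} haplotypes; "
            f"{n_slots} unknown-parent slots require one each"
        )
    next_hap = 0
    # genome[i][chrom] = (track_sire_side, track_dam_side)
    genome: list[dict[str, tuple[list, list]]] = []
    truth = TruthRecord(f_pedigree=_kinship_f(ped.ids, ped.sire, ped.dam))
    for i in range(ped.n):
        sides = []
        for parent in (ped.sire[i], ped.dam[i]):
            if parent == -1:
                label = next_hap
                next_hap += 1
                sides.append({c: [(1, label)] for c in chrom_names})
            else:
                tracks = {}
                for c in chrom_names:
                    a, b = genome[parent][c]
                    tracks[c] = _transmit(
                        a, b, cfg.chrom_length_bp, cfg.morgans_per_chrom, rng
                    )
                sides.append(tracks)
        genome.append({c: (sides[0][c], sides[1][c]) for c in chrom_names})
        tracts = []
        for c in chrom_names:
            a, b = genome[i][c]
            tracts.extend((c, lo, hi) for lo, hi in _ibd_tracts(a, b, cfg.chrom_length_bp))
        truth.ibd_tracts[ped.ids[i]] = tracts

    dosage = np.empty((ped.n, founder_panel.n_snps), dtype=np.int8)
    for i in range(ped.n):
        for c in chrom_names:
            block = blocks[c]
            pos = positions[block]
            a, b = genome[i][c]
            ha = founder_panel.haplotypes[_track_labels_at(a, pos), block]
            hb = founder_panel.haplotypes[_track_labels_at(b, pos), block]
            dosage[i, block] = ha + hb
    if cfg.genotype_error_rate > 0:
        err = rng.random(dosage.shape) < cfg.genotype_error_rate
        shift = rng.integers(1, 3, size=dosage.shape)
        dosage = np.where(err, (dosage + shift) % 3, dosage).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = MISSING
    samples = [
        SampleRecord(ped.ids[i], "sim", str(ped.sex[i])) for i in range(ped.n)
    ]
    ds = GenotypeDataset(founder_panel.snps, samples, dosage)
    return ds, truth


def ibd_fraction(truth: TruthRecord, sample_id: str, cfg: SimConfig) -> float:
    """Fraction of the simulated genome inside recorded IBD tracts."""
    total = sum(hi - lo + 1 for _, lo, hi in truth.ibd_tracts[sample_id])
    return total / (cfg.n_chrom * cfg.chrom_length_bp)


# ---------------------------------------------------------------------------
# Selective sweeps
# ---------------------------------------------------------------------------

def plant_sweep(
    panel: HaplotypePanel,
    chrom: str,
    center_bp: int,
    length_bp: int,
    carrier_fraction: float,
    seed: int = 0,
) -> tuple[HaplotypePanel, TruthRecord]:
    """Overwrite a region with one shared haplotype in a random carrier set.

    The region [center - L/2, center + L/2] must fit on the chromosome; the
    core SNP nearest the center carries the derived allele on every carrier.
    """
    if not 0 < carrier_fraction < 1:
        raise ValueError("carrier_fraction must lie in (0, 1)")
    start = center_bp - length_bp // 2
    end = center_bp + length_bp // 2
    chrom_pos = np.array(
        [s.pos_bp for s in panel.snps if s.chrom == chrom], dtype=np.int64
    )
    if chrom_pos.size == 0:
        raise ValueError(f"no SNPs on chromosome {chrom}")
    if start < 1 or center_bp > int(chrom_pos.max()):
        raise ValueError("sweep region exceeds the chromosome")
    rng = np.random.default_rng(seed)
    in_region = np.array(
        [s.chrom == chrom and start <= s.pos_bp <= end for s in panel.snps]
    )
    if not in_region.any():
        raise ValueError("sweep region contains no SNPs")
    region_idx = np.flatnonzero(in_region)
    k = int(round(carrier_fraction * panel.n_haplotypes))
    k = max(1, min(k, panel.n_haplotypes - 1))
    carriers = np.sort(rng.choice(panel.n_haplotypes, size=k, replace=False))
    hap = panel.haplotypes.copy()
    template = hap[carriers[0], region_idx].copy()
    region_pos = np.array([panel.snps[j].pos_bp for j in region_idx])
    core_local = int(np.argmin(np.abs(region_pos - center_bp)))
    template[core_local] = 1
    hap[np.ix_(carriers, region_idx)] = template
    swept = HaplotypePanel(panel.snps, hap, panel.sample_ids)
    truth = TruthRecord(
        sweep=SweepTruth(
            chrom=chrom,
            start_bp=int(start),
            end_bp=int(end),
            carrier_fraction=carrier_fraction,
            carrier_haplotypes=carriers.tolist(),
            core_snp_id=panel.snps[region_idx[core_local]].snp_id,
        )
    )
    return swept, truth


def panel_to_dataset(
    panel: HaplotypePanel, population: str = "sim"
) -> GenotypeDataset:
    """Pair consecutive haplotypes into diploid dosage genotypes."""
    if panel.n_haplotypes % 2:
        raise ValueError("odd number of haplotypes")
    n_ind = panel.n_haplotypes // 2
    dosage = (
        panel.haplotypes[0::2].astype(np.int8) + panel.haplotypes[1::2].astype(np.int8)
    )
    samples = [SampleRecord(f"ind{i}", population) for i in range(n_ind)]
    return GenotypeDataset(panel.snps, samples, dosage)
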