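"""Read, write, merge, QC-filter and subsample SNP-array genotype panels.

The central container is :class:`GenotypeDataset`: an ordered SNP map, an
ordered sample sheet with breed labels, and a samples x SNPs dosage matrix
counting copies of ``allele_a2`` (0/1/2, with -1 for a missing call).
Binary PLINK 1.9 triplets (.bed/.bim/.fam, SNP-major) and text .ped/.map
are supported natively.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1.9, SNP-major
# 2-bit .bed code -> dosage of allele_a2 (00 hom a1, 01 missing, 10 het, 11 hom a2)
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}

_NON_AUTOSOMES = {"X", "Y", "XY", "MT", "M"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "0": "0"}

SEX_TO_PLINK = {"male": 1, "female": 2, "unknown": 0}
PLINK_TO_SEX = {1: "male", 2: "female"}


class FormatError(ValueError):
    """Malformed input file (bad magic bytes, unparsable records)."""


class IntegrityError(ValueError):
    """Internally inconsistent dataset (dimension or key mismatches)."""


class IncompatibleAlleleError(ValueError):
    """Allele pairs for a shared SNP cannot be reconciled across datasets."""


@dataclass(frozen=True)
class SNPRecord:
    snp_id: str
    chrom: str
    pos_bp: int
    allele_a1: str
    allele_a2: str


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    population: str = "pop"
    sex: str = "unknown"


@dataclass
class QCReport:
    n_snps_in: int
    n_samples_in: int
    n_non_autosomal_removed: int
    n_low_callrate_snps_removed: int
    n_low_callrate_samples_removed: int
    n_snps_out: int
    n_samples_out: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, v) for k, v in dataclasses.asdict(self).items()],
            columns=["step", "count"],
        )


class GenotypeDataset:
    """Samples x SNPs dosage matrix plus marker map and sample sheet."""

    def __init__(
        self,
        snps: Sequence[SNPRecord],
        samples: Sequence[SampleRecord],
        dosage: np.ndarray,
    ):
        self.snps = list(snps)
        self.samples = list(samples)
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(self.samples), len(self.snps)):
            raise IntegrityError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise IntegrityError("dosage entries must be in {0,1,2,MISSING}")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise IntegrityError("snp_id values must be unique")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise IntegrityError("sample_id values must be unique")
        self.dosage = dosage

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def populations(self) -> list[str]:
        """Distinct breed labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    def population_mask(self, population: str) -> np.ndarray:
        mask = np.array([s.population == population for s in self.samples])
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        return mask

    def positions(self) -> np.ndarray:
        return np.array([s.pos_bp for s in self.snps], dtype=np.int64)

    def chromosomes(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps])

    def take(self, sample_idx=None, snp_idx=None) -> "GenotypeDataset":
        """Subset by integer indices, preserving order of the index arrays."""
        sample_idx = (
            np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        )
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            [self.snps[i] for i in snp_idx],
            [self.samples[i] for i in sample_idx],
            self.dosage[np.ix_(sample_idx, snp_idx)],
        )

    def sort_by_position(self) -> "GenotypeDataset":
        order = sorted(
            range(self.n_snps), key=lambda i: (_chrom_key(self.snps[i].chrom), self.snps[i].pos_bp)
        )
        return self.take(snp_idx=order)

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.snps == other.snps
            and self.samples == other.samples
            and np.array_equal(self.dosage, other.dosage)
        )


def _chrom_key(chrom: str):
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


def is_autosome(chrom: str) -> bool:
    return chrom.upper() not in _NON_AUTOSOMES


# ---------------------------------------------------------------------------
# PLINK binary triplet
# ---------------------------------------------------------------------------

def read_plink(path_prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK 1.9 .bed/.bim/.fam triplet (SNP-major).

    Dosage is coded as copies of ``allele_a2`` (the second .bim allele);
    the PLINK missing code maps to :data:`MISSING`. SNP order follows .bim.
    """
    prefix = Path(path_prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    snps = [
        SNPRecord(r.snp_id, r.chrom, int(r.pos), r.a1, r.a2) for r in bim.itertuples()
    ]
    samples = [
        SampleRecord(r.iid, r.fid, PLINK_TO_SEX.get(int(r.sex), "unknown"))
        for r in fam.itertuples()
    ]
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK 1.9)")
    n_samples, n_snps = len(samples), len(snps)
    bytes_per_snp = (n_samples + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * n_snps:
        raise IntegrityError(
            f"{prefix}.bed: {body.size} body bytes, expected "
            f"{bytes_per_snp * n_snps} for {n_samples} samples x {n_snps} SNPs"
        )
    dosage = np.empty((n_samples, n_snps), dtype=np.int8)
    if n_snps:
        mat = body.reshape(n_snps, bytes_per_snp)
        # sample i lives in byte i//4 of each SNP row, at bits (i%4)*2
        idx = np.arange(n_samples)
        byte_of = idx // 4
        shift_of = (idx % 4) * 2
        codes = (mat[:, byte_of] >> shift_of[None, :]) & 0b11
        dosage = _CODE_TO_DOSAGE[codes].T.copy()
    return GenotypeDataset(snps, samples, dosage)


def write_plink(ds: GenotypeDataset, path_prefix: str | Path) -> None:
    """Write a bit-exact PLINK 1.9 .bed/.bim/.fam triplet; inverse of read_plink."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in ds.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}\t{s.allele_a1}\t{s.allele_a2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in ds.samples:
            fh.write(f"{s.population} {s.sample_id} 0 0 {SEX_TO_PLINK[s.sex]} -9\n")
    n_samples = ds.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    codes = np.zeros((ds.n_snps, n_samples), dtype=np.uint8)
    for dose, code in _DOSAGE_TO_CODE.items():
        codes[(ds.dosage == dose).T] = code
    padded = np.zeros((ds.n_snps, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n_samples] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# Text .ped/.map
# ---------------------------------------------------------------------------

def write_ped_map(ds: GenotypeDataset, path_prefix: str | Path) -> None:
    prefix = Path(path_prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for s in ds.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, samp in enumerate(ds.samples):
            fields = [samp.population, samp.sample_id, "0", "0",
                      str(SEX_TO_PLINK[samp.sex]), "-9"]
            for j, snp in enumerate(ds.snps):
                g = ds.dosage[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [snp.allele_a1] * (2 - g) + [snp.allele_a2] * g
            fh.write(" ".join(fields) + "\n")


def read_ped_map(path_prefix: str | Path) -> GenotypeDataset:
    prefix = Path(path_prefix)
    mp = pd.read_csv(
        prefix.with_suffix(".map"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str, "snp_id": str},
    )
    samples, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            fid, iid, _, _, sex = parts[:5]
            samples.append(SampleRecord(iid, fid, PLINK_TO_SEX.get(int(sex), "unknown")))
            rows.append(parts[6:])
    n_snps = len(mp)
    # infer alleles per SNP from observed calls (a2 = last distinct allele seen)
    alleles: list[list[str]] = [[] for _ in range(n_snps)]
    for row in rows:
        for j in range(n_snps):
            for a in row[2 * j : 2 * j + 2]:
                if a != "0" and a not in alleles[j]:
                    alleles[j].append(a)
    snps = []
    for j, r in enumerate(mp.itertuples()):
        obs = sorted(alleles[j])
        a1 = obs[0] if obs else "0"
        a2 = obs[1] if len(obs) > 1 else "0"
        snps.append(SNPRecord(r.snp_id, r.chrom, int(r.pos), a1, a2))
    dosage = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, snp in enumerate(snps):
            pair = row[2 * j : 2 * j + 2]
            if "0" in pair:
                continue
            dosage[i, j] = sum(a == snp.allele_a2 for a in pair)
    return GenotypeDataset(snps, samples, dosage)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def _reconcile(ref: SNPRecord, other: SNPRecord) -> str:
    """Return 'same', 'swap', 'flip' or 'flip_swap'; raise if irreconcilable.

    Strand flips (A<->T, C<->G complement of both alleles) are attempted
    before declaring incompatibility, but never for strand-ambiguous A/T or
    C/G SNPs, where a flip is indistinguishable from a swap.
    """
    if (ref.chrom, ref.pos_bp) != (other.chrom, other.pos_bp):
        raise IncompatibleAlleleError(
            f"SNP {ref.snp_id}: conflicting coordinates "
            f"{ref.chrom}:{ref.pos_bp} vs {other.chrom}:{other.pos_bp}"
        )
    pair_ref = (ref.allele_a1, ref.allele_a2)
    pair_other = (other.allele_a1, other.allele_a2)
    if pair_other == pair_ref:
        return "same"
    if pair_other == pair_ref[::-1]:
        return "swap"
    ambiguous = {frozenset("AT"), frozenset("CG")}
    if frozenset(pair_ref) in ambiguous or frozenset(pair_other) in ambiguous:
        raise IncompatibleAlleleError(
            f"SNP {ref.snp_id}: strand-ambiguous alleles {pair_ref} vs {pair_other}"
        )
    flipped = tuple(_COMPLEMENT.get(a, a) for a in pair_other)
    if flipped == pair_ref:
        return "flip"
    if flipped == pair_ref[::-1]:
        return "flip_swap"
    raise IncompatibleAlleleError(
        f"SNP {ref.snp_id}: alleles {pair_other} incompatible with {pair_ref}"
    )


def merge_datasets(datasets: Sequence[GenotypeDataset]) -> GenotypeDataset:
    """Merge panels on shared snp_ids, concatenating samples.

    The SNP set is the intersection by snp_id (first dataset's order). When a
    later dataset carries the (a1,a2) pair swapped relative to the first, its
    dosages are recoded g -> 2-g; pure strand flips keep dosages unchanged.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to merge")
    all_sample_ids = [sid for ds in datasets for sid in ds.sample_ids]
    if len(set(all_sample_ids)) != len(all_sample_ids):
        raise IntegrityError("sample_ids must be globally unique across datasets")
    shared = set(datasets[0].snp_ids)
    for ds in datasets[1:]:
        shared &= set(ds.snp_ids)
    ref = datasets[0]
    keep = [i for i, s in enumerate(ref.snps) if s.snp_id in shared]
    snps = [ref.snps[i] for i in keep]
    blocks = [ref.dosage[:, keep]]
    for ds in datasets[1:]:
        index = {s.snp_id: j for j, s in enumerate(ds.snps)}
        cols = np.array([index[s.snp_id] for s in snps], dtype=int)
        block = ds.dosage[:, cols].copy()
        for out_j, snp in enumerate(snps):
            rel = _reconcile(snp, ds.snps[cols[out_j]])
            if rel in ("swap", "flip_swap"):
                col = block[:, out_j]
                observed = col != MISSING
                col[observed] = 2 - col[observed]
        blocks.append(block)
    samples = [s for ds in datasets for s in ds.samples]
    return GenotypeDataset(snps, samples, np.vstack(blocks))


# ---------------------------------------------------------------------------
# QC filtering and subsampling
# ---------------------------------------------------------------------------

def qc_filter(
    ds: GenotypeDataset,
    snp_call_rate: float = 0.95,
    sample_call_rate: float = 0.90,
    autosomes_only: bool = True,
) -> tuple[GenotypeDataset, QCReport]:
    """Remove non-autosomal SNPs, low-call-rate SNPs, then low-call-rate samples.

    Removal uses strict "<": a marker or sample is retained iff its call rate
    is >= the threshold. Sample call rates are computed on surviving SNPs.
    """
    if not (0 < snp_call_rate <= 1 and 0 < sample_call_rate <= 1):
        raise ValueError("call-rate thresholds must lie in (0, 1]")
    n_snps_in, n_samples_in = ds.n_snps, ds.n_samples
    if autosomes_only:
        auto_idx = [i for i, s in enumerate(ds.snps) if is_autosome(s.chrom)]
    else:
        auto_idx = list(range(ds.n_snps))
    n_non_auto = n_snps_in - len(auto_idx)
    ds = ds.take(snp_idx=auto_idx)

    observed = ds.dosage != MISSING
    if ds.n_samples:
        snp_rate = observed.mean(axis=0)
    else:
        snp_rate = np.ones(ds.n_snps)
    keep_snps = np.flatnonzero(snp_rate >= snp_call_rate)
    n_low_snps = ds.n_snps - keep_snps.size
    ds = ds.take(snp_idx=keep_snps)

    observed = ds.dosage != MISSING
    if ds.n_snps:
        sample_rate = observed.mean(axis=1)
    else:
        sample_rate = np.ones(ds.n_samples)
    keep_samples = np.flatnonzero(sample_rate >= sample_call_rate)
    n_low_samples = ds.n_samples - keep_samples.size
    ds = ds.take(sample_idx=keep_samples)

    report = QCReport(
        n_snps_in=n_snps_in,
        n_samples_in=n_samples_in,
        n_non_autosomal_removed=n_non_auto,
        n_low_callrate_snps_removed=int(n_low_snps),
        n_low_callrate_samples_removed=int(n_low_samples),
        n_snps_out=ds.n_snps,
        n_samples_out=ds.n_samples,
    )
    return ds, report


def subsample_populations(
    ds: GenotypeDataset,
    max_per_pop: int = 48,
    min_per_pop: int = 5,
    seed: int = 0,
) -> GenotypeDataset:
    """Drop breeds below min_per_pop; cap larger breeds at max_per_pop.

    Oversized breeds are reduced by seeded uniform sampling without
    replacement; the same seed always yields the same selection.
    """
    if not max_per_pop >= min_per_pop >= 1:
        raise ValueError("require max_per_pop >= min_per_pop >= 1")
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for pop in ds.populations:
        idx = np.flatnonzero(ds.population_mask(pop))
        if idx.size < min_per_pop:
            continue
        if idx.size > max_per_pop:
            idx = np.sort(rng.choice(idx, size=max_per_pop, replace=False))
        keep.extend(idx.tolist())
    return ds.take(sample_idx=sorted(keep))
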