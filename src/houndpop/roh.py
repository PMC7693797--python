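"""Runs of homozygosity: calling, length-class summaries, F_ROH, islands.

A run is a maximal stretch of consecutive SNPs on one chromosome of one
individual containing no heterozygous call and at most ``max_missing``
missing calls; it qualifies as an ROH when it holds at least ``min_snps``
homozygous calls and spans at least ``min_length_bp``. Runs are built
greedily left to right; a heterozygous call always terminates a run, missing
calls are spanned up to the budget but never count toward ``min_snps``.
Segment span is first-to-last homozygous SNP, inclusive (+1 bp).

F_ROH is the summed ROH length divided by the autosomal genome length
(default 2,392,715,236 bp, the canine autosome total used throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, SampleRecord

AUTOSOME_LENGTH_BP = 2_392_715_236

ROH_CLASSES = ("short", "medium", "long")


@dataclass(frozen=True)
class ROHParams:
    min_snps: int = 25
    min_length_bp: int = 500_000
    max_het: int = 0
    max_missing: int = 5
    class_bounds_bp: tuple[int, int] = (2_500_000, 5_000_000)
    autosome_length_bp: int = AUTOSOME_LENGTH_BP
    max_gap_bp: int | None = None  # optional cap on inter-SNP gaps; off by default

    def __post_init__(self):
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        lo, hi = self.class_bounds_bp
        if not lo < hi:
            raise ValueError("class bounds must be strictly increasing")

    def classify(self, length_bp: int) -> str:
        """Length class with half-open boundaries [0.5,2.5), [2.5,5), [5,inf) Mb."""
        lo, hi = self.class_bounds_bp
        if length_bp < lo:
            return "short"
        if length_bp < hi:
            return "medium"
        return "long"


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int       # homozygous SNPs in the run
    n_missing: int    # missing SNPs spanned

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class ROHIsland:
    chrom: str
    start_bp: int
    end_bp: int
    peak_share: float


@dataclass
class ClassStats:
    n_roh: float = 0.0     # mean segments per individual
    l_roh_mb: float = 0.0  # mean segment length (pooled across individuals), Mb
    s_roh_mb: float = 0.0  # mean summed length per individual, Mb
    f_roh: float = 0.0     # mean S_ROH / autosome length


@dataclass
class ROHSummary:
    population: str
    n_individuals: int
    by_class: dict[str, ClassStats] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(population=self.population, roh_class=cls, **vars(st))
            for cls, st in self.by_class.items()
        ]
        return pd.DataFrame(rows)


def _scan_chromosome(
    genotypes: np.ndarray, positions: np.ndarray, params: ROHParams
) -> list[tuple[int, int, int, int]]:
    """Greedy left-to-right run construction on one chromosome of one sample.

    Returns (start_idx, end_idx, n_hom, n_missing) tuples over SNP indices;
    start/end indices point at homozygous SNPs.
    """
    hom = (genotypes == 0) | (genotypes == 2)
    het = genotypes == 1
    miss = genotypes == MISSING
    n = genotypes.size
    out = []
    i = 0
    while i < n:
        if not hom[i]:
            i += 1
            continue
        # extend as far as the het/missing budgets and (optionally) gap cap allow
        n_het = n_miss = 0
        j = i
        last_hom = i
        k = i + 1
        while k < n:
            if params.max_gap_bp is not None and positions[k] - positions[k - 1] > params.max_gap_bp:
                break
            if het[k]:
                if n_het + 1 > params.max_het:
                    break
                n_het += 1
            elif miss[k]:
                if n_miss + 1 > params.max_missing:
                    break
                n_miss += 1
            else:
                last_hom = k
            j = k
            k += 1
        n_hom = int(hom[i : last_hom + 1].sum())
        n_missing_inside = int(miss[i : last_hom + 1].sum())
        span = int(positions[last_hom] - positions[i] + 1)
        if n_hom >= params.min_snps and span >= params.min_length_bp:
            out.append((i, last_hom, n_hom, n_missing_inside))
        i = j + 1
    return out


def call_roh(ds: GenotypeDataset, params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Call ROH segments for every individual in a position-sorted dataset."""
    chroms = ds.chromosomes()
    positions = ds.positions()
    segments: list[ROHSegment] = []
    # contiguous chromosome blocks, positions strictly increasing within each
    blocks: list[tuple[str, int, int]] = []
    start = 0
    for k in range(1, ds.n_snps + 1):
        if k == ds.n_snps or chroms[k] != chroms[start]:
            blocks.append((chroms[start], start, k))
            start = k
    seen = set()
    for chrom, lo, hi in blocks:
        if chrom in seen:
            raise ValueError(f"dataset not sorted: chromosome {chrom} not contiguous")
        seen.add(chrom)
        pos = positions[lo:hi]
        if (np.diff(pos) <= 0).any():
            raise ValueError(f"dataset not sorted by position on chromosome {chrom}")
    for sample_i, sample in enumerate(ds.samples):
        row = ds.dosage[sample_i]
        for chrom, lo, hi in blocks:
            for si, ei, n_hom, n_miss in _scan_chromosome(
                row[lo:hi], positions[lo:hi], params
            ):
                segments.append(
                    ROHSegment(
                        sample_id=sample.sample_id,
                        chrom=chrom,
                        start_bp=int(positions[lo + si]),
                        end_bp=int(positions[lo + ei]),
                        n_snps=n_hom,
                        n_missing=n_miss,
                    )
                )
    return segments


def froh(
    segments: list[ROHSegment],
    params: ROHParams = ROHParams(),
    roh_class: str = "all",
) -> float:
    """Genomic inbreeding coefficient of one individual: summed ROH length in
    the chosen class divided by the autosomal genome length."""
    total = sum(
        seg.length_bp
        for seg in segments
        if roh_class == "all" or params.classify(seg.length_bp) == roh_class
    )
    return total / params.autosome_length_bp


def classify_and_summarize(
    segments: list[ROHSegment],
    samples: list[SampleRecord],
    params: ROHParams = ROHParams(),
) -> dict[str, ROHSummary]:
    """Per-population N_ROH / L_ROH / S_ROH / F_ROH by length class.

    N_ROH is the mean per-individual count (individuals with no ROH count 0);
    L_ROH is total length over total count pooled within the class; S_ROH is
    the mean per-individual summed length; F_ROH = mean S_ROH over the
    autosome length.
    """
    by_sample = {s.sample_id: [] for s in samples}
    for seg in segments:
        if seg.sample_id not in by_sample:
            raise KeyError(f"segment for unknown sample {seg.sample_id!r}")
        by_sample[seg.sample_id].append(seg)
    pops: dict[str, list[SampleRecord]] = {}
    for s in samples:
        pops.setdefault(s.population, []).append(s)
    out: dict[str, ROHSummary] = {}
    for pop, members in pops.items():
        summary = ROHSummary(population=pop, n_individuals=len(members))
        for cls in ("all",) + ROH_CLASSES:
            counts, sums, lengths = [], [], []
            for s in members:
                segs = [
                    seg
                    for seg in by_sample[s.sample_id]
                    if cls == "all" or params.classify(seg.length_bp) == cls
                ]
                counts.append(len(segs))
                sums.append(sum(seg.length_bp for seg in segs))
                lengths.extend(seg.length_bp for seg in segs)
            total_count = sum(counts)
            summary.by_class[cls] = ClassStats(
                n_roh=total_count / len(members),
                l_roh_mb=(sum(lengths) / total_count / 1e6) if total_count else 0.0,
                s_roh_mb=sum(sums) / len(members) / 1e6,
                f_roh=sum(sums) / len(members) / params.autosome_length_bp,
            )
        out[pop] = summary
    return out


def roh_incidence(segments: list[ROHSegment], ds: GenotypeDataset) -> pd.DataFrame:
    """Per-SNP count (and share) of individuals whose ROH cover the marker."""
    chroms = ds.chromosomes()
    positions = ds.positions()
    counts = np.zeros(ds.n_snps, dtype=int)
    chrom_index: dict[str, np.ndarray] = {}
    for chrom in np.unique(chroms):
        chrom_index[chrom] = np.flatnonzero(chroms == chrom)
    # count distinct individuals per SNP (overlapping segments of one
    # sample must not double-count)
    by_sample: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    covered = np.zeros(ds.n_snps, dtype=bool)
    for segs in by_sample.values():
        covered[:] = False
        for seg in segs:
            idx = chrom_index.get(seg.chrom)
            if idx is None:
                continue
            pos = positions[idx]
            lo = np.searchsorted(pos, seg.start_bp, side="left")
            hi = np.searchsorted(pos, seg.end_bp, side="right")
            covered[idx[lo:hi]] = True
        counts += covered
    n = max(ds.n_samples, 1)
    return pd.DataFrame(
        {
            "snp_id": ds.snp_ids,
            "chrom": chroms,
            "pos": positions,
            "count": counts,
            "share": counts / n,
        }
    )


def find_islands(
    incidence: pd.DataFrame, n_samples: int, threshold: float = 0.70
) -> list[ROHIsland]:
    """Maximal runs of consecutive SNPs covered in >= threshold of samples."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    islands: list[ROHIsland] = []
    share = incidence["count"].to_numpy() / n_samples
    chroms = incidence["chrom"].to_numpy()
    pos = incidence["pos"].to_numpy()
    above = share >= threshold
    start = None
    for i in range(len(incidence) + 1):
        ongoing = i < len(incidence) and above[i] and (
            start is None or chroms[i] == chroms[start]
        )
        if ongoing:
            if start is None:
                start = i
            continue
        if start is not None:
            end = i - 1
            islands.append(
                ROHIsland(
                    chrom=str(chroms[start]),
                    start_bp=int(pos[start]),
                    end_bp=int(pos[end]),
                    peak_share=float(share[start : end + 1].max()),
                )
            )
            start = None
        if i < len(incidence) and above[i]:
            start = i
    return islands


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                sample_id=s.sample_id, chrom=s.chrom, start_bp=s.start_bp,
                end_bp=s.end_bp, length_bp=s.length_bp, n_snps=s.n_snps,
                n_missing=s.n_missing,
            )
            for s in segments
        ],
        columns=[
            "sample_id", "chrom", "start_bp", "end_bp", "length_bp",
            "n_snps", "n_missing",
        ],
    )


def write_bed(segments: list[ROHSegment], path) -> None:
    """BED export (0-based half-open) of called segments."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{s.sample_id}\n")
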