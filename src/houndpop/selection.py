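"""Extended haplotype homozygosity and the iHS selection scan.

Works on fully phased, fully called binary haplotypes (0 ancestral,
1 derived). SNP arrays carry no ancestral state, so by default the
panel-minor allele is treated as derived; a user-supplied ancestral-allele
table can override this. iHS signs depend on the polarization; |iHS| and
the reported -log10 p-values are what the scan ranks on.

EHH at distance x from a core SNP is the probability that two random
core-allele-carrying haplotypes are identical over the whole stretch from
the core to x: sum over identity groups of C(n_g,2) / C(n_core,2). iHH is
the trapezoidal integral of EHH over genetic distance on both sides of the
core, truncated where EHH falls below a floor (0.05 by default, matching
common practice). unstandardized iHS = ln(iHH_ancestral / iHH_derived),
standardized to zero mean and unit variance within derived-allele-frequency
bins; p-values come from a two-sided standard-normal reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotype_io import SNPRecord


@dataclass
class HaplotypePanel:
    """(2 * n_individuals) x n_snps binary haplotype matrix with marker map."""

    snps: list[SNPRecord]
    haplotypes: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.snps):
            raise ValueError("haplotype matrix does not match the SNP list")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotypes must be binary (0 ancestral, 1 derived)")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def positions(self) -> np.ndarray:
        return np.array([s.pos_bp for s in self.snps], dtype=np.int64)

    def chromosomes(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps])

    def derived_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def polarize_minor_derived(panel: HaplotypePanel) -> tuple[HaplotypePanel, np.ndarray]:
    """Flip columns so the minor allele is coded 1 (derived).

    Returns the polarized panel and a boolean mask of flipped columns.
    """
    freq = panel.derived_freq()
    flip = freq > 0.5
    hap = panel.haplotypes.copy()
    hap[:, flip] = 1 - hap[:, flip]
    return HaplotypePanel(panel.snps, hap, panel.sample_ids), flip


def read_phased_vcf(path) -> HaplotypePanel:
    """Load a phased VCF (GT with '|' separators required) into a panel.

    REF is coded 0 and ALT 1; polarization is applied downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snps: list[SNPRecord] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"site {var.ID or var.POS}: only biallelic sites supported")
        gts = np.array(var.genotypes)  # (n_samples, 3): a, b, phased flag
        if not gts[:, 2].all():
            raise ValueError(f"site {var.ID or var.POS}: unphased genotype present")
        if (gts[:, :2] < 0).any():
            raise ValueError(f"site {var.ID or var.POS}: missing call in phased panel")
        snps.append(
            SNPRecord(
                var.ID or f"{var.CHROM}_{var.POS}",
                str(var.CHROM),
                int(var.POS),
                str(var.REF),
                str(var.ALT[0]),
            )
        )
        columns.append(gts[:, :2].reshape(-1))
    hap = np.stack(columns, axis=1) if columns else np.zeros((2 * len(sample_ids), 0))
    return HaplotypePanel(snps, hap, sample_ids)


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Plain-text phased VCF export (pairs of rows form individuals)."""
    if panel.n_haplotypes % 2:
        raise ValueError("odd number of haplotypes cannot form diploid samples")
    n_ind = panel.n_haplotypes // 2
    sample_ids = panel.sample_ids or [f"ind{i}" for i in range(n_ind)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in panel.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j, snp in enumerate(panel.snps):
            ref = snp.allele_a1 if snp.allele_a1 != "0" else "A"
            alt = snp.allele_a2 if snp.allele_a2 != "0" else "G"
            gts = "\t".join(
                f"{panel.haplotypes[2 * i, j]}|{panel.haplotypes[2 * i + 1, j]}"
                for i in range(n_ind)
            )
            fh.write(
                f"{snp.chrom}\t{snp.pos_bp}\t{snp.snp_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------

def ehh(
    panel: HaplotypePanel,
    core_idx: int,
    allele: int,
    direction: str,
    stop_below: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH curve from the core SNP outward in one direction.

    Returns (positions, ehh values) starting at the core (EHH = 1) and
    walking 'left' or 'right' along the core SNP's chromosome. Haplotype
    identity groups are refined SNP by SNP; EHH_x = sum C(n_g,2)/C(n,2).
    When ``stop_below`` is given the walk ends just after the first value
    under it (the curve past an integration floor is never needed).
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    chroms = panel.chromosomes()
    on_chrom = np.flatnonzero(chroms == chroms[core_idx])
    carriers = np.flatnonzero(panel.haplotypes[:, core_idx] == allele)
    n = carriers.size
    if n < 2:
        raise ValueError("fewer than two carrier haplotypes at the core")
    denom = n * (n - 1) / 2
    step = 1 if direction == "right" else -1
    local = list(on_chrom)
    core_local = local.index(core_idx)
    path = local[core_local::step] if step == 1 else local[core_local::-1]
    groups = np.zeros(n, dtype=np.int64)
    positions, values = [], []
    for rank, j in enumerate(path):
        if rank > 0:
            col = panel.haplotypes[carriers, j].astype(np.int64)
            _, groups = np.unique(groups * 2 + col, return_inverse=True)
        counts = np.bincount(groups)
        positions.append(panel.snps[j].pos_bp)
        value = float(np.sum(counts * (counts - 1) / 2) / denom)
        values.append(value)
        if stop_below is not None and value < stop_below:
            break
    return np.array(positions), np.array(values)


def ihh_from_curve(
    positions: np.ndarray,
    values: np.ndarray,
    cM_per_Mb: float = 1.0,
    ehh_floor: float = 0.05,
) -> tuple[float, bool]:
    """One-sided trapezoidal iHH (Morgans) with floor truncation.

    The curve is cut at the first point where EHH < floor; if it never
    reaches the floor the whole curve is integrated and the truncation flag
    is returned True.
    """
    below = np.flatnonzero(values < ehh_floor)
    truncated_at_end = below.size == 0
    cut = below[0] if below.size else len(values)
    pos = positions[:cut]
    val = values[:cut]
    if len(pos) < 2:
        return 0.0, truncated_at_end
    gdist = np.abs(pos - pos[0]).astype(float) * (cM_per_Mb / 100.0) / 1e6
    return float(np.trapezoid(val, gdist)), truncated_at_end


def ihh(
    panel: HaplotypePanel,
    core_idx: int,
    allele: int,
    cM_per_Mb: float = 1.0,
    ehh_floor: float = 0.05,
) -> float:
    """Two-sided integrated EHH for one core allele."""
    total = 0.0
    warn = False
    for direction in ("left", "right"):
        pos, val = ehh(panel, core_idx, allele, direction, stop_below=ehh_floor)
        area, trunc = ihh_from_curve(pos, val, cM_per_Mb, ehh_floor)
        total += area
        warn |= trunc and len(pos) > 1
    if warn:
        warnings.warn(
            f"EHH did not reach the floor before the chromosome end at core "
            f"{panel.snps[core_idx].snp_id}; integral truncated there",
            stacklevel=2,
        )
    return total


# ---------------------------------------------------------------------------
# iHS scan
# ---------------------------------------------------------------------------

def ihs_pvalue(abs_ihs: float) -> float:
    """-log10 of the two-sided Gaussian p-value for a standardized score."""
    if abs_ihs < 0:
        raise ValueError("|iHS| must be non-negative")
    return float(-np.log10(np.maximum(2 * norm.sf(abs_ihs), np.finfo(float).tiny)))


def ihs_scan(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    bin_width: float = 0.025,
    cM_per_Mb: float = 1.0,
    ehh_floor: float = 0.05,
    polarized: bool = False,
) -> pd.DataFrame:
    """Genome-wide iHS over all qualifying SNPs.

    SNPs with minor-allele frequency below maf_min, fewer than two carriers
    of either allele, or a vanishing iHH on either side are skipped.
    unstandardized scores ln(iHH_A/iHH_D) are standardized within
    derived-frequency bins of width bin_width.
    """
    if not polarized:
        panel, _ = polarize_minor_derived(panel)
    freq = panel.derived_freq()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(panel.n_snps):
            maf = min(freq[j], 1 - freq[j])
            if maf < maf_min:
                continue
            n_derived = int(panel.haplotypes[:, j].sum())
            if n_derived < 2 or panel.n_haplotypes - n_derived < 2:
                continue
            ihh_a = ihh(panel, j, 0, cM_per_Mb, ehh_floor)
            ihh_d = ihh(panel, j, 1, cM_per_Mb, ehh_floor)
            if ihh_a <= 0 or ihh_d <= 0:
                continue
            rows.append(
                dict(
                    snp_id=panel.snps[j].snp_id,
                    chrom=panel.snps[j].chrom,
                    pos_bp=panel.snps[j].pos_bp,
                    freq_derived=float(freq[j]),
                    ihh_a=ihh_a,
                    ihh_d=ihh_d,
                    unihs=float(np.log(ihh_a / ihh_d)),
                )
            )
    result = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos_bp", "freq_derived", "ihh_a", "ihh_d", "unihs"],
    )
    if result.empty:
        result["ihs"] = result["logp"] = pd.Series(dtype=float)
        return result
    bins = np.floor(result["freq_derived"].to_numpy() / bin_width).astype(int)
    ihs = np.full(len(result), np.nan)
    un = result["unihs"].to_numpy()
    for b in np.unique(bins):
        sel = bins == b
        mu = un[sel].mean()
        sd = un[sel].std()
        ihs[sel] = (un[sel] - mu) / sd if sd > 0 else 0.0
    result["ihs"] = ihs
    result["logp"] = [ihs_pvalue(abs(x)) for x in ihs]
    return result
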