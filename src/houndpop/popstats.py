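"""Per-breed diversity statistics and Nei's standard genetic distance.

Per-locus statistics follow the classical SNP conventions: allele frequency
from observed genotypes, H_obs as the heterozygote fraction, H_exp = 2pq
(uncorrected), nucleotide diversity pi as H_exp with the 2n/(2n-1)
pairwise-sampling correction, and F_is = (pi - H_obs)/pi. Fixed loci have
pi = 0 and an undefined F_is (NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass(frozen=True)
class LocusStats:
    p: float          # frequency of allele_a2
    n_typed: int
    h_obs: float
    h_exp: float
    pi: float
    fis: float        # NaN when pi == 0


@dataclass
class PopulationStats:
    population: str
    n_loci: int
    pct_polymorphic: float
    n_mean: float         # mean individuals typed per locus
    n_total: int          # total samples in the population
    p_mean: float         # mean major-allele frequency
    h_obs_mean: float
    h_obs_sd: float
    h_exp_mean: float
    h_exp_sd: float
    pi_mean: float
    pi_sd: float
    fis_mean: float
    fis_sd: float


def _locus_arrays(dosage: np.ndarray):
    """Vectorized per-locus statistics over a (samples x loci) dosage block."""
    observed = dosage != MISSING
    n = observed.sum(axis=0).astype(float)
    if (n == 0).any():
        raise ValueError("locus with no observed genotypes")
    d = np.where(observed, dosage, 0).astype(float)
    p = d.sum(axis=0) / (2 * n)
    h_obs = ((dosage == 1) & observed).sum(axis=0) / n
    h_exp = 2 * p * (1 - p)
    pi = np.where(n >= 1, (2 * n) / (2 * n - 1) * h_exp, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = np.where(pi > 0, (pi - h_obs) / pi, np.nan)
    return p, n, h_obs, h_exp, pi, fis


def locus_stats(dosage_column: np.ndarray, mask: np.ndarray | None = None) -> LocusStats:
    """Statistics for one locus, optionally restricted to a population mask."""
    col = np.asarray(dosage_column)
    if mask is not None:
        col = col[np.asarray(mask)]
    p, n, h_obs, h_exp, pi, fis = _locus_arrays(col[:, None])
    return LocusStats(
        p=float(p[0]), n_typed=int(n[0]), h_obs=float(h_obs[0]),
        h_exp=float(h_exp[0]), pi=float(pi[0]), fis=float(fis[0]),
    )


def population_stats(ds: GenotypeDataset, population: str) -> PopulationStats:
    """Table-style summary over all loci for one breed.

    Fixed loci contribute zeros to the heterozygosity means but are excluded
    from the F_is aggregate; a locus is polymorphic when both alleles are
    observed in the breed.
    """
    mask = ds.population_mask(population)
    block = ds.dosage[mask]
    p, n, h_obs, h_exp, pi, fis = _locus_arrays(block)
    poly = (p > 0) & (p < 1)
    defined = ~np.isnan(fis)
    return PopulationStats(
        population=population,
        n_loci=ds.n_snps,
        pct_polymorphic=100.0 * poly.mean(),
        n_mean=float(n.mean()),
        n_total=int(mask.sum()),
        p_mean=float(np.maximum(p, 1 - p).mean()),
        h_obs_mean=float(h_obs.mean()),
        h_obs_sd=float(h_obs.std()),
        h_exp_mean=float(h_exp.mean()),
        h_exp_sd=float(h_exp.std()),
        pi_mean=float(pi.mean()),
        pi_sd=float(pi.std()),
        fis_mean=float(fis[defined].mean()) if defined.any() else float("nan"),
        fis_sd=float(fis[defined].std()) if defined.any() else float("nan"),
    )


def stats_table(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-breed summary table (one row per population)."""
    rows = [vars(population_stats(ds, pop)) for pop in ds.populations]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nei's standard genetic distance (1972)
# ---------------------------------------------------------------------------

def allele_frequencies(ds: GenotypeDataset, population: str) -> np.ndarray:
    """Per-locus frequency of allele_a2 within a breed (NaN if untyped)."""
    mask = ds.population_mask(population)
    block = ds.dosage[mask]
    observed = block != MISSING
    n = observed.sum(axis=0).astype(float)
    d = np.where(observed, block, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, d.sum(axis=0) / (2 * n), np.nan)


def nei_distance(freqs_pop1: np.ndarray, freqs_pop2: np.ndarray) -> float:
    """Nei (1972) standard distance between two biallelic frequency vectors.

    D = -ln( sum J12 / sqrt(sum J11 * sum J22) ) with per-locus
    J11 = p1^2 + q1^2, J22 = p2^2 + q2^2, J12 = p1 p2 + q1 q2, summed over
    loci typed in both populations. Returns +inf when sum J12 = 0.
    """
    p1 = np.asarray(freqs_pop1, dtype=float)
    p2 = np.asarray(freqs_pop2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("frequency vectors cover different locus lists")
    ok = ~(np.isnan(p1) | np.isnan(p2))
    p1, p2 = p1[ok], p2[ok]
    q1, q2 = 1 - p1, 1 - p2
    j11 = float(np.sum(p1 * p1 + q1 * q1))
    j22 = float(np.sum(p2 * p2 + q2 * q2))
    j12 = float(np.sum(p1 * p2 + q1 * q2))
    if j12 == 0.0:
        return math.inf
    return -math.log(j12 / math.sqrt(j11 * j22))


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal; entries may be +inf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def distance_matrix(ds: GenotypeDataset) -> DistanceMatrix:
    """All pairwise Nei distances between the dataset's breeds."""
    pops = ds.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    freqs = {pop: allele_frequencies(ds, pop) for pop in pops}
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(freqs[pops[i]], freqs[pops[j]])
    return DistanceMatrix(labels=list(pops), d=d)


def _finite(dm: DistanceMatrix, inf_sentinel: float) -> np.ndarray:
    d = dm.d.copy()
    if np.isinf(d).any():
        import warnings

        warnings.warn(
            f"infinite distances written as sentinel {inf_sentinel}", stacklevel=3
        )
        d[np.isinf(d)] = inf_sentinel
    return d


def export_phylip(dm: DistanceMatrix, path, inf_sentinel: float = 99.0) -> None:
    """PHYLIP square distance matrix (SplitsTree-readable)."""
    d = _finite(dm, inf_sentinel)
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, d):
            name = label.replace(" ", "_")[:10].ljust(10)
            fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def export_nexus(dm: DistanceMatrix, path, inf_sentinel: float = 99.0) -> None:
    """NEXUS DISTANCES block (SplitsTree-readable)."""
    d = _finite(dm, inf_sentinel)
    labels = [lb.replace(" ", "_") for lb in dm.labels]
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(labels)};\n  TAXLABELS\n")
        for lb in labels:
            fh.write(f"    {lb}\n")
        fh.write("  ;\nEND;\n\nBEGIN DISTANCES;\n")
        fh.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n  MATRIX\n")
        for lb, row in zip(labels, d):
            fh.write(f"    {lb}  " + "  ".join(f"{x:.6f}" for x in row) + "\n")
        fh.write("  ;\nEND;\n")


def read_nexus_distances(path) -> DistanceMatrix:
    """Minimal reader for the NEXUS distances block written by export_nexus."""
    labels, rows, in_matrix = [], [], False
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token.upper().startswith("MATRIX"):
                in_matrix = True
                continue
            if in_matrix:
                if token == ";":
                    break
                parts = token.split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels=labels, d=np.array(rows))


def read_phylip_distances(path) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline())
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels=labels, d=np.array(rows))
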