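"""Composite-genotype LD, window-based LD pruning, and LD-decay Ne estimation.

r2 between two markers is the squared Pearson correlation of their dosage
vectors over pairwise-complete samples (the Rogers-Huff composite measure;
no phase required). Historical effective population size is recovered from
binned LD decay through Sved's relation E[r2] = 1/(alpha + 4 Ne c) after
subtracting the 1/(2n) sample-size term, with each distance bin dated to
about t = 1/(2c) generations ago.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


def r2_composite(col_i: np.ndarray, col_j: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete samples.

    Returns NaN when fewer than two complete pairs remain or either marker is
    monomorphic among them.
    """
    x = np.asarray(col_i, dtype=float)
    y = np.asarray(col_j, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return float("nan")
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(
    ds: GenotypeDataset,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> tuple[GenotypeDataset, list[str]]:
    """Sliding-window greedy LD pruning.

    Windows of ``window_snps`` markers advance by ``step_snps``; within each
    window pairs are scanned in map order and whenever r2 > r2_max the first
    (left) marker of the pair is pruned. Pruned markers are ignored in later
    comparisons. Fully deterministic.
    """
    chroms = ds.chromosomes()
    pruned = np.zeros(ds.n_snps, dtype=bool)
    cache: dict[tuple[int, int], float] = {}

    def r2(a: int, b: int) -> float:
        key = (a, b)
        if key not in cache:
            cache[key] = r2_composite(ds.dosage[:, a], ds.dosage[:, b])
        return cache[key]

    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        n = idx.size
        start = 0
        while start < n:
            window = idx[start : start + window_snps]
            for ai in range(len(window)):
                a = window[ai]
                if pruned[a]:
                    continue
                for bi in range(ai + 1, len(window)):
                    b = window[bi]
                    if pruned[b]:
                        continue
                    val = r2(a, b)
                    if not np.isnan(val) and val > r2_max:
                        pruned[a] = True
                        break
            if start + window_snps >= n:
                break
            start += step_snps
    keep = np.flatnonzero(~pruned)
    pruned_ids = [ds.snps[i].snp_id for i in np.flatnonzero(pruned)]
    return ds.take(snp_idx=keep), pruned_ids


def ld_decay_bins(
    ds: GenotypeDataset,
    max_dist_bp: float,
    n_bins: int,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Bin all intra-chromosomal marker pairs by distance; mean r2 per bin.

    Pairs where either marker has MAF < maf_min are excluded; empty bins are
    dropped with a warning. Returns columns bin_mid_bp, r2_mean, n_pairs.
    """
    if max_dist_bp <= 0:
        raise ValueError("max_dist_bp must be positive")
    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    chroms = ds.chromosomes()
    positions = ds.positions()
    any_missing = (ds.dosage == MISSING).any()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        block = ds.dosage[:, idx].astype(float)
        obs = block != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(obs, block, 0).sum(axis=0) / (2 * np.maximum(n_obs, 1))
        maf = np.minimum(freq, 1 - freq)
        ok = (maf >= maf_min) & (n_obs >= 2)
        idx, block = idx[ok], block[:, ok]
        pos = positions[idx]
        m = idx.size
        if m < 2:
            continue
        if not any_missing:
            centred = block - block.mean(axis=0)
            sd = centred.std(axis=0)
            corr = (centred / np.where(sd == 0, 1, sd)).T @ (
                centred / np.where(sd == 0, 1, sd)
            ) / block.shape[0]
            r2mat = corr**2
        else:
            r2mat = None
        for a in range(m):
            dist = pos[a + 1 :] - pos[a]
            within = np.flatnonzero(dist <= max_dist_bp)
            for off in within:
                b = a + 1 + off
                val = (
                    r2mat[a, b]
                    if r2mat is not None
                    else r2_composite(block[:, a], block[:, b])
                )
                if np.isnan(val):
                    continue
                k = min(int(np.searchsorted(edges, dist[off], side="right") - 1), n_bins - 1)
                sums[k] += val
                counts[k] += 1
    mids = (edges[:-1] + edges[1:]) / 2
    empty = counts == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} empty distance bins dropped", stacklevel=2)
    keep = ~empty
    return pd.DataFrame(
        {
            "bin_mid_bp": mids[keep],
            "r2_mean": sums[keep] / counts[keep],
            "n_pairs": counts[keep],
        }
    )


def estimate_ne(
    bins: pd.DataFrame,
    n_individuals: int,
    alpha: float = 1.0,
    cM_per_Mb: float = 1.0,
) -> pd.DataFrame:
    """Historical Ne per distance bin via Sved's relation.

    c = bin_mid_bp * (cM_per_Mb/100) / 1e6 Morgans; r2_adj = r2_mean - 1/(2n);
    Ne = (1/(4c)) * (1/r2_adj - alpha); t_gen = 1/(2c). Bins with
    non-positive r2_adj (or non-positive Ne) yield NaN.
    """
    if len(bins) == 0:
        raise ValueError("no distance bins supplied")
    if n_individuals < 2:
        raise ValueError("need at least two individuals")
    c = bins["bin_mid_bp"].to_numpy() * (cM_per_Mb / 100.0) / 1e6
    if (c == 0).any():
        raise ValueError("bin midpoint of zero distance: cannot date LD")
    r2_mean = bins["r2_mean"].to_numpy()
    r2_adj = r2_mean - 1.0 / (2 * n_individuals)
    with np.errstate(divide="ignore", invalid="ignore"):
        ne = np.where(r2_adj > 0, (1.0 / (4 * c)) * (1.0 / r2_adj - alpha), np.nan)
    ne = np.where(ne > 0, ne, np.nan)
    return pd.DataFrame(
        {
            "bin_mid_bp": bins["bin_mid_bp"].to_numpy(),
            "c_morgan": c,
            "t_gen": 1.0 / (2 * c),
            "r2_mean": r2_mean,
            "r2_adj": r2_adj,
            "ne": ne,
            "n_pairs": bins["n_pairs"].to_numpy()
            if "n_pairs" in bins
            else np.full(len(bins), np.nan),
        }
    )
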