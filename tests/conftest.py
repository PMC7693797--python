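import numpy as np
import pandas as pd
import pytest

from houndpop.genotype_io import GenotypeDataset, SampleRecord, SNPRecord


def make_dataset(
    dosage,
    positions=None,
    chroms=None,
    populations=None,
    alleles=None,
    snp_ids=None,
):
    """Build a GenotypeDataset from a plain nested list / array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_snps = dosage.shape
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(n_snps)]
    chroms = chroms if chroms is not None else ["1"] * n_snps
    populations = populations if populations is not None else ["pop"] * n_samples
    alleles = alleles if alleles is not None else [("A", "G")] * n_snps
    snp_ids = snp_ids if snp_ids is not None else [f"rs{j}" for j in range(n_snps)]
    snps = [
        SNPRecord(snp_ids[j], str(chroms[j]), int(positions[j]), *alleles[j])
        for j in range(n_snps)
    ]
    samples = [SampleRecord(f"s{i}", populations[i]) for i in range(n_samples)]
    return GenotypeDataset(snps, samples, dosage)


def random_dataset(rng, n_samples=10, n_snps=50, missing_rate=0.05, n_chrom=2):
    dosage = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    miss = rng.random((n_samples, n_snps)) < missing_rate
    dosage[miss] = -1
    per = n_snps // n_chrom
    chroms = [str(1 + min(j // per, n_chrom - 1)) for j in range(n_snps)]
    positions = []
    last_chrom = None
    for c in chroms:
        if c != last_chrom:
            pos = 0
            last_chrom = c
        pos += int(rng.integers(1_000, 50_000))
        positions.append(pos)
    return make_dataset(dosage, positions=positions, chroms=chroms)


def random_pedigree_frame(rng, n_founders=6, n_gen=3, per_gen=8):
    """Random mating pedigree as a raw DataFrame (valid, acyclic)."""
    rows = []
    males, females = [], []
    for k in range(n_founders):
        sex = "male" if k % 2 == 0 else "female"
        name = f"f{k}"
        rows.append((name, "", "", sex))
        (males if sex == "male" else females).append(name)
    for g in range(n_gen):
        new_m, new_f = [], []
        for k in range(per_gen):
            sex = "male" if k % 2 == 0 else "female"
            name = f"g{g}_{k}"
            rows.append((name, rng.choice(males), rng.choice(females), sex))
            (new_m if sex == "male" else new_f).append(name)
        males = males + new_m
        females = females + new_f
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
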