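# Methods

This note records the statistical definitions, numerical conventions, and
design choices behind each module, and what the synthetic-data generator
does and does not emulate.

## Genotype container and I/O

Genotypes live in a samples × SNPs `int8` dosage matrix counting copies of
the second (`a2`) allele of each marker, with −1 for a missing call. PLINK
1.9 binary triplets are read and written natively (SNP-major 2-bit codes;
the missing code round-trips exactly); positions are 1-based inclusive
throughout, converted to 0-based half-open only in BED exports.

**Merging.** Panels are joined on marker identifiers (the chips at issue
share Illumina IDs); a shared ID with conflicting coordinates is an error
rather than a silent preference for one map. Allele pairs are reconciled in
the order: identical → swapped (dosages recoded g → 2−g) → strand-flipped
(both alleles complemented) → flipped-and-swapped. A/T and C/G markers are
never strand-flipped — a flip is indistinguishable from a swap there — so a
mismatch on such a marker is an error.

**QC.** The order of operations is fixed: non-autosomal markers are dropped
first, then markers with call rate below the SNP threshold (default 0.95),
then samples with call rate below the sample threshold (default 0.90),
computed on the surviving markers. Removal uses strict `<`: a marker at
exactly 95% call rate is retained. Breed subsampling drops breeds with
fewer than 5 animals and caps larger breeds at 48 by seeded uniform
sampling without replacement. QC after merging is the default order; both
orders are available by composing the functions.

## Diversity statistics

Per-locus, within a breed, with n the animals typed at the locus and p the
`a2` frequency among them:

- H_obs = heterozygote fraction; H_exp = 2p(1−p), uncorrected;
- π = 2n/(2n−1) · H_exp — the mean pairwise difference among the 2n sampled
  alleles (exact identity, verified by enumeration in the tests);
- F_IS = (π − H_obs)/π, undefined (NaN) at fixed loci.

Fixed loci contribute zeros to heterozygosity means but are excluded from
the F_IS aggregate; a locus is polymorphic when both alleles are observed
in the breed. These definitions were fixed deliberately — the common
population-statistics toolchains differ in their finite-sample corrections
across versions, so any deviation from a particular tool's output is
explainable from the formulas above. Breed-level standard deviations are
population SDs (ddof = 0) over loci. The summary reports both the mean
animals typed per locus and the total sample count, since "N" is ambiguous
in this kind of table.

Nei's (1972) standard distance is computed on QC'd, un-pruned markers:
per locus J11 = p1²+q1², J22 = p2²+q2², J12 = p1p2+q1q2, summed over loci
typed in both breeds, then D = −ln(ΣJ12/√(ΣJ11·ΣJ22)); D = +∞ when no
allele is shared, written to PHYLIP/NEXUS exports as a configurable large
sentinel (default 99.0) with a warning.

## Runs of homozygosity

A run is built greedily left-to-right per sample per chromosome: it starts
at a homozygous call and extends until a heterozygote appears (the het
budget defaults to 0) or the missing budget (default 5) would be exceeded;
the run is then trimmed to its last homozygous call. It is emitted when it
holds ≥ 25 homozygous calls and spans ≥ 500 kb, measured first-to-last
homozygous SNP inclusive (+1 bp). Missing calls are spanned but never count
toward the 25 — the stricter of the two possible readings, configurable.
Sparse inter-SNP gaps are not capped by default (`max_gap_bp` exists, off
by default). Emitted segments never overlap within one sample.

Length classes are half-open: short [0.5, 2.5), medium [2.5, 5),
long [5, ∞) Mb, so a segment of exactly 2.5 Mb is medium. Per breed,
N_ROH is the mean per-animal segment count (animals with none count 0),
S_ROH the mean per-animal summed length, L_ROH the pooled total length over
the pooled count — equal to S_ROH/N_ROH, which is the arithmetic the
published-style tables obey — and F_ROH = S_ROH / 2,392,715,236 bp, the
canine autosome length used throughout. F_ROH is additive across classes.

ROH islands are maximal runs of consecutive SNPs whose ROH incidence
(distinct animals covered) reaches the threshold share; the threshold is
"≥ 70%" (the more inclusive of the two phrasings in circulation),
configurable. Incidence counts distinct animals, so overlapping segments
of one animal cannot double-count.

## LD and effective population size

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples (composite/Rogers–Huff; no phasing needed,
invariant to allele recoding). LD pruning slides a window of 50 markers
advanced by 5; within a window, pairs are scanned in map order and the
*left* marker of any pair with r² > 0.5 is pruned and ignored thereafter —
deterministic by construction. (The window is in markers: a 50 bp window
would contain at most one array SNP.)

Ne estimation bins intra-chromosomal pairs (both MAFs ≥ 0.05 by default)
by distance. Per bin with midpoint d: c = d · (cM/Mb)/10⁸ Morgans,
r²_adj = mean r² − 1/(2n) for n diploids, and Sved's relation inverted:
Ne = (1/4c)(1/r²_adj − α), dated to t = 1/(2c) generations ago. α = 1 by
default (no mutation), 2.2 selectable. The physical-to-genetic map is
1 cM/Mb unless overridden. Bins with non-positive r²_adj or Ne yield NaN
rather than a number.

## Pedigree analytics

- **F** (Wright): Meuwissen–Luo — the dummy-progeny row of the Cholesky
  factor of the numerator relationship matrix A is traced through the
  pedigree, giving exact F without materializing A. Verified against the
  full tabular method on random pedigrees (exact to 1e-12).
- **AR**: mean of the individual's A-row over all animals, via Colleau's
  indirect method (one backward sweep for L'v, a diagonal scale, one
  forward sweep for Lz) in O(n).
- **Completeness**: gen_max (deepest known-ancestor path), gen_complete
  (deepest fully-known generation), gen_equiv = Σ over known-ancestor
  paths of (1/2)^depth.
- **ΔF and realized Ne**: the individual-increase form
  ΔF_i = 1 − (1−F_i)^(1/(t_i−1)) over animals with gen_equiv t_i > 1,
  averaged; Ne = 1/(2ΔF), infinite when ΔF = 0. A regression-on-generation
  variant is provided (`delta_f_regression`) for comparison; the
  individual-increase form is the default because it is the conventional
  output of genealogical packages in this field.
- **Founder statistics**: founder contributions q_k are accumulated by one
  upward sweep from the reference animals (each animal passes half its
  weight to each known parent; weight arriving at an unknown-parent slot is
  credited to that animal as new founder material — the half-founder
  convention, which keeps Σq = 1 when pedigrees are ragged). f_e = 1/Σq².
  The reported founder count follows the strict definition (both parents
  unknown), so in ragged pedigrees f_e can exceed it; in complete pedigrees
  the invariant f_a ≤ f_e ≤ n_founders holds.
- **f_a (Boichard)**: ancestors — proper ancestors of the reference — are
  selected greedily by marginal contribution: the candidate's expected
  contribution computed in a pedigree where each already-selected
  ancestor's parent links are cut, multiplied by the unexplained fraction
  of the candidate's own genome (selected ancestors absorb). The second
  factor is what keeps Σ marginals = 1 when candidates descend from
  already-selected ancestors. f_a = 1/Σp². Restricting candidates to
  proper ancestors prevents reference animals from trivially explaining
  themselves.

The reference population defaults to the offspringless animals (the
genotyped probands in a typical breed study); any id list can be supplied.
Birthdates parse as ISO-8601; a parent born after its offspring is a
warning, not an error — kennel records are messy — while cycles and
sire/dam role conflicts are hard errors.

## Selection scan

Haplotypes are binary (0 ancestral / 1 derived), fully phased and fully
called. Because SNP arrays carry no ancestral state, the default
polarization treats the panel-minor allele as derived; an ancestral-allele
table can override it. iHS signs depend on this choice; rankings on |iHS|
are affected only through the frequency-binned standardization.

EHH at SNP x from a core is Σ_g C(n_g,2)/C(n_core,2) over groups of
identical extended haplotypes among core-allele carriers — exactly 1 at the
core, non-increasing outward (asserted on every curve in the tests). iHH
integrates EHH trapezoidally over genetic distance (1 cM/Mb default) on
both sides, truncated at the first point where EHH < 0.05 (floor, curve
point excluded); if the floor is never reached the integral runs to the
chromosome end with a warning. unstandardized iHS = ln(iHH_A/iHH_D) is
standardized to zero mean, unit variance (ddof = 0) within derived-frequency
bins of width 0.025, and −log₁₀ p uses the two-sided standard normal tail.
SNPs with MAF < 0.05, fewer than two carriers of either allele, or a
vanishing one-sided integral are skipped. EHH/MAF floors and bin width
follow the defaults of the standard haplotype-scan tooling; all are
configurable. No gap penalty is applied by default.

## Synthetic data

The generator emulates: multi-chromosome diploid SNP panels with uniform
random marker positions; founder allele frequencies uniform on
[0.05, 0.5]; Wright–Fisher drift (random mating, distinct parents, Poisson
crossovers without interference, no mutation) which produces the
distance-decaying LD the Ne estimator consumes; designed pedigrees
(full-sib, half-sib, parent–offspring, random mating) with analytically
known F; gene-dropping of uniquely labelled founder chromosomes, recording
IBD-homozygous tracts as truth *before* optional genotyping error and
missingness are injected; and planted sweeps (a carrier fraction shares one
haplotype over a region, the core SNP forced derived).

It does not emulate: mutation, selection other than the planted sweep,
variable recombination maps, genotyping batch effects, or ascertainment
bias of array SNPs. Passing recovery tests therefore demonstrates
algorithmic correctness under idealized noise, not robustness to every
artefact of real array data. One systematic gap matters for interpretation:
called ROH are identity-by-state and extend a few SNPs beyond the true IBD
tract (and can bridge short non-IBD gaps), so boundary agreement is
asymptotic in marker density; the recovery tests use a dense map
(~8 kb spacing) where per-tract Jaccard ≥ 0.95 for tracts above the calling
thresholds.

Desk-scale defaults: 2 chromosomes × 50 Mb carrying 5,000 SNPs, Ne = 100
diploids, 200 generations, 1 cM/Mb. Every generator is a deterministic
function of its seed.

### Validation problem sizes

- LD-based Ne recovery: 10 replicate drift simulations at the default
  scenario, 50 diploids sampled, pairs binned to 5 Mb in 20 bins; the
  pooled median across bins and replicates is compared with the truth
  (individual replicates scatter with their own drift histories).
- IBD recovery: 200 replicate two-family full-sib cohorts on the default
  genome (realized IBD fractions have large per-proband variance because
  only ~1 crossover occurs per 50 Mb chromosome per meiosis; cohort
  replication tightens the mean).
- Sweep recovery: a 2 Mb sweep at 80% carrier frequency planted at the
  center of a 50 Mb chromosome with 1,000 independent background sites and
  96 haplotypes — the sweep occupies a small fraction of each frequency
  bin, keeping the binned standardization well-behaved. A background with
  its own strong drift-generated haplotype structure (small-Ne
  Wright–Fisher) is deliberately not used here: at Ne ≈ 100 drift produces
  genuine sweep-like regions that compete with the planted one, which is a
  property of the biology, not of the scan.

## Pipeline

`houndpop run --config FILE` executes simulate → QC → stats → distances →
ROH → Ne → pedigree → iHS (any subset) from one YAML file whose defaults
encode every analysis parameter above; unknown keys are rejected. Outputs
are per-stage tables plus `summary.json`; `run.log` records the version,
seed, and the fully resolved parameter set. Identical configs produce
byte-identical outputs.

## Known limitations

- The LD-decay Ne assumes a constant 1 cM/Mb map and Sved's equilibrium
  relation; recent demographic change shows up as bin-to-bin trends, not
  corrected bias.
- iHS on array data depends on the minor-as-derived polarization; absolute
  scores are comparable across datasets only under the same convention.
- The ROH caller has no gap cap by default, so very sparse regions can
  produce long segments supported by few markers; set `max_gap_bp` on
  sparse maps.
- f_e/f_a with ragged pedigrees use the half-founder convention above;
  tools that instead invent phantom founder parents will differ there.
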