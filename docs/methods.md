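# Methods

## Evidence model and scoring

A gene universe is a table of (id, symbol, chromosome, 1-based inclusive
start/end). Seven boolean evidence tracks attach to it: two mouse
microarray sources (MuAc: acute ethanol response; MuPref: preference
drinking), a human alcoholic-cortex microarray source (HuAlc), an
addiction/alcoholism candidate chip (HuAddChip), human linkage-interval
membership (HuLink), and worm (Ce) and fly (Dr) screen lists. Non-human
lists arrive in their own identifier namespace and are harmonized through
an ortholog map; a source id mapping to several human genes credits every
target (the screening stage is recall-oriented, and the mapping report
logs the multiplicity for audit). Linkage membership is body-overlap only
(≥ 1 bp, no flank): whether a flank should apply is genuinely open, and
body-only is the conservative reading of interval containment.

The derived `Cross` flag is true iff evidence spans ≥ 2 distinct species
among {mouse, human, worm, fly}, with HuLink excluded from the species
tally. `Cross` is binary rather than graded by species count because the
score has a single bonus term. The initial list — the set scoring is
restricted to — is the union of the three microarray sources; the
`initial_sources` option restricts or extends it.

Scores are `S = Σ wᵢ·indicatorᵢ` under a named weighting matrix. The ten
presets use weights in {0.5, 1}; with those, every score is an exact
multiple of 0.5, so score distributions use exact-value bins and threshold
comparisons carry a 1e-9 tolerance only to guard custom floating-point
weights. Ranking ties break lexicographically by symbol, making every
ordering deterministic.

## GWAS arm

QC keeps markers with failure rate (1 − call rate) ≤ 0.05 and MAF ≥ 0.01.
An exact Hardy-Weinberg test (enumeration of heterozygote configurations
at fixed allele counts; monomorphic markers return p = 1) is applied in
controls at α = 1e-6 by default; threshold and group are configurable
because standard practice varies and the exclusion report makes the choice
visible. Exclusions are attributed to the first failing rule in the order
call rate → MAF → HWE; the order affects per-reason counts, never the
surviving set. MAF is computed from pooled cases+controls. A 2×2 allelic
chi-square (1 df, no continuity correction; zero-margin tables return
p = 1) is provided so synthetic genotype data can flow end to end; real
studies would normally import association p-values computed elsewhere.

A marker belongs to a gene iff its position lies in
[start − 10 kb, end + 10 kb], inclusive at both ends; one marker may
belong to several genes. Interval queries use an interval tree, but the
contract is the inclusive-bounds rule, not the data structure.

## Q-values

For a p-value vector of length m, π₀ is estimated as
`#{p > λ}/(m(1 − λ))` over λ ∈ {0.05, …, 0.95}, extrapolated to λ → 1
with a cubic smoothing spline and clipped to (1/m, 1]. Then
`q(i) = min over j with p(j) ≥ p(i) of π₀·m·p(j)/rank(j)`, with ties in p
sharing the max-rank q (which preserves monotonicity). π₀ := 1 recovers
the Benjamini-Hochberg step-up adjustment exactly, and `fixed:λ` variants
are exposed. Below m = 100 the λ-grid tail counts are too sparse for the
smoother and the estimator falls back to fixed λ = 0.5 with a warning.
Subset-restricted q-values are always recomputed inside the subset —
q-values depend on the whole vector, so slicing a global vector would be
wrong — and a marker mapped to several subset genes enters once.

One property the naive intuition gets wrong: under a global null the
minimum q-value is *not* typically near 1. For step-up FDR with
independent uniform p-values, P(min q ≤ α) = α·π₀ — roughly half of null
GWAS runs dip below q = 0.5. The calibration test asserts exactly this
law rather than the (false) expectation that null minima concentrate
near 1.

## Length-matched permutation evaluation

Longer genes host more markers, so comparing a gene set's q-value bin
occupancy against unmatched random sets would reward length, not signal.
For each score cutoff (≥ 0.5, 1, 1.5, 2 and, where used, = 2.5), B random
sets of the observed size are drawn uniformly without replacement from
genes within ±50 kb of the observed set's mean length (one pool per
cutoff, matched to the mean, per the evaluation design). On small
synthetic universes the pool can be thinner than the sample; the sampler
then doubles the tolerance until it suffices (each widening is warned);
disabling widening reproduces the strict behavior and raises instead.

The empirical p for a (cutoff × q-bin) cell is the fraction of
permutations whose bin *proportion* (count/subset size) strictly exceeds
the observed one. The strict comparison is the classical "larger than"
estimator; because it can return an anti-conservative 0, the add-one
estimator (x+1)/(B+1) is reported alongside. Cells with zero observed
markers are N/A. B defaults to 100 for screening; a winner is typically
re-run at B = 1000.

Matrices are ordered by smallest observed minimum q over all cutoffs,
with ties broken by more observed markers at q < 0.5 and then by the
smaller empirical p at the most stringent populated bin; the full
criterion values are emitted so the selection is auditable.

## Over-representation analysis

Query lists are tested against flat GMT collections with the
hypergeometric upper tail, computed as a log-space sum (`gammaln`) so
p-values of order 1e-40 on genome-sized backgrounds remain accurate, then
BH-adjusted within each collection (matching how per-category web tools
adjust; a global adjustment is configurable). The default background is
the supplied gene universe; an explicit integer N is accepted because
published tools use their own (unknown) backgrounds, which is also why
claims against published enrichment p-values are bounds, not equalities.
GO DAG propagation is out of scope — collections are flat sets.

The min-p baseline assigns each gene the smallest p among its mapped
markers and takes the top k. It is intentionally not corrected for gene
length; a test asserts the resulting length bias on null data, since that
bias is the point of the comparison.

## Synthetic-data generator

The generator emulates the study conditions, scaled to desk size:

- **Universe**: 2000 genes by default on four chromosomes (60/60/50/40 Mb),
  lengths lognormal(μ=10.1, σ=1.1) (median ≈ 24 kb, mean ≈ 45 kb —
  realistic human gene-length skew). Genes may overlap (real genomes do);
  a flag packs them disjointly for clean toy fixtures.
- **Evidence**: per-source counts default to ≈ 10% of the universe carrying
  microarray evidence with shorter chip/worm/fly lists (120/100/60/130/15/25),
  mirroring the relative sizes of the original sources. Sources within a
  species are drawn disjoint; the controlled quantity is the fraction of
  distinct evidence genes seen in ≥ 2 species, steered by a per-slot reuse
  probability solved from the target fraction (default 0.3) and verified
  to calibrate within binomial error. Worm and fly lists are emitted in
  their own id namespace with 1:1 ortholog maps so the harmonization path
  is always exercised.
- **GWAS**: 20,000 markers by default (density doubled inside gene±10 kb
  windows), 1205 cases / 700 controls when genotype counts are emitted.
  Null markers draw p ~ Uniform(0,1); markers in planted-gene windows draw
  p ~ Beta(a,1) with a = 0.2 by default (median p ≈ 0.03). The planted set
  is either explicit or the 25 genes with the broadest species support. A
  2% defect fraction receives low call rate, MAF < 1%, or an
  HWE-violating genotype distribution (inbreeding-style homozygote excess)
  to exercise each filter. Signal is planted at the p-value level rather
  than by simulating genotype effects because the evaluation arm consumes
  p-values; genotype emission exists to exercise QC, not to model LD,
  stratification, or realistic allele-frequency spectra — which is what
  passing tests do *not* demonstrate about real data.
- **Annotations**: ~50 random GMT sets plus one designated set loaded with
  planted genes at 20:1 membership odds, giving enrichment a known
  positive control.

Everything is keyed off one integer seed (stage-wise fan-out via stable
hashing), and identical configurations are byte-identical on disk.

## Recovery experiments

Two parameter-recovery experiments define what "the evaluation works"
means here. (1) *Planted subset*: the q-value minimum over markers in the
planted genes must undercut a random same-size gene subset in ≥ 18 of 20
seeded studies. (2) *Matrix recovery*: signal is planted in the WSM3
score ≥ 2 stratum and WSM3 must be selected against mouse-weighted WSM6
and uniform WSM9 in ≥ 16 of 20 seeds. The second experiment evaluates
matrices over the ≥ cutoffs only: equality strata (= 2.5) under
competitor matrices can collapse to tiny subsets consisting purely of
planted genes, and the minimum-q criterion would then reward them by
chance, making the generating matrix unidentifiable. Restricting to ≥
cutoffs keeps the experiment well-posed; at B = 30 recovery is 20/20 in
the shipped configuration.

## Problem sizes and numerical choices

Test and example runs use compact studies (400–2000 genes, 4000–20,000
markers, B = 10–200) chosen so the full suite runs in about a minute on
one CPU while every statistical check retains clear power; all the
properties verified (calibration, recovery, determinism, oracle
agreement) are size-independent. Degenerate inputs have defined behavior
throughout: empty p-vectors and empty gene subsets raise or warn
explicitly, monomorphic markers take HWE p = 1, zero-margin allelic
tables take p = 1, empty q-bins report N/A, and an empty score stratum is
skipped with its absence recorded in the report.

## Known limitations

- Evidence integration trusts the supplied lists; there is no
  probe-to-gene annotation or sequence-based orthology inference.
- The generator's GWAS has independent markers — no LD, so marker counts
  behave like effective counts, which flatters FDR methods relative to
  real chips.
- Weights are evaluated, not learned; the matrices are fixed hypotheses.
- Enrichment uses flat gene sets; ontology structure and term
  relationships are ignored.
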