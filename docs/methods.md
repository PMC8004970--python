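# Methods

## Setting

Maternal plasma cell-free DNA is a mixture: a fraction *f* (the fetal
fraction) of fragments derive from the fetus, the rest from the mother. The
fetus shares one allele per autosomal locus with the mother; the other is
paternally inherited. Amplicon-based MPS genotyping of such a mixture shows
the paternal allele as a minor signal riding on the maternal background —
at roughly *f*/2 of reads when the mother is homozygous — competing with
sequencing noise (SNPs) and PCR stutter (STRs). The pipeline turns per-locus
allele read counts for mother, alleged father, maternal plasma and
(optionally) a reference fetus into paternally-inherited-allele calls, a
fetal-fraction estimate and a combined paternity index (CPI).

## Genotype calling thresholds

All thresholds live in `nippt.config.CallingConfig`:

| parameter | default | meaning |
|---|---|---|
| `snp_min_depth` / `str_min_depth` | 15× / 10× | nonplasma locus depth minimum |
| `snp_het_ratio` / `str_het_ratio` | 0.2 / 0.35 | second/top count ratio for a heterozygote call (inclusive ≥) |
| `plasma_snp_min_depth` | 50× | plasma SNP evaluation gate |
| `snp_noise_threshold` | 0.02 | minor-allele fraction separating paternal signal from noise |
| `plasma_str_min_depth` / `plasma_ystr_min_depth` | 30× / 10× | plasma STR gates |
| `str_low_count_fraction` | 0.01 | STR noise filter (fraction of pre-filter locus depth; ≥ retained) |
| `stutter_sd_multiplier` | 3.0 | rule (1): ratio must exceed mean + 3·SD (strict >) |
| `other_position_factor` | 0.5 | rule (2): count must exceed half the corresponding parental (strict >) |

The 2% SNP threshold is applied to minor reads over total locus reads, and is
inclusive by default (`snp_noise_inclusive=False` switches to strict >).

## Plasma STR calling

Sequence simplification is greedy left-to-right run-length encoding against
the locus's declared repeat motifs: a run of ≥ 2 motif copies becomes a
variable block with its count erased; everything else is kept verbatim as
literal blocks. Two alleles differing only in variable-block counts share an
architecture; an undecomposable sequence gets a literal architecture and
forms a singleton group. A member's repeat-unit total is the sum of its
variable-block run lengths.

Within a group, members are processed in decreasing count order, starting
from the highest-count (parental) member. Each member is evaluated at its
repeat-unit offset from the **nearest already-accepted allele**, because a
plasma locus carries up to three true alleles (two maternal, one paternal)
and a stutter product sits next to whichever true allele spawned it, not
necessarily next to the single highest-count member. At offsets ±1 the
stutter-ratio test applies (rule 1); at other offsets the ladder test applies
(rule 2), with the corresponding parental being the member one repeat unit
closer to the reference. When no member occupies that rung the candidate
cannot be stutter-of-stutter and passes: rejecting it instead would
systematically discard true paternal alleles two or more repeat units from
the maternal ones whenever no stutter ladder connects them. Accepted members
immediately become references for the members below them — this is what lets
the second maternal allele anchor the classification of its own stutter.
Ties for parental go to the lexicographically smallest sequence
(deterministic).

Stutter statistics default to mean 0.08, SD 0.015 at N−1 and mean 0.02,
SD 0.008 at N+1, per locus unless overridden (`StutterModel`); real
kit-specific statistics should replace them when available. Y-STR calls are
compared with the alleged father's haplotype as match/mismatch only and are
never multiplied into the CPI; X-STRs are reported but likewise excluded.

## Fetal fraction

f̂ = mean over informative loci of 2·n_father/(n_father + n_mother), using
only loci where the mother is homozygous and an oPIA was detected — the only
configuration where n_father is unambiguously fetal-specific. Values are
clipped at 1, which only matters beyond f = 2/3 where the formula stops being
meaningful. Loci where the mother is heterozygous are excluded.

## Paternity index

Per locus, PI = Σ_G P(O|G)·P(G|GM,GAF) / Σ_G P(O|G)·P(G|GM,RM), summing over
all child genotypes constructible from the union of frequency-table,
observed and parental alleles. The observation model: each chromosomal copy
of a true allele drops out independently with probability *d* (heterozygous
allele missed with probability *d*, homozygote with *d*²); with probability
*c* one drop-in allele foreign to the true genotype appears, chosen with
population-frequency weights; two or more unexplained alleles have
likelihood zero (single-drop-in model). Parental genotypes are treated as
error-free — they come from high-input blood samples — so *d* and *c* apply
only to the plasma-inferred child profile, which is taken as the maternal
alleles plus the locus's oPIAs; loci skipped in plasma contribute PI = 1
(neutral) rather than being scored as whole-genotype dropout.

Transmission: a parent passes each allele with probability ½; with
probability μ the transmitted allele mutates — STRs stepwise with weight
decay 0.9 per repeat-unit distance (normalized so total off-allele mass is
exactly μ; default μ = 10⁻³), SNPs uniformly to the other bases (default
10⁻⁸). The random man's transmitted allele is frequency-drawn under
Hardy–Weinberg, mutation-marginalized. Unseen alleles get a floor frequency
of 5/(2N), N = 500 by default.

Default per-class likelihood parameters are calibration choices anchored to
the empirically observed plasma error structure: A-STR *d* = 0.58,
*c* = 0.16 (the observed per-ePIA dropout and per-oPIA drop-in rates); SNP
*d* = 0.24 (one minus the ~76% detection rate), *c* = 0.004 (the ~0.4% error
rate). All are exposed in `LikelihoodParams`.

Per-locus PIs are multiplied (log10-summed) within the iiSNP and A-STR
classes; the combined log10 CPI is their sum. Inclusion requires CPI
strictly above the LR threshold (reported at 10, 100, 1000 and 10,000);
exclusion requires CPI < 10⁻⁴; otherwise inconclusive.

## Synthetic data

The generator emulates the study conditions end to end: Hardy–Weinberg trio
genotypes from synthetic frequencies (SNP MAF ~ U(0.1, 0.5); STRs 6–12
consecutive repeat alleles, symmetric Dirichlet(1.5)); fetal fraction fixed
or log-uniform on [0.003, 0.5], spanning the 0.32%–50.3% range seen in real
plasma; per-locus depths lognormal with medians 600× (SNP), 450× (A-STR) and
400× (X/Y-STR) in plasma and 500× nonplasma, matching a multiplexed
MiSeq-class run shared across ~150 amplicons; fetal-template capture
decaying logistically around 160 bp at 0.05/bp (cffDNA is short, so long
amplicons lose fetal signal; the real functional form is unknown — the
logistic merely embodies the direction); stutter reads spawned at N−1/N+1 of
every true STR allele with ratios drawn from the same `StutterModel` the
caller uses (Normal, truncated at 0, Poisson counts; optional N−2 tail off
by default, matching the observation that nearly all STR false positives are
single-step stutter or microvariants); and per-read SNP miscalls at 0.2%,
below the 2% calling threshold. Gestational week is sampled but causally
disconnected from *f* by default, reflecting the absence of a
week–detection correlation in the data this models. One numpy Generator
drives every draw, so a seed fully determines a cohort.

Because stutter counts add Poisson noise on top of the Normal ratio draw,
the simulator's A-STR drop-in rate (~30%) runs above the 16% seen in the
real cohort; the acceptance properties do not depend on that rate. Not
modelled: read-level errors, PCR-cycle chemistry, linkage between loci,
population substructure, maternal or placental mosaicism. Passing tests
therefore demonstrate correctness of the analysis logic under the stated
mixture model, not performance on any particular instrument.

## Problem sizes and numerics

The test suite and the acceptance script use desk-scale computations
throughout: the 17-family reference-cohort aggregates are exact integer/
rational arithmetic; the PI engine is validated against brute-force
enumeration (≤ 6-allele loci, 60 randomized instances plus a derandomized
property test) at 1e-9 relative tolerance; fetal-fraction recovery uses 50
simulated cases at f ≥ 0.05 (mean relative error ≤ 20%, observed ~12%);
unrelated-trio separation uses 108 simulated negative tests at f ≥ 0.1
(zero inclusions at LR 10,000 observed); the monotonicity screens use 40
cases across f ∈ [0.005, 0.5]. These sizes make the full suite run in well
under a minute while leaving the binomial/Poisson sampling error far from
each assertion's margin.

## Known limitations

* The bundled panel's amplicon lengths are plausible stand-ins matching the
  published length distribution, not the proprietary kit values; supply a
  real panel TSV for production use.
* The dropout/drop-in parameters are cohort-level calibrations, not
  per-locus estimates; a real deployment should re-estimate them (and the
  stutter statistics) from its own validation data.
* The likelihood treats the plasma-inferred child profile as a genotype
  observation with dropout/drop-in, rather than modelling the mother+child
  mixture at read level; maternal alleles are therefore always "observed",
  which slightly biases child-genotype posteriors toward maternal alleles
  under both hypotheses.
* X-STR kinship likelihoods, alternative hypotheses (sibling, incest) and
  locus linkage are out of scope.
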