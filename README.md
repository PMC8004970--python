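# nippt

Noninvasive prenatal paternity testing (NIPPT) from massively parallel
sequencing read-count tables.

Cell-free DNA in maternal plasma contains a minor fetal component (the fetal
fraction *f*, typically well under 20% and carried on fragments mostly shorter
than 160 bp). Half of the fetal genome is paternally inherited, so paternity
can be tested before birth, without amniocentesis, by looking for paternally
inherited alleles (PIAs) in plasma sequencing data. This package implements
that analysis for a combined forensic panel of 94 identity-informative SNPs
(iiSNPs), 27 autosomal STRs, 7 X-STRs and 24 Y-STRs:

* **Nonplasma genotyping** of mother, alleged father and reference fetus from
  read counts (depth ≥ 15×/10× and heterozygote ratio ≥ 0.2/0.35 for
  SNPs/STRs). A fetal allele the mother lacks is an *expected* PIA (ePIA).
* **Plasma SNP analysis**: at ≥ 50× depth, the top non-maternal allele is an
  *observed* PIA (oPIA) when its read fraction reaches the 2% background-noise
  threshold. Fetal fraction is estimated at informative loci (mother
  homozygous, oPIA present) as *f* = 2·n<sub>father</sub> /
  (n<sub>father</sub> + n<sub>mother</sub>), averaged over loci.
* **Plasma STR analysis** under PCR stutter interference, in four steps:
  (1) drop sequences below 1% of locus depth; (2) drop sequences absent from
  the STR allele sequence database (supplemented with both parents' called
  alleles); (3) simplify each sequence to its repeat architecture and group
  identical architectures, the highest-count member being the *parental*
  allele; (4) call a non-parental member a *potential* (paternal) allele only
  if it beats the stutter expectation — at the N−1/N+1 positions its ratio to
  the neighbouring true allele must exceed the stutter-ratio mean + 3 SD, and
  at other positions its count must exceed half that of its corresponding
  parental one repeat-unit closer. oPIAs are the called alleles minus the
  maternal ones.
* **Paternity index** per locus with dropout, drop-in and mutation:

  PI = Σ<sub>G</sub> P(O | G) P(G | GM, GAF) / Σ<sub>G</sub> P(O | G) P(G | GM, random man)

  marginalizing over latent child genotypes G, where each true-allele copy
  drops out with probability *d*, at most one drop-in allele appears with
  probability *c* (frequency-weighted), and transmission allows stepwise STR
  mutation. Per-locus PIs are multiplied (iiSNP and A-STR only; X/Y-STRs are
  reported but never multiplied in) into the combined paternity index, with
  inclusion declared at CPI > 10⁴ and exclusion at CPI < 10⁻⁴.
* **Synthetic data**: a seeded generator produces complete cases — trio
  genotypes, nonplasma and plasma read tables with maternal/fetal mixture,
  logistic amplicon-length-dependent fetal capture, per-position stutter and
  SNP noise — so the whole pipeline is testable with no external data.

## Worked example

Simulate one family at fetal fraction 0.30 and analyse it:

```bash
nippt simulate --seed 11 --n-cases 1 --fetal-fraction 0.3 --out demo
nippt case demo/case1 --frequencies demo/frequencies.csv --str-db demo/str_database.tsv
```

```json
{
 "case_id": "case1",
 "prospective": false,
 "fetal_fraction": 0.2690652804555331,
 "n_informative_loci": 19,
 "snp":  {"n_expected": 20, "n_observed": 19, "n_correct": 19, "detection_rate": 0.95},
 "astr": {"n_expected": 15, "n_observed": 17, "n_correct": 12},
 "log10_cpi": {"iiSNP": 6.077937198232821, "A-STR": 5.630032343060028},
 "log10_cpi_combined": 11.707969541292849,
 "classification_lr10000": "inclusion"
}
```

Reading: 19 of the 20 expected paternal SNP alleles were seen in plasma (95%
detection), all consistent with the reference fetus; the fetal fraction
estimate (0.269) recovers the simulated 0.30; the combined log10 CPI of 11.7
far exceeds the inclusion threshold log10(10⁴) = 4, so paternity is included.
Analysing the same case with `--prospective` (no reference fetus) yields the
same CPI without the correctness columns. `nippt cohort` summarises a
directory of cases into per-case and threshold tables.

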