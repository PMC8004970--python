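"""Paternity index under dropout, drop-in and mutation.

The plasma-inferred child profile is noisy: a true (paternal) allele can fail
to be observed (dropout) and an artifact allele can be observed (drop-in).
The per-locus paternity index therefore marginalizes over latent child
genotypes G:

    PI = sum_G P(O | G) P(G | GM, GAF)  /  sum_G P(O | G) P(G | GM, random man)

where O is the observed allele set, GM/GAF the mother's and alleged father's
(error-free, high-depth) genotypes, and the random man's transmitted allele is
drawn from population frequencies under Hardy-Weinberg.

Observation model (single drop-in per locus): each chromosomal copy of a true
allele drops independently with probability d (a heterozygous allele is missed
with probability d, a homozygote with d^2); with probability c a single
drop-in allele appears, chosen with population frequency weights; more than
one unexplained observed allele has likelihood 0.

Transmission model: a parent passes each of its two alleles with probability
1/2; with probability mu the transmitted allele mutates — for STRs to another
repeat allele with weight decaying geometrically in the repeat-unit distance,
for SNPs uniformly to the other base(s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .panel import FrequencyTable

LR_THRESHOLDS = (10.0, 100.0, 1000.0, 10000.0)
EXCLUSION_CPI = 1e-4


@dataclass(frozen=True)
class LikelihoodParams:
    """Dropout/drop-in/mutation parameters of the observation and transmission models.

    Defaults are per-marker-class calibration choices: for A-STRs the
    per-allele dropout and per-locus drop-in match the empirically observed
    58% / 16%; for SNPs, dropout 0.24 (one minus the ~76% detection rate) and
    drop-in 0.004 (the ~0.4% error rate).  Mutation rates follow forensic
    convention: 1e-3 per meiosis with geometric step decay 0.9 for STRs, 1e-8
    for SNPs.
    """

    dropout: float = 0.24
    dropin: float = 0.004
    str_mutation_rate: float = 0.0
    str_step_decay: float = 0.9
    snp_mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dropout", "dropin", "str_mutation_rate", "snp_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1): got {v}")


SNP_PARAMS = LikelihoodParams(dropout=0.24, dropin=0.004, snp_mutation_rate=1e-8)
ASTR_PARAMS = LikelihoodParams(dropout=0.58, dropin=0.16, str_mutation_rate=1e-3)


def _repeat_value(allele: str) -> float | None:
    try:
        return float(allele)
    except ValueError:
        return None


def transmission_prob(
    child_allele: str,
    parent_genotype: tuple[str, str],
    allele_space: tuple[str, ...],
    params: LikelihoodParams,
    is_str: bool,
) -> float:
    """P(transmitted allele = child_allele | parent genotype), with mutation.

    Each parental allele is transmitted with probability 1/2; a transmitted
    allele x stays x with probability 1 - mu and mutates to allele b != x with
    probability mu * w(b) / sum w, where for STRs w(b) = decay^|rep(b)-rep(x)|
    over the allele space (so the total mutation mass over non-x alleles is
    exactly mu), and for SNPs w is uniform over the other alleles.
    """
    mu = params.str_mutation_rate if is_str else params.snp_mutation_rate
    total = 0.0
    for x in parent_genotype:
        if mu == 0.0:
            total += 0.5 * (1.0 if x == child_allele else 0.0)
            continue
        others = [b for b in allele_space if b != x]
        if x == child_allele or not others:
            total += 0.5 * (1.0 - mu if others else 1.0)
            continue
        if is_str:
            vx = _repeat_value(x)
            weights = []
            for b in others:
                vb = _repeat_value(b)
                if vx is None or vb is None:
                    weights.append(1.0)  # non-numeric labels: uniform
                else:
                    weights.append(params.str_step_decay ** abs(vb - vx))
            z = sum(weights)
            w = weights[others.index(child_allele)]
        else:
            z = float(len(others))
            w = 1.0
        total += 0.5 * mu * w / z
    return total


def obs_likelihood(
    observed: frozenset[str],
    genotype: tuple[str, str],
    params: LikelihoodParams,
    locus_freqs: dict[str, float],
    floor: float = 0.005,
) -> float:
    """P(observed allele set | true child genotype) under dropout + single drop-in."""
    d, c = params.dropout, params.dropin
    copies: dict[str, int] = {}
    for a in genotype:
        copies[a] = copies.get(a, 0) + 1
    p = 1.0
    for allele, k in copies.items():
        if allele in observed:
            p *= 1.0 - d**k
        else:
            p *= d**k
    unexplained = observed - set(genotype)
    if len(unexplained) > 1:
        return 0.0
    if len(unexplained) == 1:
        (a,) = unexplained
        p *= c * locus_freqs.get(a, floor)
    else:
        p *= 1.0 - c
    return p


def _genotype_prior_hp(
    genotype: tuple[str, str],
    gm: tuple[str, str],
    gaf: tuple[str, str],
    allele_space: tuple[str, ...],
    params: LikelihoodParams,
    is_str: bool,
) -> float:
    x, y = genotype
    p_xy = transmission_prob(x, gm, allele_space, params, is_str) * transmission_prob(
        y, gaf, allele_space, params, is_str
    )
    if x == y:
        return p_xy
    p_yx = transmission_prob(y, gm, allele_space, params, is_str) * transmission_prob(
        x, gaf, allele_space, params, is_str
    )
    return p_xy + p_yx


def _paternal_marginal(
    allele: str,
    allele_space: tuple[str, ...],
    locus_freqs: dict[str, float],
    params: LikelihoodParams,
    is_str: bool,
    floor: float,
) -> float:
    """P(random man transmits `allele`): frequency-weighted, mutation-marginalized."""
    mu = params.str_mutation_rate if is_str else params.snp_mutation_rate
    if mu == 0.0:
        return locus_freqs.get(allele, floor)
    total = 0.0
    for z in allele_space:
        total += locus_freqs.get(z, floor) * transmission_prob(allele, (z, z), allele_space, params, is_str)
    return total


def _genotype_prior_hd(
    genotype: tuple[str, str],
    gm: tuple[str, str],
    allele_space: tuple[str, ...],
    locus_freqs: dict[str, float],
    params: LikelihoodParams,
    is_str: bool,
    floor: float,
) -> float:
    x, y = genotype
    p_xy = transmission_prob(x, gm, allele_space, params, is_str) * _paternal_marginal(
        y, allele_space, locus_freqs, params, is_str, floor
    )
    if x == y:
        return p_xy
    p_yx = transmission_prob(y, gm, allele_space, params, is_str) * _paternal_marginal(
        x, allele_space, locus_freqs, params, is_str, floor
    )
    return p_xy + p_yx


def locus_pi(
    observed: frozenset[str],
    gm: tuple[str, str],
    gaf: tuple[str, str],
    locus_freqs: dict[str, float],
    params: LikelihoodParams,
    is_str: bool = False,
    floor: float = 0.005,
) -> float:
    """Per-locus paternity index marginalized over latent child genotypes.

    The latent-genotype space is built from the frequency table's alleles
    plus any observed or parental alleles (unseen ones get the floor
    frequency).
    """
    allele_space = tuple(dict.fromkeys([*locus_freqs, *observed, *gm, *gaf]))
    num = 0.0
    den = 0.0
    for pair in combinations_with_replacement(allele_space, 2):
        lik = obs_likelihood(observed, pair, params, locus_freqs, floor)
        if lik == 0.0:
            continue
        num += lik * _genotype_prior_hp(pair, gm, gaf, allele_space, params, is_str)
        den += lik * _genotype_prior_hd(pair, gm, allele_space, locus_freqs, params, is_str, floor)
    if den == 0.0:
        return 1.0 if num == 0.0 else math.inf
    return num / den


# ---------------------------------------------------------------------------
# combination


@dataclass
class LRResult:
    """Combined paternity index with threshold classification.

    Only iiSNP and A-STR loci contribute to the CPI; X- and Y-STRs are
    reported but never multiplied in.  Classification: inclusion when
    CPI > threshold, exclusion when CPI < 1e-4, otherwise inconclusive.
    """

    case_id: str
    per_locus_pi: dict[str, float] = field(default_factory=dict)
    log10_cpi_by_class: dict[str, float] = field(default_factory=dict)
    log10_cpi_combined: float = 0.0

    def included_at(self, threshold: float) -> bool:
        return self.log10_cpi_combined > math.log10(threshold)

    def classification(self, threshold: float = 10000.0) -> str:
        if self.log10_cpi_combined > math.log10(threshold):
            return "inclusion"
        if self.log10_cpi_combined < math.log10(EXCLUSION_CPI):
            return "exclusion"
        return "inconclusive"


def combine_cpi(
    per_locus_pi: dict[str, float],
    marker_classes: dict[str, str],
    case_id: str = "",
) -> LRResult:
    """Multiply per-locus PIs (sum log10) within iiSNP and A-STR classes and combine."""
    result = LRResult(case_id=case_id, per_locus_pi=dict(per_locus_pi))
    sums = {"iiSNP": 0.0, "A-STR": 0.0}
    for locus_id, pi in per_locus_pi.items():
        cls = marker_classes.get(locus_id)
        if cls not in sums:
            continue
        if pi <= 0:
            raise ValueError(f"{locus_id}: PI {pi} <= 0 is impossible under the model")
        sums[cls] += math.log10(pi)
    result.log10_cpi_by_class = sums
    result.log10_cpi_combined = sums["iiSNP"] + sums["A-STR"]
    return result
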