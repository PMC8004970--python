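"""Paternity-index engine vs closed forms and an exhaustive-enumeration oracle."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from nippt.paternity import (
    LikelihoodParams,
    combine_cpi,
    locus_pi,
    obs_likelihood,
    transmission_prob,
)

NOISELESS = LikelihoodParams(dropout=0.0, dropin=0.0)


# ------------------------------------------------------------- transmission


def test_mendelian_limit():
    space = ("12", "13", "14")
    assert transmission_prob("12", ("12", "13"), space, NOISELESS, True) == pytest.approx(0.5)
    assert transmission_prob("12", ("12", "12"), space, NOISELESS, True) == pytest.approx(1.0)
    assert transmission_prob("14", ("12", "13"), space, NOISELESS, True) == 0.0


def test_mutation_mass_sums_to_mu():
    """Total probability of transmitting a non-parental allele equals mu, and the
    step distribution favours near repeat counts geometrically."""
    params = LikelihoodParams(dropout=0, dropin=0, str_mutation_rate=1e-3, str_step_decay=0.9)
    space = tuple(str(n) for n in range(8, 18))
    probs = {a: transmission_prob(a, ("12", "12"), space, params, True) for a in space}
    assert sum(probs.values()) == pytest.approx(1.0, rel=1e-12)
    assert probs["12"] == pytest.approx(1 - 1e-3)
    off_mass = sum(v for a, v in probs.items() if a != "12")
    assert off_mass == pytest.approx(1e-3, rel=1e-12)
    assert probs["13"] > probs["14"] > probs["15"]
    assert probs["13"] / probs["14"] == pytest.approx(1 / 0.9)


def test_snp_mutation_to_alternate_base():
    params = LikelihoodParams(dropout=0, dropin=0, snp_mutation_rate=1e-8)
    space = ("A", "G")
    assert transmission_prob("G", ("A", "A"), space, params, False) == pytest.approx(1e-8)
    assert transmission_prob("A", ("A", "A"), space, params, False) == pytest.approx(1 - 1e-8)


# ------------------------------------------------------------- observation model


def oracle_obs_likelihood(observed, genotype, d, c, freqs, floor=0.005):
    """Independent enumeration over per-copy dropout patterns and the single
    drop-in outcome."""
    total = 0.0
    dropin_options = [(None, 1.0 - c)] + [(a, c * freqs.get(a, floor)) for a in freqs] + [
        (a, c * floor) for a in observed if a not in freqs
    ]
    for pattern in itertools.product([False, True], repeat=2):  # True = copy dropped
        p_pattern = 1.0
        surviving = set()
        for copy, dropped in zip(genotype, pattern):
            p_pattern *= d if dropped else (1.0 - d)
            if not dropped:
                surviving.add(copy)
        for dropin, p_in in dropin_options:
            if dropin is not None and dropin in genotype:
                # drop-in means an allele *foreign to the true genotype*
                # appears; coincident/resurrection events are not part of
                # the single-drop-in model
                continue
            result = surviving | ({dropin} if dropin else set())
            if result == set(observed):
                total += p_pattern * p_in
    return total


def test_obs_likelihood_worked_examples():
    freqs = {"A": 0.5, "B": 0.3, "C": 0.2}
    assert obs_likelihood(frozenset("AB"), ("A", "B"), NOISELESS, freqs) == pytest.approx(1.0)
    p = obs_likelihood(frozenset("A"), ("A", "B"), LikelihoodParams(dropout=0.1, dropin=0.0), freqs)
    assert p == pytest.approx(0.9 * 0.1)
    p = obs_likelihood(frozenset("AC"), ("A", "A"), LikelihoodParams(dropout=0.1, dropin=0.05), freqs)
    assert p == pytest.approx((1 - 0.01) * 0.05 * 0.2)


def test_two_unexplained_alleles_impossible_under_single_dropin():
    p = obs_likelihood(frozenset("ABC"), ("A", "A"), LikelihoodParams(dropout=0.1, dropin=0.05), {"A": 0.4, "B": 0.3, "C": 0.3})
    assert p == 0.0


@settings(derandomize=True, max_examples=300)
@given(
    g1=st.sampled_from("ABCD"),
    g2=st.sampled_from("ABCD"),
    observed=st.sets(st.sampled_from("ABCD"), max_size=2),
    d=st.floats(0.0, 0.9),
    c=st.floats(0.0, 0.5),
)
def test_obs_likelihood_matches_enumeration(g1, g2, observed, d, c):
    freqs = {"A": 0.4, "B": 0.3, "C": 0.2, "D": 0.1}
    params = LikelihoodParams(dropout=d, dropin=c)
    expected = oracle_obs_likelihood(observed, (g1, g2), d, c, freqs)
    got = obs_likelihood(frozenset(observed), (g1, g2), params, freqs)
    assert got == pytest.approx(expected, rel=1e-9, abs=1e-15)


# ------------------------------------------------------------- locus PI


def oracle_locus_pi(observed, gm, gaf, freqs, d, c, floor=0.005):
    """Exhaustive enumeration over (maternal pick, paternal pick / random-man
    allele, dropout pattern, drop-in): independent of the engine's closed forms.
    No mutation (mu = 0)."""
    alleles = list(dict.fromkeys([*freqs, *observed, *gm, *gaf]))

    def child_prob(observed, paternal_dist):
        total = 0.0
        for mat in gm:
            for pat, p_pat in paternal_dist:
                g = (mat, pat)
                total += 0.5 * p_pat * oracle_obs_likelihood(observed, g, d, c, freqs, floor)
        return total

    hp = [(a, 0.5) for a in gaf]
    hd = [(a, freqs.get(a, floor)) for a in alleles]
    num = child_prob(observed, hp)
    den = child_prob(observed, hd)
    if den == 0.0:
        return 1.0 if num == 0.0 else math.inf
    return num / den


# classic noise-free trio PI forms for a biallelic SNP, child compatible
def test_closed_form_trio_pi_all_snp_configurations():
    p, q = 0.6, 0.4
    freqs = {"A": p, "B": q}
    cases = [
        # (mother, child, father, expected PI)
        (("A", "A"), ("A", "A"), ("A", "A"), 1 / p),
        (("A", "A"), ("A", "A"), ("A", "B"), 1 / (2 * p)),
        (("A", "A"), ("A", "B"), ("B", "B"), 1 / q),
        (("A", "A"), ("A", "B"), ("A", "B"), 1 / (2 * q)),
        (("A", "B"), ("A", "A"), ("A", "A"), 1 / p),
        (("A", "B"), ("A", "A"), ("A", "B"), 1 / (2 * p)),
        (("A", "B"), ("B", "B"), ("B", "B"), 1 / q),
        (("A", "B"), ("A", "B"), ("A", "B"), 1 / (p + q)),  # (1/2)(p+q)... symmetric het
        (("A", "B"), ("A", "B"), ("A", "A"), 1 / (p + q)),
    ]
    for gm, child, gaf, expected in cases:
        pi = locus_pi(frozenset(child), gm, gaf, freqs, NOISELESS)
        assert pi == pytest.approx(expected, rel=1e-9), (gm, child, gaf)


def test_mismatching_father_excluded_when_noise_free():
    freqs = {"A": 0.6, "B": 0.4}
    pi = locus_pi(frozenset("AB"), ("A", "A"), ("A", "A"), freqs, NOISELESS)
    assert pi == 0.0


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    data=st.data(),
    d=st.floats(0.0, 0.6),
    c=st.floats(0.0, 0.3),
)
def test_locus_pi_matches_exhaustive_oracle(data, d, c):
    alleles = ["10", "11", "12", "13"]
    raw = [data.draw(st.floats(0.05, 1.0)) for _ in alleles]
    total = sum(raw)
    freqs = {a: r / total for a, r in zip(alleles, raw)}
    gm = tuple(sorted(data.draw(st.tuples(st.sampled_from(alleles), st.sampled_from(alleles)))))
    gaf = tuple(sorted(data.draw(st.tuples(st.sampled_from(alleles), st.sampled_from(alleles)))))
    observed = frozenset(data.draw(st.sets(st.sampled_from(alleles), max_size=3)))
    params = LikelihoodParams(dropout=d, dropin=c)
    expected = oracle_locus_pi(observed, gm, gaf, freqs, d, c)
    got = locus_pi(observed, gm, gaf, freqs, params, is_str=True)
    assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)


def test_pi_invariant_under_allele_relabeling():
    freqs = {"10": 0.5, "11": 0.3, "12": 0.2}
    params = LikelihoodParams(dropout=0.2, dropin=0.05)
    pi1 = locus_pi(frozenset({"10", "11"}), ("10", "10"), ("11", "12"), freqs, params)
    relabel = {"10": "21", "11": "22", "12": "23"}
    freqs2 = {relabel[a]: f for a, f in freqs.items()}
    pi2 = locus_pi(frozenset({"21", "22"}), ("21", "21"), ("22", "23"), freqs2, params)
    assert pi1 == pytest.approx(pi2, rel=1e-12)


# ------------------------------------------------------------- combination


def test_combine_cpi_sums_log10_by_class():
    pis = {"rs1": 10.0, "rs2": 100.0, "strA": 50.0, "x1": 1e6}
    classes = {"rs1": "iiSNP", "rs2": "iiSNP", "strA": "A-STR", "x1": "X-STR"}
    res = combine_cpi(pis, classes, "c")
    assert res.log10_cpi_by_class["iiSNP"] == pytest.approx(3.0)
    assert res.log10_cpi_by_class["A-STR"] == pytest.approx(math.log10(50.0))
    # X-STR never enters the combined CPI
    assert res.log10_cpi_combined == pytest.approx(3.0 + math.log10(50.0))


def test_combine_cpi_published_case_sums_and_thresholds():
    res = combine_cpi({"s": 10**6.27, "a": 10**3.76}, {"s": "iiSNP", "a": "A-STR"}, "9")
    assert res.log10_cpi_combined == pytest.approx(10.03, abs=1e-9)
    assert res.included_at(10000.0)
    res6 = combine_cpi({"s": 10**3.08, "a": 10**0.17}, {"s": "iiSNP", "a": "A-STR"}, "6")
    assert res6.log10_cpi_combined == pytest.approx(3.25, abs=1e-9)
    assert not res6.included_at(10000.0)
    assert res6.classification(10000.0) == "inconclusive"


def test_combine_cpi_neutral_profile_and_errors():
    res = combine_cpi({"rs1": 1.0, "strA": 1.0}, {"rs1": "iiSNP", "strA": "A-STR"})
    assert res.log10_cpi_combined == 0.0
    with pytest.raises(ValueError):
        combine_cpi({"rs1": 0.0}, {"rs1": "iiSNP"})
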