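"""Plasma STR filtering, sequence simplification, grouping and stutter rules."""

import numpy as np
import pytest

from nippt.config import CallingConfig
from nippt.genotyping import CALLED, GenotypeProfile, LocusGenotype
from nippt.panel import AlleleObservation, Marker, StrAlleleDatabase
from nippt.plasma_snp import PIAReport, LocusPiaRecord
from nippt.plasma_str import (
    StutterModel,
    filter_by_database,
    filter_low_count,
    group_and_call,
    simplify_sequence,
    str_opias,
    str_rates,
)

STR = Marker("strA", "A-STR", "2", 120, (("ATCT", True),))
COMPOUND = Marker("strB", "A-STR", "3", 140, (("TCTA", True), ("TCA", False), ("TCTA", True)))


def seq_obs(locus, *triples):
    return [AlleleObservation(locus, name, count, seq) for name, seq, count in triples]


# ---------------------------------------------------------------- low-count


def test_low_count_filter_boundary():
    obs = seq_obs(
        "strA",
        ("12", "ATCT" * 12, 9801),
        ("11", "ATCT" * 11, 100),  # exactly 1.00% -> retained
        ("10", "ATCT" * 10, 99),   # 0.99% -> removed
    )
    kept = filter_low_count(obs)
    assert {o.allele_name for o in kept} == {"12", "11"}


def test_low_count_single_sequence_always_retained():
    obs = seq_obs("strA", ("12", "ATCT" * 12, 3))
    assert filter_low_count(obs) == obs


# ---------------------------------------------------------------- database


def test_database_filter_with_parental_supplement():
    db = StrAlleleDatabase({"strA": {"ATCT" * 12: "population-db"}})
    obs = seq_obs(
        "strA",
        ("12", "ATCT" * 12, 500),     # in db
        ("13", "ATCT" * 13, 100),     # only in father's profile
        ("9", "ATCT" * 9, 80),        # nowhere
    )
    kept = filter_by_database(obs, db, "strA", parental_supplement={"ATCT" * 13})
    assert {o.allele_name for o in kept} == {"12", "13"}


def test_database_filter_requires_some_source():
    with pytest.raises(ValueError, match="empty"):
        filter_by_database([], StrAlleleDatabase(), "strA", ())


# ---------------------------------------------------------------- simplify


def test_simplify_erases_variable_repeat_counts():
    a = simplify_sequence("ATCT" * 11, ["ATCT"])
    b = simplify_sequence("ATCT" * 10, ["ATCT"])
    assert a.architecture == b.architecture
    assert a.repeat_units == 11 and b.repeat_units == 10


def test_simplify_keeps_interruptions_verbatim():
    s1 = simplify_sequence("TCTA" * 4 + "TCA" + "TCTA" * 8, ["TCTA"])
    s2 = simplify_sequence("TCTA" * 4 + "TCA" + "TCTA" * 7, ["TCTA"])
    assert s1.architecture == s2.architecture
    assert ("lit", "TCA") in s1.architecture.blocks
    assert s1.repeat_units == 12 and s2.repeat_units == 11


def test_simplify_distinguishes_motifs():
    a = simplify_sequence("ATCT" * 10, ["ATCT", "ATCG"])
    b = simplify_sequence("ATCG" * 10, ["ATCT", "ATCG"])
    assert a.architecture != b.architecture


def test_simplify_undecomposable_is_literal():
    s = simplify_sequence("GGGCCC", ["ATCT"])
    assert s.architecture.is_literal
    assert s.repeat_units == 0


# ---------------------------------------------------------------- grouping / stutter rules


def model(mean=0.08, sd=0.01):
    return StutterModel(default_minus1=(mean, sd), default_plus1=(0.02, 0.008))


def test_n_minus_1_above_mean_plus_3sd_is_potential():
    obs = seq_obs("strA", ("12", "ATCT" * 12, 1000), ("11", "ATCT" * 11, 120))
    call = group_and_call(obs, STR, model())  # threshold 0.08 + 3*0.01 = 0.11
    assert call.called_alleles == {"12", "11"}  # 0.12 > 0.11


def test_n_minus_1_within_stutter_range_not_called():
    obs = seq_obs("strA", ("12", "ATCT" * 12, 1000), ("11", "ATCT" * 11, 100))
    call = group_and_call(obs, STR, model())
    assert call.called_alleles == {"12"}  # 0.10 <= 0.11


def test_other_position_uses_half_corresponding_parental():
    obs = seq_obs(
        "strA",
        ("12", "ATCT" * 12, 1000),
        ("11", "ATCT" * 11, 120),
        ("10", "ATCT" * 10, 70),  # N-2: corresponding parental is the N-1 member (120)
    )
    call = group_and_call(obs, STR, model())
    assert "10" in call.called_alleles  # 70 > 60


def test_other_position_called_without_corresponding_member():
    """A distant member with no stutter ladder between it and the parental
    cannot be stutter-of-stutter and is called."""
    obs = seq_obs("strA", ("12", "ATCT" * 12, 1000), ("10", "ATCT" * 10, 70))
    call = group_and_call(obs, STR, model())
    assert call.called_alleles == {"12", "10"}


def test_groups_isolate_different_architectures():
    # a microvariant-like interruption allele forms its own group and is kept
    obs = seq_obs(
        "strB",
        ("12", "TCTA" * 2 + "TCA" + "TCTA" * 10, 900),
        ("11", "TCTA" * 2 + "TCA" + "TCTA" * 9, 80),
        ("10", "TCTA" * 10, 60),  # no interruption: different architecture
    )
    call = group_and_call(obs, COMPOUND, model())
    assert len(call.groups) == 2
    assert "10" in call.called_alleles  # parental of its own group
    assert "11" not in call.called_alleles  # stutter of the main group


def test_adding_reads_to_true_allele_never_removes_it():
    """Monotone filters: growing a true allele's count keeps it called."""
    base = 200
    for extra in (0, 200, 2000):
        obs = seq_obs("strA", ("12", "ATCT" * 12, 1000), ("13", "ATCT" * 13, base + extra))
        call = group_and_call(obs, STR, model())
        assert {"12", "13"} <= call.called_alleles


def _mother_with(alleles):
    prof = GenotypeProfile("m")
    prof.genotypes["strA"] = LocusGenotype(
        "strA", tuple(AlleleObservation("strA", a, 100, "ATCT" * int(a)) for a in alleles), 200, CALLED
    )
    return prof


def test_str_opias_subtract_maternal_alleles():
    obs = seq_obs("strA", ("12", "ATCT" * 12, 1000), ("13", "ATCT" * 13, 800))
    call = group_and_call(obs, STR, model())
    assert str_opias(call, _mother_with(("12",))) == {"13"}
    assert str_opias(call, _mother_with(("12", "13"))) == frozenset()


def test_str_rates_aggregation():
    def rep(expected, observed, correct):
        r = PIAReport("c", "A-STR")
        r.records["L"] = LocusPiaRecord(
            "L",
            epias=frozenset(f"e{i}" for i in range(expected)),
            opias=frozenset(f"o{i}" for i in range(observed)),
        )
        r.records["L"].correct = frozenset(f"o{i}" for i in range(correct))
        r.records["L"].false_positive = r.records["L"].opias - r.records["L"].correct
        return r

    rates = str_rates([rep(10, 6, 5), rep(10, 4, 3)])
    assert rates["dropout_rate"] == pytest.approx((20 - 8) / 20)
    assert rates["dropin_rate"] == pytest.approx(2 / 10)


def test_rule1_false_positive_rate_within_nominal_tail():
    """Stutter drawn from the model itself should pass the mean+3SD test at
    roughly the Gaussian tail mass (~0.13%); checked over 2000 simulated loci
    at high depth where Poisson counting noise is negligible."""
    rng = np.random.default_rng(42)
    m = model(0.08, 0.015)
    false_calls = 0
    n_loci = 2000
    for _ in range(n_loci):
        parental = 20000
        ratio = max(0.0, rng.normal(0.08, 0.015))
        stutter = rng.poisson(parental * ratio)
        obs = seq_obs("strA", ("12", "ATCT" * 12, parental), ("11", "ATCT" * 11, int(stutter)))
        call = group_and_call(obs, STR, m)
        if "11" in call.called_alleles:
            false_calls += 1
    # nominal tail 0.00135 -> expect ~2.7; allow generous sampling slack
    assert false_calls <= 12
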