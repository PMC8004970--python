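"""Plasma STR allele identification under stutter interference.

Detecting a paternally inherited STR allele in plasma is harder than for SNPs
because PCR stutter creates artifact sequences one or more repeat units away
from true alleles, at ratios comparable to the fetal signal.  The four-step
strategy implemented here:

1. **Low-count filter** — sequences below 1% of the locus depth are removed as
   PCR/sequencing noise.
2. **Database filter** — sequences absent from the STR allele sequence
   database (population database supplemented with both parents' called
   alleles) are removed.
3. **Sequence simplification and grouping** — each sequence is reduced to its
   repeat architecture (run-length encoding with repeat counts of variable
   blocks erased); sequences sharing an architecture form a group whose
   highest-count member is the *parental* allele.
4. **Stutter-threshold test** — a non-parental group member is a *potential*
   (paternal) allele iff its ratio to the parental exceeds mean + 3 SD of the
   stutter-ratio distribution at the N-1/N+1 positions, or, at other
   positions, its count is more than half that of its *corresponding*
   parental (the member one repeat-unit step closer to the parental).

The plasma STR genotype is the union of parental and potential alleles;
oPIAs are that union minus the maternal alleles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .config import CallingConfig, DEFAULT_CONFIG
from .genotyping import CALLED, GenotypeProfile
from .panel import AlleleObservation, Marker, StrAlleleDatabase
from .plasma_snp import PIAReport

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stutter model


@dataclass
class StutterModel:
    """Mean/SD of stutter ratio per locus and stutter position.

    Keyed by ``(locus_id, offset)`` with offsets in repeat units (-1 for N-1,
    +1 for N+1).  Loci/positions without an entry fall back to the global
    defaults; the defaults are configurable because stutter statistics are
    kit- and locus-specific.
    """

    entries: dict[tuple[str, int], tuple[float, float]] = field(default_factory=dict)
    default_minus1: tuple[float, float] = (0.08, 0.015)
    default_plus1: tuple[float, float] = (0.02, 0.008)

    def get(self, locus_id: str, offset: int) -> tuple[float, float]:
        key = (locus_id, offset)
        if key in self.entries:
            return self.entries[key]
        if offset == -1:
            return self.default_minus1
        if offset == 1:
            return self.default_plus1
        raise KeyError(f"no stutter entry for offset {offset}")

    def threshold(self, locus_id: str, offset: int, sd_multiplier: float = 3.0) -> float:
        mean, sd = self.get(locus_id, offset)
        return mean + sd_multiplier * sd


# ---------------------------------------------------------------------------
# sequence simplification


@dataclass(frozen=True)
class SimplifiedArchitecture:
    """Repeat architecture of an STR sequence.

    ``blocks`` is an ordered tuple of ``("var", motif)`` for variable repeat
    runs (counts erased) and ``("lit", text)`` for interruption/flank
    sequence retained verbatim.  Two alleles differing only in repeat counts
    of variable blocks share an architecture.
    """

    blocks: tuple[tuple[str, str], ...]

    def __str__(self) -> str:
        return "|".join(m + "*" if kind == "var" else m for kind, m in self.blocks)

    @property
    def is_literal(self) -> bool:
        return all(kind == "lit" for kind, _ in self.blocks)


@dataclass(frozen=True)
class SimplifiedSequence:
    sequence: str
    architecture: SimplifiedArchitecture
    repeat_units: int  # total repeats across variable blocks


def simplify_sequence(sequence: str, motifs: Sequence[str]) -> SimplifiedSequence:
    """Greedy left-to-right run-length simplification of an STR sequence.

    At each position the motif (from the locus's declared repeat motifs) with
    the longest run of at least two consecutive copies is consumed as a
    variable block; everything else accumulates into literal blocks.  A
    sequence with no repeat run at all gets a literal architecture equal to
    the raw sequence and forms a singleton group downstream.
    """
    blocks: list[tuple[str, str]] = []
    units = 0
    lit: list[str] = []
    i = 0
    n = len(sequence)
    while i < n:
        best_motif = None
        best_run = 0
        for m in motifs:
            lm = len(m)
            if lm == 0:
                continue
            k = 0
            while sequence[i + k * lm : i + (k + 1) * lm] == m:
                k += 1
            if k >= 2 and k * lm > best_run * (len(best_motif) if best_motif else 0):
                best_motif, best_run = m, k
        if best_motif is not None:
            if lit:
                blocks.append(("lit", "".join(lit)))
                lit = []
            blocks.append(("var", best_motif))
            units += best_run
            i += best_run * len(best_motif)
        else:
            lit.append(sequence[i])
            i += 1
    if lit:
        blocks.append(("lit", "".join(lit)))
    return SimplifiedSequence(sequence, SimplifiedArchitecture(tuple(blocks)), units)


# ---------------------------------------------------------------------------
# filters


def filter_low_count(
    observations: list[AlleleObservation],
    config: CallingConfig = DEFAULT_CONFIG,
) -> list[AlleleObservation]:
    """Drop sequences below 1% of the pre-filter locus depth (inclusive >= retained)."""
    depth = sum(o.read_count for o in observations)
    if depth <= 0:
        return []
    return [o for o in observations if o.read_count / depth >= config.str_low_count_fraction]


def filter_by_database(
    observations: list[AlleleObservation],
    db: StrAlleleDatabase,
    locus_id: str,
    parental_supplement: Iterable[str] = (),
) -> list[AlleleObservation]:
    """Keep sequences present in the database or among the parents' called alleles."""
    supplement = set(parental_supplement)
    if len(db) == 0 and not supplement:
        raise ValueError("empty STR database and no parental supplement: filter would drop everything")
    return [o for o in observations if db.contains(locus_id, o.allele_seq) or o.allele_seq in supplement]


# ---------------------------------------------------------------------------
# grouping and stutter testing


@dataclass
class GroupMember:
    observation: AlleleObservation
    repeat_units: int
    offset: int  # repeat-unit offset from the group's parental allele
    role: str = "member"  # parental | potential | stutter | rejected
    rule: str = ""


@dataclass
class ArchitectureGroup:
    architecture: SimplifiedArchitecture
    members: list[GroupMember]

    @property
    def parental(self) -> GroupMember:
        return next(m for m in self.members if m.role == "parental")


@dataclass
class LocusStrCall:
    locus_id: str
    status: str  # evaluated | skipped_low_depth
    depth: int
    groups: list[ArchitectureGroup] = field(default_factory=list)
    audit: list[dict] = field(default_factory=list)

    @property
    def called_alleles(self) -> frozenset[str]:
        names = set()
        for g in self.groups:
            for m in g.members:
                if m.role in ("parental", "potential"):
                    names.add(m.observation.allele_name)
        return frozenset(names)

    @property
    def called_observations(self) -> list[AlleleObservation]:
        return [
            m.observation
            for g in self.groups
            for m in g.members
            if m.role in ("parental", "potential")
        ]


def group_and_call(
    observations: list[AlleleObservation],
    marker: Marker,
    stutter_model: StutterModel,
    config: CallingConfig = DEFAULT_CONFIG,
) -> LocusStrCall:
    """Group filtered sequences by simplified architecture and test stutter rules.

    Within each group the highest-count member is the parental allele (ties
    broken toward the lexicographically smallest sequence).  The remaining
    members are processed in decreasing count order, each evaluated at its
    repeat-unit offset from the *nearest already-accepted allele* — a plasma
    locus holds two maternal alleles plus possibly a paternal one, and a
    stutter product sits next to whichever true allele spawned it, not
    necessarily next to the single highest-count member.  Members at offsets
    +-1 pass as potential alleles iff their ratio to the accepted allele's
    count strictly exceeds mean + 3 SD of the stutter ratio at that position;
    members at other offsets pass iff their count strictly exceeds half that
    of the corresponding parental one step closer (with no member at that
    rung they cannot be stutter-of-stutter and pass).  Accepted members
    immediately become reference alleles for the members below them.
    """
    depth = sum(o.read_count for o in observations)
    call = LocusStrCall(marker.locus_id, "evaluated", depth)
    motifs = marker.repeat_motifs or ()
    groups: dict[SimplifiedArchitecture, list[tuple[AlleleObservation, SimplifiedSequence]]] = {}
    for o in observations:
        simp = simplify_sequence(o.allele_seq, motifs)
        if simp.architecture.is_literal:
            # undecomposable: literal architecture unique to this raw sequence
            arch = SimplifiedArchitecture((("lit", o.allele_seq),))
            simp = SimplifiedSequence(o.allele_seq, arch, 0)
        groups.setdefault(simp.architecture, []).append((o, simp))

    for arch, items in groups.items():
        items = sorted(items, key=lambda t: (-t[0].read_count, t[0].allele_seq))
        parental_obs, parental_simp = items[0]
        members = [GroupMember(parental_obs, parental_simp.repeat_units, 0, role="parental", rule="max-count")]
        accepted = [members[0]]
        by_units = {parental_simp.repeat_units: members[0]}
        rest = []
        for o, simp in items[1:]:
            m = GroupMember(o, simp.repeat_units, simp.repeat_units - parental_simp.repeat_units)
            rest.append(m)
            # highest-count member per repeat count serves as the ladder rung
            if simp.repeat_units not in by_units:
                by_units[simp.repeat_units] = m
        for m in rest:  # already in decreasing count order
            ref = min(
                accepted,
                key=lambda a: (abs(m.repeat_units - a.repeat_units), -a.observation.read_count),
            )
            off = m.repeat_units - ref.repeat_units
            m.offset = off
            if off == 0:
                # same architecture and repeat count but different raw
                # sequence: not a stutter position; left uncalled
                m.role = "stutter"
                m.rule = f"duplicate repeat count {m.repeat_units}"
            elif abs(off) == 1:
                thr = stutter_model.threshold(marker.locus_id, off, config.stutter_sd_multiplier)
                ratio = m.observation.read_count / ref.observation.read_count
                m.role = "potential" if ratio > thr else "stutter"
                m.rule = f"N{off:+d} of {ref.observation.allele_name}: ratio {ratio:.4f} vs mean+3SD {thr:.4f}"
            else:
                rung_units = m.repeat_units - (1 if off > 0 else -1)
                corresponding = by_units.get(rung_units)
                if corresponding is None or corresponding is m:
                    # no stutter ladder between this member and the reference:
                    # it cannot be stutter-of-stutter, so it passes rule (2)
                    # against a zero reference count
                    m.role = "potential"
                    m.rule = f"offset {off:+d}: no member at corresponding repeat count {rung_units}"
                else:
                    half = config.other_position_factor * corresponding.observation.read_count
                    m.role = "potential" if m.observation.read_count > half else "stutter"
                    m.rule = (
                        f"offset {off:+d}: count {m.observation.read_count} vs "
                        f"half-corresponding {half:.1f}"
                    )
            if m.role == "potential":
                accepted.append(m)
            members.append(m)
        call.groups.append(ArchitectureGroup(arch, members))
        for m in members:
            call.audit.append(
                {
                    "locus_id": marker.locus_id,
                    "sequence": m.observation.allele_seq,
                    "allele_name": m.observation.allele_name,
                    "read_count": m.observation.read_count,
                    "group": str(arch),
                    "offset": m.offset,
                    "role": m.role,
                    "rule": m.rule,
                }
            )
    return call


def call_plasma_str(
    observations: list[AlleleObservation],
    marker: Marker,
    db: StrAlleleDatabase,
    mother: GenotypeProfile,
    father: GenotypeProfile,
    stutter_model: StutterModel,
    config: CallingConfig = DEFAULT_CONFIG,
) -> LocusStrCall:
    """Full four-step plasma STR call at one locus (depth gate included)."""
    depth = sum(o.read_count for o in observations)
    min_depth = config.plasma_ystr_min_depth if marker.marker_class == "Y-STR" else config.plasma_str_min_depth
    if depth < min_depth:
        return LocusStrCall(marker.locus_id, "skipped_low_depth", depth)
    kept = filter_low_count(observations, config)
    supplement = {
        o.allele_seq
        for profile in (mother, father)
        for geno in (profile.genotypes.get(marker.locus_id),)
        if geno is not None and geno.status == CALLED
        for o in geno.alleles
    }
    kept = filter_by_database(kept, db, marker.locus_id, supplement)
    if not kept:
        return LocusStrCall(marker.locus_id, "evaluated", depth)
    return group_and_call(kept, marker, stutter_model, config)


def str_opias(call: LocusStrCall, mother: GenotypeProfile) -> frozenset[str]:
    """Parental + potential alleles minus maternal alleles (by allele name)."""
    if call.status != "evaluated":
        return frozenset()
    return call.called_alleles - mother.alleles_at(call.locus_id)


def ystr_match(calls: dict[str, LocusStrCall], father: GenotypeProfile) -> dict[str, bool]:
    """Per-locus match/mismatch of plasma Y-STR calls against the alleged father.

    Y-STRs are haploid lineage markers: they support comparison but are never
    multiplied into the combined paternity index.
    """
    verdict = {}
    for locus_id, call in calls.items():
        if call.status != "evaluated" or not call.called_alleles:
            continue
        verdict[locus_id] = call.called_alleles <= father.alleles_at(locus_id)
    return verdict


def str_rates(reports: list[PIAReport]) -> dict:
    """Cohort dropout/drop-in rates and false-positive origin breakdown.

    dropout = (sum expected - sum correct) / sum expected;
    drop-in = sum false positives / sum observed.  NaN on zero denominators.
    """
    n_expected = sum(r.n_expected for r in reports)
    n_observed = sum(r.n_observed for r in reports)
    n_correct = sum(r.n_correct or 0 for r in reports)
    n_false = sum(r.n_false_positive or 0 for r in reports)
    origin = {"N-1": 0, "N+1": 0, "other": 0}
    for r in reports:
        for rec in r.records.values():
            for allele, cls in rec.stutter_origin.items():
                origin[cls] = origin.get(cls, 0) + 1
    return {
        "n_expected": n_expected,
        "n_observed": n_observed,
        "n_correct": n_correct,
        "n_false_positive": n_false,
        "dropout_rate": (n_expected - n_correct) / n_expected if n_expected else math.nan,
        "dropin_rate": n_false / n_observed if n_observed else math.nan,
        "false_positive_origin": origin,
    }
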