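"""Nonplasma genotype calling and expected paternally inherited alleles (ePIAs).

Mother, alleged father and reference fetus are typed from high-input samples
(blood, amniotic fluid / chorionic villus), so calling is simple thresholding:
a locus passes if its depth reaches the class-specific minimum (15x for SNPs,
10x for STRs); the top-count allele is always called, and the second allele is
called as a heterozygote iff the heterozygote ratio (second-highest / highest
count) reaches the class threshold (0.2 for SNPs, 0.35 for STRs).

An ePIA at a locus is any allele the fetus carries that the mother does not
(e.g. mother AA, fetus AB -> ePIA B): the paternal contribution one expects to
find in maternal plasma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import CallingConfig, DEFAULT_CONFIG
from .panel import AlleleObservation, Marker, SampleReadTable

logger = logging.getLogger(__name__)

CALLED = "called"
NO_CALL = "no_call_low_depth"


@dataclass(frozen=True)
class LocusGenotype:
    locus_id: str
    alleles: tuple[AlleleObservation, ...]  # called alleles, highest count first
    depth: int
    status: str
    het_ratio: float = 0.0

    @property
    def allele_names(self) -> frozenset[str]:
        return frozenset(a.allele_name for a in self.alleles)

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2


@dataclass
class GenotypeProfile:
    sample_id: str
    genotypes: dict[str, LocusGenotype] = field(default_factory=dict)

    def alleles_at(self, locus_id: str) -> frozenset[str]:
        geno = self.genotypes.get(locus_id)
        if geno is None or geno.status != CALLED:
            return frozenset()
        return geno.allele_names


@dataclass
class EpiaSet:
    case_id: str
    epias: dict[str, frozenset[str]] = field(default_factory=dict)

    def total(self) -> int:
        return sum(len(v) for v in self.epias.values())


def heterozygote_ratio(observations: list[AlleleObservation]) -> float:
    """Second-highest over highest allele count at a locus; 0 for a single allele."""
    counts = sorted((o.read_count for o in observations), reverse=True)
    if not counts or counts[0] == 0:
        raise ValueError("heterozygote ratio undefined: no reads at locus")
    if len(counts) == 1:
        return 0.0
    return counts[1] / counts[0]


def call_genotype(
    observations: list[AlleleObservation],
    marker: Marker,
    config: CallingConfig = DEFAULT_CONFIG,
) -> LocusGenotype:
    """Call a nonplasma genotype at one locus.

    Threshold comparisons are inclusive (>=).  A third allele above the
    heterozygote threshold triggers a contamination warning but the top two
    are still called.
    """
    locus_id = marker.locus_id
    depth = sum(o.read_count for o in observations)
    min_depth = config.snp_min_depth if marker.marker_class == "iiSNP" else config.str_min_depth
    het_threshold = config.snp_het_ratio if marker.marker_class == "iiSNP" else config.str_het_ratio
    if depth < min_depth:
        return LocusGenotype(locus_id, (), depth, NO_CALL)
    ranked = sorted(observations, key=lambda o: (-o.read_count, o.allele_name))
    ratio = heterozygote_ratio(observations)
    called = [ranked[0]]
    if len(ranked) > 1 and ratio >= het_threshold:
        called.append(ranked[1])
    if len(ranked) > 2 and ranked[2].read_count / ranked[0].read_count >= het_threshold:
        logger.warning(
            "%s: third allele %s above heterozygote threshold; possible contamination",
            locus_id,
            ranked[2].allele_name,
        )
    return LocusGenotype(locus_id, tuple(called), depth, CALLED, het_ratio=ratio)


def call_profile(
    table: SampleReadTable,
    panel: list[Marker],
    config: CallingConfig = DEFAULT_CONFIG,
) -> GenotypeProfile:
    """Call genotypes at every panel locus present in the sample.

    Y-STR loci with no reads (female samples) are reported as no-calls
    without warning.
    """
    profile = GenotypeProfile(sample_id=table.sample_id)
    for marker in panel:
        obs = table.observations.get(marker.locus_id)
        if not obs or all(o.read_count == 0 for o in obs):
            profile.genotypes[marker.locus_id] = LocusGenotype(marker.locus_id, (), 0, NO_CALL)
            continue
        profile.genotypes[marker.locus_id] = call_genotype(obs, marker, config)
    return profile


def expected_pias(
    mother: GenotypeProfile,
    fetus: GenotypeProfile,
    panel: list[Marker],
    marker_classes: tuple[str, ...] | None = None,
    case_id: str = "",
) -> EpiaSet:
    """Fetal alleles absent from the mother, per locus.

    Loci where either sample is a no-call are skipped rather than treated as
    zero ePIAs, so per-case ePIA counts vary with typing success.
    """
    result = EpiaSet(case_id=case_id)
    for marker in panel:
        if marker_classes and marker.marker_class not in marker_classes:
            continue
        gm = mother.genotypes.get(marker.locus_id)
        gf = fetus.genotypes.get(marker.locus_id)
        if gf is None or gf.status != CALLED:
            continue
        if marker.marker_class == "Y-STR":
            # mother carries no Y: every fetal Y allele is paternally inherited
            maternal: frozenset[str] = frozenset()
        else:
            if gm is None or gm.status != CALLED:
                continue
            maternal = gm.allele_names
        result.epias[marker.locus_id] = frozenset(gf.allele_names - maternal)
    return result
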