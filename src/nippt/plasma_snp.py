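"""Plasma SNP analysis: observed paternally inherited alleles and fetal fraction.

In maternal plasma the fetal genome is a minor component of the cell-free DNA,
so a paternally inherited SNP allele appears as a minor allele fraction on top
of the maternal background.  A locus is evaluated only at >=50x depth; the
highest-count non-maternal allele is an observed PIA (oPIA) when its fraction
of the locus depth clears the 2% background-noise threshold, and the inferred
plasma (child) genotype is the maternal alleles plus that minor allele.

The fetal fraction is estimated at informative loci (mother homozygous, oPIA
detected) as f = 2*n_father / (n_father + n_mother) — the factor 2 because the
fetus carries one paternal and one maternal haplotype — and averaged over loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .config import CallingConfig, DEFAULT_CONFIG
from .genotyping import CALLED, GenotypeProfile, EpiaSet
from .panel import AlleleObservation, Marker, SampleReadTable

logger = logging.getLogger(__name__)

EVALUATED = "evaluated"
SKIPPED = "skipped_low_depth"


@dataclass(frozen=True)
class PlasmaSnpCall:
    locus_id: str
    status: str
    depth: int
    major_alleles: tuple[AlleleObservation, ...] = ()  # maternal-consistent alleles
    minor_allele: AlleleObservation | None = None
    minor_fraction: float = 0.0

    @property
    def opias(self) -> frozenset[str]:
        return frozenset() if self.minor_allele is None else frozenset({self.minor_allele.allele_name})

    @property
    def inferred_genotype(self) -> frozenset[str]:
        names = {a.allele_name for a in self.major_alleles}
        if self.minor_allele is not None:
            names.add(self.minor_allele.allele_name)
        return frozenset(names)


@dataclass
class LocusPiaRecord:
    locus_id: str
    epias: frozenset[str]
    opias: frozenset[str]
    correct: frozenset[str] | None = None       # oPIAs consistent with the reference fetus
    false_positive: frozenset[str] | None = None
    stutter_origin: dict[str, str] = field(default_factory=dict)  # STR FP -> {"N-1","N+1","other"}


@dataclass
class PIAReport:
    """Per-case expected-vs-observed PIA bookkeeping for one marker class."""

    case_id: str
    marker_class: str
    records: dict[str, LocusPiaRecord] = field(default_factory=dict)
    has_reference: bool = True

    @property
    def n_expected(self) -> int:
        return sum(len(r.epias) for r in self.records.values())

    @property
    def n_observed(self) -> int:
        return sum(len(r.opias) for r in self.records.values())

    @property
    def n_correct(self) -> int | None:
        if not self.has_reference:
            return None
        return sum(len(r.correct or ()) for r in self.records.values())

    @property
    def n_false_positive(self) -> int | None:
        if not self.has_reference:
            return None
        return sum(len(r.false_positive or ()) for r in self.records.values())

    @property
    def detection_rate(self) -> float:
        """n_correct / n_expected; NaN when no ePIAs exist or no reference fetus."""
        if not self.has_reference or self.n_expected == 0:
            return math.nan
        return self.n_correct / self.n_expected


@dataclass
class FetalFractionEstimate:
    case_id: str
    per_locus: dict[str, float] = field(default_factory=dict)
    mean: float = math.nan

    @property
    def n_informative_loci(self) -> int:
        return len(self.per_locus)


def call_plasma_snp(
    observations: list[AlleleObservation],
    mother_alleles: frozenset[str],
    marker: Marker,
    config: CallingConfig = DEFAULT_CONFIG,
) -> PlasmaSnpCall:
    """Detect the paternal minor allele at one plasma SNP locus.

    At a biallelic SNP at most one oPIA can exist; if several non-maternal
    labels pass the threshold (sequencing artifact) the highest-count one is
    taken with a warning.
    """
    depth = sum(o.read_count for o in observations)
    if depth < config.plasma_snp_min_depth:
        return PlasmaSnpCall(marker.locus_id, SKIPPED, depth)
    major = tuple(
        sorted(
            (o for o in observations if o.allele_name in mother_alleles),
            key=lambda o: -o.read_count,
        )
    )
    candidates = sorted(
        (o for o in observations if o.allele_name not in mother_alleles),
        key=lambda o: (-o.read_count, o.allele_name),
    )
    minor = None
    fraction = 0.0
    passing = []
    for cand in candidates:
        frac = cand.read_count / depth
        ok = frac >= config.snp_noise_threshold if config.snp_noise_inclusive else frac > config.snp_noise_threshold
        if ok:
            passing.append((cand, frac))
    if passing:
        if len(passing) > 1:
            logger.warning(
                "%s: %d non-maternal alleles above noise threshold; taking highest-count",
                marker.locus_id,
                len(passing),
            )
        minor, fraction = passing[0]
    return PlasmaSnpCall(
        marker.locus_id, EVALUATED, depth, major_alleles=major, minor_allele=minor, minor_fraction=fraction
    )


def snp_pia_report(
    calls: dict[str, PlasmaSnpCall],
    epias: EpiaSet,
    reference_fetus: GenotypeProfile | None = None,
    case_id: str = "",
) -> PIAReport:
    """Compare observed plasma oPIAs with the expected set.

    With a reference fetus, an oPIA is correct iff the fetus carries that
    allele; without one (prospective mode) correctness fields stay None.
    """
    report = PIAReport(case_id=case_id, marker_class="iiSNP", has_reference=reference_fetus is not None)
    for locus_id, call in calls.items():
        epia = epias.epias.get(locus_id, frozenset())
        opia = call.opias if call.status == EVALUATED else frozenset()
        rec = LocusPiaRecord(locus_id=locus_id, epias=epia, opias=opia)
        if reference_fetus is not None:
            fetal = reference_fetus.alleles_at(locus_id)
            rec.correct = frozenset(a for a in opia if a in fetal)
            rec.false_positive = opia - rec.correct
        report.records[locus_id] = rec
    return report


def fetal_fraction(
    calls: dict[str, PlasmaSnpCall],
    mother: GenotypeProfile,
    case_id: str = "",
) -> FetalFractionEstimate:
    """Estimate fetal fraction from informative plasma SNP loci.

    Only loci where the mother is homozygous and an oPIA was detected enter
    the estimate: there n_father is unambiguously fetal-specific.  With zero
    informative loci the estimate is NaN.
    """
    est = FetalFractionEstimate(case_id=case_id)
    for locus_id, call in calls.items():
        if call.status != EVALUATED or call.minor_allele is None:
            continue
        geno = mother.genotypes.get(locus_id)
        if geno is None or geno.status != CALLED or geno.is_het:
            continue
        n_father = call.minor_allele.read_count
        n_mother = sum(o.read_count for o in call.major_alleles)
        if n_father + n_mother == 0:
            continue
        # clip at 1: the formula exceeds 1 only when fetal reads outnumber
        # maternal ones, outside the regime (f < 2/3) where it is meaningful
        est.per_locus[locus_id] = min(1.0, 2.0 * n_father / (n_father + n_mother))
    if est.per_locus:
        est.mean = sum(est.per_locus.values()) / len(est.per_locus)
    else:
        logger.warning("%s: no informative loci for fetal fraction", case_id or "case")
    return est
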