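"""Per-case orchestration and cohort-level reporting.

``run_case`` composes the full workflow — nonplasma genotype calling, expected
PIAs, plasma SNP/STR paternal-allele detection, fetal fraction, and the
combined paternity index — for one family.  ``summarize_cohort`` builds the
cohort tables (per-case log10 CPI matrix, aggregate dropout/drop-in rates,
inclusion percentages at each LR threshold for real vs unrelated trios), and
``correlation_analysis`` runs the rank-correlation screen of detection rate
against fetal fraction, gestational week and amplicon length.

The module also bundles a reference cohort of 17 families (per-case PIA counts
and log10 CPI values as published for the assay this pipeline models) whose
aggregates serve as fixed ground truth for the aggregation code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .config import CallingConfig, DEFAULT_CONFIG
from .genotyping import CALLED, EpiaSet, GenotypeProfile, call_profile, expected_pias
from .panel import FrequencyTable, Marker, SampleReadTable, StrAlleleDatabase
from .paternity import (
    ASTR_PARAMS,
    LR_THRESHOLDS,
    SNP_PARAMS,
    LikelihoodParams,
    LRResult,
    combine_cpi,
    locus_pi,
)
from .plasma_snp import (
    EVALUATED,
    FetalFractionEstimate,
    LocusPiaRecord,
    PIAReport,
    PlasmaSnpCall,
    call_plasma_snp,
    fetal_fraction,
    snp_pia_report,
)
from .plasma_str import LocusStrCall, StutterModel, call_plasma_str, str_opias, ystr_match


@dataclass
class CaseReport:
    case_id: str
    prospective: bool
    fetal_fraction_estimate: FetalFractionEstimate
    snp_calls: dict[str, PlasmaSnpCall]
    snp_report: PIAReport
    str_calls: dict[str, dict[str, LocusStrCall]]   # marker class -> locus -> call
    str_reports: dict[str, PIAReport]               # "A-STR", "X-STR"
    ystr_verdict: dict[str, bool]
    lr_result: LRResult
    epias: dict[str, EpiaSet] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _classify_stutter_origin(call: LocusStrCall, allele: str) -> str:
    for group in call.groups:
        for m in group.members:
            if m.observation.allele_name == allele and m.role in ("parental", "potential"):
                if m.offset == -1:
                    return "N-1"
                if m.offset == 1:
                    return "N+1"
                return "other"
    return "other"


def _str_report(
    calls: dict[str, LocusStrCall],
    mother: GenotypeProfile,
    epias: EpiaSet | None,
    reference_fetus: GenotypeProfile | None,
    marker_class: str,
    case_id: str,
) -> PIAReport:
    report = PIAReport(case_id=case_id, marker_class=marker_class, has_reference=reference_fetus is not None)
    for locus_id, call in calls.items():
        opia = str_opias(call, mother)
        epia = epias.epias.get(locus_id, frozenset()) if epias else frozenset()
        rec = LocusPiaRecord(locus_id=locus_id, epias=epia, opias=opia)
        if reference_fetus is not None:
            fetal = reference_fetus.alleles_at(locus_id)
            rec.correct = frozenset(a for a in opia if a in fetal)
            rec.false_positive = opia - rec.correct
            for a in rec.false_positive:
                rec.stutter_origin[a] = _classify_stutter_origin(call, a)
        report.records[locus_id] = rec
    return report


def run_case(
    tables: dict[str, SampleReadTable],
    panel: list[Marker],
    freqs: FrequencyTable,
    db: StrAlleleDatabase,
    config: CallingConfig = DEFAULT_CONFIG,
    stutter_model: StutterModel | None = None,
    snp_params: LikelihoodParams = SNP_PARAMS,
    astr_params: LikelihoodParams = ASTR_PARAMS,
    case_id: str = "",
) -> CaseReport:
    """Run the complete analysis for one family.

    Requires mother, alleged_father and plasma tables; a reference_fetus table
    is optional (without it the run is *prospective*: oPIAs and CPI are
    computed but correctness fields stay empty).
    """
    for role in ("mother", "alleged_father", "plasma"):
        if role not in tables:
            raise ValueError(f"missing mandatory sample: {role}")
    stutter_model = stutter_model or StutterModel()
    case_id = case_id or tables["plasma"].case_id or tables["plasma"].sample_id
    warnings_log: list[str] = []

    mother = call_profile(tables["mother"], panel, config)
    father = call_profile(tables["alleged_father"], panel, config)
    fetus = call_profile(tables["reference_fetus"], panel, config) if "reference_fetus" in tables else None

    epias: dict[str, EpiaSet] = {}
    if fetus is not None:
        for cls in ("iiSNP", "A-STR", "X-STR", "Y-STR"):
            epias[cls] = expected_pias(mother, fetus, panel, (cls,), case_id=case_id)

    plasma = tables["plasma"]
    by_class: dict[str, list[Marker]] = {}
    for m in panel:
        by_class.setdefault(m.marker_class, []).append(m)

    # plasma SNPs
    snp_calls: dict[str, PlasmaSnpCall] = {}
    for m in by_class.get("iiSNP", ()):
        geno = mother.genotypes.get(m.locus_id)
        if geno is None or geno.status != CALLED:
            continue
        obs = plasma.observations.get(m.locus_id, [])
        snp_calls[m.locus_id] = call_plasma_snp(obs, geno.allele_names, m, config)
    snp_report = snp_pia_report(snp_calls, epias.get("iiSNP", EpiaSet(case_id)), fetus, case_id)
    ff = fetal_fraction(snp_calls, mother, case_id)

    # plasma STRs
    str_calls: dict[str, dict[str, LocusStrCall]] = {"A-STR": {}, "X-STR": {}, "Y-STR": {}}
    for cls in ("A-STR", "X-STR", "Y-STR"):
        for m in by_class.get(cls, ()):
            if cls != "Y-STR":
                geno = mother.genotypes.get(m.locus_id)
                if geno is None or geno.status != CALLED:
                    continue
            obs = plasma.observations.get(m.locus_id, [])
            str_calls[cls][m.locus_id] = call_plasma_str(obs, m, db, mother, father, stutter_model, config)

    str_reports = {
        cls: _str_report(str_calls[cls], mother, epias.get(cls), fetus, cls, case_id)
        for cls in ("A-STR", "X-STR")
    }
    ystr = ystr_match(str_calls["Y-STR"], father)

    # paternity index over iiSNP + A-STR
    per_locus_pi: dict[str, float] = {}
    marker_classes = {m.locus_id: m.marker_class for m in panel}
    for m in [*by_class.get("iiSNP", ()), *by_class.get("A-STR", ())]:
        lid = m.locus_id
        gm = mother.genotypes.get(lid)
        gaf = father.genotypes.get(lid)
        if gm is None or gaf is None or gm.status != CALLED or gaf.status != CALLED:
            per_locus_pi[lid] = 1.0
            continue
        if m.marker_class == "iiSNP":
            call = snp_calls.get(lid)
            if call is None or call.status != EVALUATED:
                per_locus_pi[lid] = 1.0
                continue
            observed = call.inferred_genotype
            params, is_str = snp_params, False
        else:
            call = str_calls["A-STR"].get(lid)
            if call is None or call.status != "evaluated" or not call.called_alleles:
                per_locus_pi[lid] = 1.0
                continue
            observed = call.called_alleles | mother.alleles_at(lid)
            params, is_str = astr_params, True
        gm_t = tuple(a.allele_name for a in gm.alleles)
        gaf_t = tuple(a.allele_name for a in gaf.alleles)
        if len(gm_t) == 1:
            gm_t = gm_t * 2
        if len(gaf_t) == 1:
            gaf_t = gaf_t * 2
        per_locus_pi[lid] = locus_pi(
            frozenset(observed), gm_t, gaf_t, freqs.locus_table(lid), params,
            is_str=is_str, floor=freqs.floor,
        )
    lr = combine_cpi(per_locus_pi, marker_classes, case_id=case_id)

    return CaseReport(
        case_id=case_id,
        prospective=fetus is None,
        fetal_fraction_estimate=ff,
        snp_calls=snp_calls,
        snp_report=snp_report,
        str_calls=str_calls,
        str_reports=str_reports,
        ystr_verdict=ystr,
        lr_result=lr,
        epias=epias,
        warnings=warnings_log,
    )


# ---------------------------------------------------------------------------
# cohort summaries


@dataclass
class CohortSummary:
    per_case: pd.DataFrame
    threshold_table: pd.DataFrame
    aggregates: dict


def summarize_cohort(
    reports: list[CaseReport],
    unrelated_results: list[LRResult] | None = None,
    thresholds: tuple[float, ...] = LR_THRESHOLDS,
) -> CohortSummary:
    """Cohort tables: per-case log10 CPI matrix and inclusion rates by threshold."""
    rows = []
    for r in reports:
        rows.append(
            {
                "case": r.case_id,
                "opia_sum": r.snp_report.n_observed + r.str_reports["A-STR"].n_observed,
                "log10_cpi_snp": r.lr_result.log10_cpi_by_class.get("iiSNP", 0.0),
                "log10_cpi_astr": r.lr_result.log10_cpi_by_class.get("A-STR", 0.0),
                "log10_cpi_combined": r.lr_result.log10_cpi_combined,
                "fetal_fraction": r.fetal_fraction_estimate.mean,
                "snp_detection_rate": r.snp_report.detection_rate,
            }
        )
    per_case = pd.DataFrame(rows)
    combined = per_case["log10_cpi_combined"].to_numpy()
    trows = []
    for thr in sorted(thresholds, reverse=True):
        real_pct = float(100.0 * (combined > math.log10(thr)).mean()) if len(combined) else math.nan
        if unrelated_results:
            unrel = np.array([u.log10_cpi_combined for u in unrelated_results])
            unrel_pct = float(100.0 * (unrel > math.log10(thr)).mean())
        else:
            unrel_pct = math.nan
        trows.append({"lr_threshold": thr, "real_inclusion_pct": real_pct, "unrelated_inclusion_pct": unrel_pct})
    threshold_table = pd.DataFrame(trows)

    snp_reports = [r.snp_report for r in reports if not r.prospective]
    astr_reports = [r.str_reports["A-STR"] for r in reports if not r.prospective]
    aggregates = {}
    if snp_reports:
        n_exp = sum(r.n_expected for r in snp_reports)
        n_obs = sum(r.n_observed for r in snp_reports)
        n_cor = sum(r.n_correct for r in snp_reports)
        aggregates["snp"] = {
            "n_expected": n_exp,
            "n_observed": n_obs,
            "n_correct": n_cor,
            "detection_rate": n_cor / n_exp if n_exp else math.nan,
            "error_rate": (n_obs - n_cor) / n_obs if n_obs else math.nan,
        }
        from .plasma_str import str_rates

        aggregates["astr"] = str_rates(astr_reports)
    return CohortSummary(per_case=per_case, threshold_table=threshold_table, aggregates=aggregates)


def correlation_analysis(
    per_case: pd.DataFrame,
    predictors: tuple[str, ...] = ("fetal_fraction", "gestational_week", "amplicon_length"),
    response: str = "detection_rate",
    exclude_outlier: str | None = None,
) -> dict[str, tuple[float, float]]:
    """Spearman rank correlation of the detection rate against each predictor.

    Returns predictor -> (rho, two-sided p).  Constant predictors or responses
    yield (nan, nan).  ``exclude_outlier`` drops one case id before testing —
    an explicit choice, never automatic.
    """
    df = per_case
    if exclude_outlier is not None:
        df = df[df["case"] != exclude_outlier]
    out = {}
    for pred in predictors:
        if pred not in df.columns:
            continue
        sub = df[[pred, response]].dropna()
        if len(sub) < 3 or sub[pred].nunique() < 2 or sub[response].nunique() < 2:
            out[pred] = (math.nan, math.nan)
            continue
        rho, p = stats.spearmanr(sub[pred], sub[response])
        out[pred] = (float(rho), float(p))
    return out


# ---------------------------------------------------------------------------
# bundled reference cohort


def load_reference_pia_counts() -> pd.DataFrame:
    """Per-case expected/observed PIA counts of the bundled 17-family reference cohort."""
    with resources.as_file(resources.files("nippt") / "data" / "cohort_pia_counts.tsv") as path:
        return pd.read_csv(path, sep="\t")


def load_reference_log10_cpi() -> pd.DataFrame:
    """Per-case log10 CPI values (SNP-only and A-STR-only) of the reference cohort."""
    with resources.as_file(resources.files("nippt") / "data" / "cohort_log10_cpi.tsv") as path:
        return pd.read_csv(path, sep="\t")


def aggregate_pia_counts(df: pd.DataFrame) -> dict:
    """Cohort aggregates from per-case PIA count columns.

    SNP detection rate = correct / expected; SNP error rate = false / observed;
    A-STR dropout = (expected - correct)/expected and drop-in = false/observed;
    X-STR false-positive fraction = false/observed.
    """
    snp_exp = int(df["snp_epia"].sum())
    snp_obs = int(df["snp_opia"].sum())
    snp_fp = int(df["snp_fp"].sum())
    snp_cor = snp_obs - snp_fp
    astr_exp = int(df["astr_epia"].sum())
    astr_obs = int(df["astr_opia"].sum())
    astr_fp = int(df["astr_fp"].sum())
    astr_cor = astr_obs - astr_fp
    xstr_obs = int(df["xstr_opia"].sum())
    xstr_fp = int(df["xstr_fp"].sum())
    return {
        "snp_epia_total": snp_exp,
        "snp_opia_total": snp_obs,
        "snp_correct_total": snp_cor,
        "snp_detection_rate_pct": 100.0 * snp_cor / snp_exp,
        "snp_error_rate_pct": 100.0 * snp_fp / snp_obs,
        "astr_epia_total": astr_exp,
        "astr_opia_total": astr_obs,
        "astr_false_positive_total": astr_fp,
        "astr_dropout_rate_pct": 100.0 * (astr_exp - astr_cor) / astr_exp,
        "astr_dropin_rate_pct": 100.0 * astr_fp / astr_obs,
        "xstr_opia_total": xstr_obs,
        "xstr_false_positive_pct": 100.0 * xstr_fp / xstr_obs,
    }


def aggregate_log10_cpi(df: pd.DataFrame, thresholds: tuple[float, ...] = LR_THRESHOLDS) -> dict:
    """Cohort aggregates from per-case log10 CPI columns.

    Combined per-case log10 CPI is the SNP + A-STR sum; inclusion at a
    threshold T means log10 CPI > log10(T) (strict).
    """
    combined = df["log10_cpi_snp"] + df["log10_cpi_astr"]
    n = len(df)
    out = {
        "n_cases": n,
        "snp_mean_log10_cpi": float(df["log10_cpi_snp"].mean()),
        "astr_mean_log10_cpi": float(df["log10_cpi_astr"].mean()),
        "combined_log10_cpi": dict(zip(df["case"].astype(str), combined.round(10))),
    }
    for thr in sorted(thresholds, reverse=True):
        tag = f"{int(thr)}"
        lt = math.log10(thr)
        out[f"snp_inclusions_lr{tag}"] = int((df["log10_cpi_snp"] > lt).sum())
        out[f"astr_inclusions_lr{tag}"] = int((df["log10_cpi_astr"] > lt).sum())
        out[f"combined_inclusions_lr{tag}"] = int((combined > lt).sum())
        out[f"combined_inclusion_pct_lr{tag}"] = 100.0 * float((combined > lt).mean())
    return out
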