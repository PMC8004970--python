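"""Synthetic NIPPT case generator.

Emulates the statistical structure of maternal-plasma MPS data that the
analysis assumes: a maternal/fetal cell-free DNA mixture with a known fetal
fraction, amplicon-length-dependent capture of the short (<160 bp) fetal
template, per-position STR stutter with configurable ratio distributions, and
sub-percent SNP background noise.  Every stochastic draw flows through one
numpy Generator, so a seed fully determines the output.

What it does not emulate: read-level errors (FASTQ), PCR-cycle chemistry,
linkage between loci, and population substructure — genotypes are
Hardy-Weinberg draws from the synthetic frequency tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .panel import (
    AlleleObservation,
    FrequencyTable,
    Marker,
    SampleReadTable,
    StrAlleleDatabase,
    load_read_table,
    write_read_table,
)
from .plasma_str import StutterModel

BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """Study-condition knobs of the simulator.

    ``fetal_fraction`` fixes f for every case; ``None`` samples f log-uniform
    over [0.003, 0.5], spanning the 0.32%-50.3% range seen in real plasma.
    Fetal template capture decays logistically with amplicon length around
    160 bp (rate ``length_k`` per bp), embodying the short-fragment nature of
    cell-free fetal DNA.  Depths are lognormal per marker class with medians
    of a few hundred reads, matching a multiplexed MiSeq-class run.
    """

    n_cases: int = 17
    fetal_fraction: float | None = None
    fetal_fraction_range: tuple[float, float] = (0.003, 0.5)
    plasma_depth: dict = field(
        default_factory=lambda: {"iiSNP": 600.0, "A-STR": 450.0, "X-STR": 400.0, "Y-STR": 400.0}
    )
    depth_sigma: float = 0.3
    nonplasma_depth: float = 500.0
    nonplasma_sigma: float = 0.25
    length_k: float = 0.05       # logistic capture decay per bp
    length_midpoint: float = 160.0
    snp_noise: float = 0.002     # per-read miscall probability at SNP loci
    stutter: StutterModel = field(default_factory=StutterModel)
    stutter_tail: bool = False   # also generate N-2 stutter at a small ratio
    stutter_tail_ratio: tuple[float, float] = (0.01, 0.004)
    nonplasma_stutter: bool = True
    unrelated: bool = False      # alleged father unrelated to the fetus
    gestational_week_range: tuple[float, float] = (7.0, 24.0)
    male_fetus_prob: float = 0.5


@dataclass
class SyntheticCase:
    case_id: str
    tables: dict[str, SampleReadTable]          # role -> read table
    genotypes: dict[str, dict[str, tuple[str, ...]]]  # role -> locus -> alleles
    fetal_fraction: float
    fetus_sex: str
    gestational_week: float
    true_epias: dict[str, frozenset[str]]
    stutter_reads: set[tuple[str, str]]         # (locus_id, sequence) of stutter origin

    @property
    def true_epia_total(self) -> int:
        return sum(len(v) for v in self.true_epias.values())


# ---------------------------------------------------------------------------
# frequencies and allele sequences


def sample_frequencies(panel: list[Marker], rng: np.random.Generator) -> FrequencyTable:
    """Synthetic population frequencies: SNP MAF ~ U(0.1, 0.5); STR loci get
    6-12 consecutive repeat alleles with symmetric-Dirichlet frequencies."""
    freqs: dict[str, dict[str, float]] = {}
    for marker in panel:
        if marker.marker_class == "iiSNP":
            a, b = rng.choice(len(BASES), size=2, replace=False)
            maf = rng.uniform(0.1, 0.5)
            freqs[marker.locus_id] = {BASES[a]: 1.0 - maf, BASES[b]: maf}
        else:
            n_alleles = int(rng.integers(6, 13))
            start = int(rng.integers(7, 14))
            names = [str(start + i) for i in range(n_alleles)]
            p = rng.dirichlet(np.full(n_alleles, 1.5))
            p = np.round(p, 6)
            p[0] += 1.0 - p.sum()  # keep the sum exactly 1 after rounding
            freqs[marker.locus_id] = dict(zip(names, p.tolist()))
    return FrequencyTable(freqs)


def str_allele_seq(marker: Marker, repeat_count: int) -> str:
    """Construct the allele sequence with `repeat_count` total repeat units.

    Literal interruption blocks are kept verbatim; with several variable
    blocks the leading ones get two copies each and the last takes the rest,
    so every variable block parses as a repeat run under greedy
    simplification.
    """
    var_blocks = [i for i, (_, var) in enumerate(marker.motif_structure) if var]
    if not var_blocks:
        raise ValueError(f"{marker.locus_id}: no variable block in motif structure")
    counts = {i: 2 for i in var_blocks[:-1]}
    counts[var_blocks[-1]] = repeat_count - 2 * (len(var_blocks) - 1)
    if counts[var_blocks[-1]] < 2:
        raise ValueError(f"{marker.locus_id}: repeat count {repeat_count} too small for structure")
    parts = []
    for i, (motif, var) in enumerate(marker.motif_structure):
        parts.append(motif * counts[i] if var else motif)
    return "".join(parts)


def stutter_allele(marker: Marker, repeat_count: int, offset: int) -> tuple[str, str]:
    """Name and sequence of the stutter product `offset` repeat units away."""
    n = repeat_count + offset
    return str(n), str_allele_seq(marker, n)


def make_str_database(freqs: FrequencyTable, panel: list[Marker]) -> StrAlleleDatabase:
    """Population STR allele sequence database covering every frequency-table allele."""
    db = StrAlleleDatabase()
    for marker in panel:
        if not marker.is_str:
            continue
        for name in freqs.alleles(marker.locus_id):
            db.add(marker.locus_id, str_allele_seq(marker, int(name)), StrAlleleDatabase.POPULATION)
    return db


# ---------------------------------------------------------------------------
# genotypes


def _draw_genotype(freqs: FrequencyTable, locus_id: str, rng: np.random.Generator, ploidy: int = 2):
    names = freqs.alleles(locus_id)
    p = np.array([freqs.get(locus_id, a) for a in names])
    p = p / p.sum()
    picks = rng.choice(len(names), size=ploidy, p=p)
    return tuple(sorted(names[i] for i in picks))


def _sample_person(panel, freqs, rng, sex: str) -> dict[str, tuple[str, ...]]:
    geno = {}
    for m in panel:
        if m.marker_class in ("iiSNP", "A-STR"):
            geno[m.locus_id] = _draw_genotype(freqs, m.locus_id, rng, 2)
        elif m.marker_class == "X-STR":
            geno[m.locus_id] = _draw_genotype(freqs, m.locus_id, rng, 2 if sex == "F" else 1)
        else:  # Y-STR
            geno[m.locus_id] = _draw_genotype(freqs, m.locus_id, rng, 1) if sex == "M" else ()
    return geno


def _sample_fetus(panel, mother, father, rng, sex: str) -> dict[str, tuple[str, ...]]:
    geno = {}
    for m in panel:
        lid = m.locus_id
        if m.marker_class in ("iiSNP", "A-STR"):
            mat = mother[lid][rng.integers(2)]
            pat = father[lid][rng.integers(2)]
            geno[lid] = tuple(sorted((mat, pat)))
        elif m.marker_class == "X-STR":
            mat = mother[lid][rng.integers(2)]
            if sex == "F":
                geno[lid] = tuple(sorted((mat, father[lid][0])))
            else:
                geno[lid] = (mat,)
        else:
            geno[lid] = father[lid] if sex == "M" else ()
    return geno


# ---------------------------------------------------------------------------
# read synthesis


def _lognormal_depth(rng, median: float, sigma: float) -> int:
    return max(1, int(round(rng.lognormal(math.log(median), sigma))))


def _capture_prob(length: float, cfg: SimConfig) -> float:
    return 1.0 / (1.0 + math.exp(cfg.length_k * (length - cfg.length_midpoint)))


def _split_reads(alleles: tuple[str, ...], total: int, rng) -> dict[str, int]:
    if not alleles or total <= 0:
        return {}
    counts = rng.multinomial(total, np.full(len(alleles), 1.0 / len(alleles)))
    out: dict[str, int] = {}
    for a, c in zip(alleles, counts):
        out[a] = out.get(a, 0) + int(c)
    return out


def _snp_noise(counts: dict[str, int], cfg: SimConfig, rng) -> dict[str, int]:
    if cfg.snp_noise <= 0:
        return counts
    out = dict(counts)
    for base, n in counts.items():
        errs = rng.binomial(n, cfg.snp_noise)
        if errs == 0:
            continue
        out[base] -= errs
        others = [b for b in BASES if b != base]
        for target, k in zip(others, rng.multinomial(errs, np.full(3, 1 / 3))):
            if k:
                out[target] = out.get(target, 0) + int(k)
    return {b: c for b, c in out.items() if c > 0}


def _add_stutter(
    marker: Marker,
    counts: dict[str, int],
    cfg: SimConfig,
    rng,
    flagged: set[tuple[str, str]] | None = None,
) -> dict[str, int]:
    """Spawn stutter reads at N-1/N+1 (and optional N-2) of each true allele."""
    out = dict(counts)
    offsets = [(-1, cfg.stutter.get(marker.locus_id, -1)), (1, cfg.stutter.get(marker.locus_id, 1))]
    if cfg.stutter_tail:
        offsets.append((-2, cfg.stutter_tail_ratio))
    for name, n in counts.items():
        try:
            rep = int(name)
        except ValueError:
            continue
        for off, (mean, sd) in offsets:
            ratio = max(0.0, rng.normal(mean, sd))
            k = rng.poisson(n * ratio)
            if k <= 0:
                continue
            try:
                sname, _ = stutter_allele(marker, rep, off)
            except ValueError:
                continue
            out[sname] = out.get(sname, 0) + int(k)
            if flagged is not None and sname not in counts:
                flagged.add((marker.locus_id, sname))
    return out


def _to_observations(marker: Marker, counts: dict[str, int]) -> list[AlleleObservation]:
    obs = []
    for name, n in sorted(counts.items()):
        if n <= 0:
            continue
        if marker.is_str:
            try:
                seq = str_allele_seq(marker, int(name))
            except ValueError:
                seq = name
        else:
            seq = name
        obs.append(AlleleObservation(marker.locus_id, name, n, seq))
    return obs


def sample_case(
    panel: list[Marker],
    freqs: FrequencyTable,
    config: SimConfig,
    rng: np.random.Generator,
    case_id: str = "case1",
) -> SyntheticCase:
    """Generate one complete case: trio genotypes plus four read-count tables."""
    sex = "M" if rng.random() < config.male_fetus_prob else "F"
    gw = float(rng.uniform(*config.gestational_week_range))
    if config.fetal_fraction is not None:
        f = config.fetal_fraction
    else:
        lo, hi = config.fetal_fraction_range
        f = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    mother = _sample_person(panel, freqs, rng, "F")
    true_father = _sample_person(panel, freqs, rng, "M")
    alleged = _sample_person(panel, freqs, rng, "M") if config.unrelated else true_father
    fetus = _sample_fetus(panel, mother, true_father, rng, sex)

    true_epias = {
        m.locus_id: frozenset(fetus[m.locus_id]) - frozenset(mother[m.locus_id])
        for m in panel
        if fetus[m.locus_id]
    }

    stutter_reads: set[tuple[str, str]] = set()
    tables: dict[str, SampleReadTable] = {}

    # nonplasma samples: high-input gDNA, balanced allele coverage
    for role, geno in (("mother", mother), ("alleged_father", alleged), ("reference_fetus", fetus)):
        observations = {}
        for m in panel:
            alleles = geno[m.locus_id]
            if not alleles:
                continue
            depth = _lognormal_depth(rng, config.nonplasma_depth, config.nonplasma_sigma)
            counts = _split_reads(alleles, depth, rng)
            if m.is_str and config.nonplasma_stutter:
                counts = _add_stutter(m, counts, config, rng)
            elif not m.is_str:
                counts = _snp_noise(counts, config, rng)
            obs = _to_observations(m, counts)
            if obs:
                observations[m.locus_id] = obs
        tables[role] = SampleReadTable(
            sample_id=f"{case_id}_{role}", role=role, observations=observations, case_id=case_id
        )

    # plasma: maternal/fetal mixture with length-dependent fetal capture
    observations = {}
    for m in panel:
        capture = _capture_prob(m.amplicon_length, config)
        depth = _lognormal_depth(rng, config.plasma_depth[m.marker_class], config.depth_sigma)
        if m.marker_class == "Y-STR":
            if sex != "M" or not fetus[m.locus_id]:
                continue
            n_fet = rng.binomial(depth, f * capture)
            counts = _split_reads(fetus[m.locus_id], n_fet, rng)
        else:
            f_eff = f * capture / (f * capture + (1.0 - f))
            n_fet = rng.binomial(depth, f_eff)
            counts = _split_reads(mother[m.locus_id], depth - n_fet, rng)
            for a, c in _split_reads(fetus[m.locus_id], n_fet, rng).items():
                counts[a] = counts.get(a, 0) + c
        if m.is_str:
            counts = _add_stutter(m, counts, config, rng, flagged=stutter_reads)
        else:
            counts = _snp_noise(counts, config, rng)
        obs = _to_observations(m, counts)
        if obs:
            observations[m.locus_id] = obs
    tables["plasma"] = SampleReadTable(
        sample_id=f"{case_id}_plasma",
        role="plasma",
        observations=observations,
        case_id=case_id,
        gestational_week=gw,
    )

    return SyntheticCase(
        case_id=case_id,
        tables=tables,
        genotypes={
            "mother": mother,
            "true_father": true_father,
            "alleged_father": alleged,
            "reference_fetus": fetus,
        },
        fetal_fraction=f,
        fetus_sex=sex,
        gestational_week=gw,
        true_epias=true_epias,
        stutter_reads=stutter_reads,
    )


def write_case(case: SyntheticCase, directory) -> None:
    """Write the four read tables plus a ground-truth JSON into a case directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for role, table in case.tables.items():
        write_read_table(table, directory / f"{role}.tsv")
    truth = {
        "case_id": case.case_id,
        "fetal_fraction": case.fetal_fraction,
        "fetus_sex": case.fetus_sex,
        "gestational_week": case.gestational_week,
        "true_epias": {k: sorted(v) for k, v in case.true_epias.items()},
        "genotypes": {role: {k: list(v) for k, v in g.items()} for role, g in case.genotypes.items()},
        "stutter_reads": sorted(list(t) for t in case.stutter_reads),
    }
    with open(directory / "truth.json", "wt", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)


def read_case_tables(directory, panel: list[Marker]) -> dict[str, SampleReadTable]:
    directory = Path(directory)
    tables = {}
    for role in ("mother", "alleged_father", "reference_fetus", "plasma"):
        path = directory / f"{role}.tsv"
        if path.exists():
            tables[role] = load_read_table(path, panel, role=role)
    return tables
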