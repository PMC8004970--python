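"""Marker panel data model and readers/writers for the pipeline's tabular inputs.

All inputs are plain UTF-8 text with a mandatory header row:

* panel: TSV ``locus_id, marker_class, chromosome, amplicon_length, motif_structure``
* read counts: TSV ``sample_id, locus_id, allele_name, allele_seq, read_count``
* population frequencies: CSV ``locus_id, allele_name, frequency``
* STR allele sequence database: TSV ``locus_id, allele_seq, allele_name, source``

STR alleles carry both a full sequence string (used by the plasma STR filters)
and a repeat-based name such as ``"12"`` (used by the likelihood engine); SNP
rows put the base in both columns.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

MARKER_CLASSES = ("iiSNP", "A-STR", "X-STR", "Y-STR")

PANEL_COLUMNS = ["locus_id", "marker_class", "chromosome", "amplicon_length", "motif_structure"]
READ_TABLE_COLUMNS = ["sample_id", "locus_id", "allele_name", "allele_seq", "read_count"]
FREQ_COLUMNS = ["locus_id", "allele_name", "frequency"]
STR_DB_COLUMNS = ["locus_id", "allele_seq", "allele_name", "source"]

SAMPLE_ROLES = ("mother", "alleged_father", "reference_fetus", "plasma", "unrelated_male")


class PanelFormatError(ValueError):
    """A tabular input is malformed (missing column, bad delimiter...)."""


class PanelValidationError(ValueError):
    """A tabular input parsed but violates an invariant."""


@dataclass(frozen=True)
class Marker:
    """One locus of the targeted panel.

    ``motif_structure`` is an ordered tuple of ``(motif, variable)`` blocks for
    STR loci — ``variable=True`` blocks are repeat runs whose count varies
    between alleles, ``variable=False`` blocks are fixed interruptions — and is
    empty for SNPs.  ``amplicon_length`` matters because cell-free fetal DNA is
    mostly <160 bp, so long amplicons capture fetal template poorly.
    """

    locus_id: str
    marker_class: str
    chromosome: str
    amplicon_length: int
    motif_structure: tuple[tuple[str, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise PanelValidationError(
                f"{self.locus_id}: unknown marker_class {self.marker_class!r}; "
                f"expected one of {MARKER_CLASSES}"
            )
        if self.amplicon_length <= 0:
            raise PanelValidationError(f"{self.locus_id}: amplicon_length must be > 0")

    @property
    def is_str(self) -> bool:
        return self.marker_class != "iiSNP"

    @property
    def repeat_motifs(self) -> tuple[str, ...]:
        """Distinct motifs of the variable blocks, used by sequence simplification."""
        return tuple(dict.fromkeys(m for m, var in self.motif_structure if var))


@dataclass(frozen=True)
class AlleleObservation:
    """Read count for one allele (sequence) at one locus in one sample."""

    locus_id: str
    allele_name: str
    read_count: int
    allele_seq: str = ""

    def __post_init__(self) -> None:
        if not self.allele_name:
            raise PanelValidationError(f"{self.locus_id}: empty allele label")
        if self.read_count < 0:
            raise PanelValidationError(
                f"{self.locus_id}/{self.allele_name}: negative read_count {self.read_count}"
            )
        if not self.allele_seq:
            object.__setattr__(self, "allele_seq", self.allele_name)


@dataclass
class SampleReadTable:
    """All read-count observations of one sample, grouped by locus."""

    sample_id: str
    role: str
    observations: dict[str, list[AlleleObservation]]
    case_id: str = ""
    gestational_week: float | None = None

    def __post_init__(self) -> None:
        if self.role not in SAMPLE_ROLES:
            raise PanelValidationError(f"unknown sample role {self.role!r}")
        for locus, obs in self.observations.items():
            seen = set()
            for o in obs:
                key = (o.locus_id, o.allele_name)
                if key in seen:
                    raise PanelValidationError(f"duplicate observation {key} in {self.sample_id}")
                seen.add(key)

    def locus_depth(self, locus_id: str) -> int:
        return sum(o.read_count for o in self.observations.get(locus_id, ()))

    def loci(self) -> list[str]:
        return list(self.observations)


class FrequencyTable:
    """Population allele frequencies with a minimum-frequency floor for unseen alleles.

    The floor defaults to 5/(2N) with N=500 reference individuals, the usual
    minimum-allele-frequency convention in forensic casework.
    """

    def __init__(self, freqs: Mapping[str, Mapping[str, float]], n_reference: int = 500):
        self._freqs: dict[str, dict[str, float]] = {
            locus: dict(alleles) for locus, alleles in freqs.items()
        }
        self.n_reference = n_reference
        for locus, alleles in self._freqs.items():
            if any(f <= 0 for f in alleles.values()):
                raise PanelValidationError(f"{locus}: non-positive frequency")
            total = sum(alleles.values())
            if abs(total - 1.0) > 0.01:
                raise PanelValidationError(f"{locus}: frequencies sum to {total:.4f}, not 1")

    @property
    def floor(self) -> float:
        return 5.0 / (2.0 * self.n_reference)

    def loci(self) -> list[str]:
        return list(self._freqs)

    def alleles(self, locus_id: str) -> list[str]:
        return list(self._freqs.get(locus_id, {}))

    def get(self, locus_id: str, allele_name: str) -> float:
        """Frequency of an allele; unseen alleles fall back to the floor."""
        return self._freqs.get(locus_id, {}).get(allele_name, self.floor)

    def locus_table(self, locus_id: str) -> dict[str, float]:
        return dict(self._freqs.get(locus_id, {}))


class StrAlleleDatabase:
    """Known STR allele sequences per locus, with provenance tags.

    The population database is supplemented with every allele called in either
    parent's nonplasma profile, so novel parental alleles are never filtered
    out of the plasma data.
    """

    POPULATION = "population-db"
    PARENTAL = "parental-supplement"

    def __init__(self, entries: Mapping[str, Mapping[str, str]] | None = None):
        # locus -> seq -> source tag
        self._entries: dict[str, dict[str, str]] = {
            locus: dict(seqs) for locus, seqs in (entries or {}).items()
        }

    def __len__(self) -> int:
        return sum(len(s) for s in self._entries.values())

    def contains(self, locus_id: str, allele_seq: str) -> bool:
        return allele_seq in self._entries.get(locus_id, ())

    def sequences(self, locus_id: str) -> set[str]:
        return set(self._entries.get(locus_id, ()))

    def add(self, locus_id: str, allele_seq: str, source: str = POPULATION) -> None:
        self._entries.setdefault(locus_id, {}).setdefault(allele_seq, source)

    def supplement_with_parents(self, *profiles) -> int:
        """Add every called parental allele; returns the number of new entries."""
        added = 0
        for profile in profiles:
            for locus_id, geno in profile.genotypes.items():
                if geno.status != "called":
                    continue
                for obs in geno.alleles:
                    if not self.contains(locus_id, obs.allele_seq):
                        self.add(locus_id, obs.allele_seq, self.PARENTAL)
                        added += 1
        return added


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing required column(s) {missing}")


def parse_motif_structure(text: str) -> tuple[tuple[str, bool], ...]:
    """Parse ``"TCTA*|TCA|TCTA*"`` into ((TCTA, True), (TCA, False), (TCTA, True)).

    A trailing ``*`` marks a variable repeat block; blocks without it are fixed
    interruption sequences.  Empty text (SNP rows) yields an empty structure.
    """
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return ()
    text = str(text).strip()
    if not text or text.lower() in ("na", "nan"):
        return ()
    blocks = []
    for block in text.split("|"):
        block = block.strip()
        if not block:
            continue
        if block.endswith("*"):
            blocks.append((block[:-1], True))
        else:
            blocks.append((block, False))
    return tuple(blocks)


def format_motif_structure(structure: tuple[tuple[str, bool], ...]) -> str:
    return "|".join(m + ("*" if var else "") for m, var in structure)


def load_panel(path) -> list[Marker]:
    """Load the marker panel TSV; returns markers in file order."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, PANEL_COLUMNS, path)
    if df.empty:
        return []
    dup = df["locus_id"][df["locus_id"].duplicated()]
    if not dup.empty:
        raise PanelValidationError(f"{path}: duplicate locus_id {sorted(set(dup))}")
    markers = []
    for row in df.itertuples(index=False):
        markers.append(
            Marker(
                locus_id=row.locus_id,
                marker_class=row.marker_class,
                chromosome=str(row.chromosome),
                amplicon_length=int(row.amplicon_length),
                motif_structure=parse_motif_structure(row.motif_structure),
            )
        )
    return markers


def default_panel_path():
    """Path of the bundled 152-marker panel fixture (94 iiSNP, 27 A-STR, 7 X-STR, 24 Y-STR).

    Per-locus amplicon lengths of commercial kits are proprietary; the bundled
    lengths are plausible values matching the published length distribution
    (>90% of SNP and ~78% of A-STR amplicons under 160 bp) and are
    user-replaceable by supplying another panel file.
    """
    return resources.files("nippt") / "data" / "panel_default.tsv"


def default_panel() -> list[Marker]:
    return load_panel(default_panel_path())


def load_read_table(
    path,
    panel: list[Marker] | None = None,
    *,
    sample_id: str | None = None,
    role: str = "plasma",
    case_id: str = "",
    gestational_week: float | None = None,
) -> SampleReadTable:
    """Load a per-sample read-count TSV.

    Metadata (role, case, gestational week) may be embedded as leading
    ``# key: value`` comment lines (as written by :func:`write_read_table`) or
    passed as keyword arguments; explicit arguments win.  Loci absent from the
    panel are dropped with a warning; duplicate (locus, allele) rows are summed.
    """
    meta: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", dtype={"read_count": "int64"}, comment="#")
    _require_columns(df, ["sample_id", "locus_id", "allele_name", "read_count"], path)
    if "allele_seq" not in df.columns:
        df["allele_seq"] = df["allele_name"]
    df["allele_seq"] = df["allele_seq"].fillna(df["allele_name"])
    if (df["read_count"] < 0).any():
        raise PanelValidationError(f"{path}: negative read_count")

    if sample_id is None:
        ids = df["sample_id"].unique().tolist() or [meta.get("sample_id", "sample")]
        if len(ids) > 1:
            raise PanelValidationError(f"{path}: multiple sample_ids {ids}; pass sample_id=")
        sample_id = str(ids[0])
    else:
        df = df[df["sample_id"] == sample_id]

    if panel is not None:
        known = {m.locus_id for m in panel}
        unknown = sorted(set(df["locus_id"]) - known)
        if unknown:
            warnings.warn(f"{path}: dropping {len(unknown)} loci absent from panel: {unknown[:5]}")
            df = df[df["locus_id"].isin(known)]

    grouped = (
        df.groupby(["locus_id", "allele_name"], sort=False)
        .agg(read_count=("read_count", "sum"), allele_seq=("allele_seq", "first"))
        .reset_index()
    )
    observations: dict[str, list[AlleleObservation]] = {}
    for row in grouped.itertuples(index=False):
        observations.setdefault(row.locus_id, []).append(
            AlleleObservation(
                locus_id=row.locus_id,
                allele_name=str(row.allele_name),
                allele_seq=str(row.allele_seq),
                read_count=int(row.read_count),
            )
        )
    gw = meta.get("gestational_week")
    return SampleReadTable(
        sample_id=sample_id,
        role=role if "role" not in meta else meta["role"],
        observations=observations,
        case_id=case_id or meta.get("case_id", ""),
        gestational_week=gestational_week if gestational_week is not None else (float(gw) if gw else None),
    )


def write_read_table(table: SampleReadTable, path) -> None:
    """Write a SampleReadTable as TSV with metadata comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for locus_id, obs in table.observations.items():
        for o in obs:
            rows.append((table.sample_id, locus_id, o.allele_name, o.allele_seq, o.read_count))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# role: {table.role}\n")
        if table.case_id:
            fh.write(f"# case_id: {table.case_id}\n")
        if table.gestational_week is not None:
            fh.write(f"# gestational_week: {table.gestational_week}\n")
        fh.write("\t".join(READ_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def load_frequencies(path, panel: list[Marker] | None = None, n_reference: int = 500) -> FrequencyTable:
    """Load a population allele-frequency CSV; per-locus sums must be 1 ± 0.01."""
    df = pd.read_csv(path, dtype={"frequency": "float64"})
    _require_columns(df, FREQ_COLUMNS, path)
    if panel is not None:
        known = {m.locus_id for m in panel}
        unknown = sorted(set(df["locus_id"]) - known)
        if unknown:
            warnings.warn(f"{path}: dropping {len(unknown)} loci absent from panel")
            df = df[df["locus_id"].isin(known)]
    freqs: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        freqs.setdefault(row.locus_id, {})[str(row.allele_name)] = float(row.frequency)
    return FrequencyTable(freqs, n_reference=n_reference)


def write_frequencies(table: FrequencyTable, path) -> None:
    rows = [
        (locus, allele, f)
        for locus in table.loci()
        for allele, f in table.locus_table(locus).items()
    ]
    pd.DataFrame(rows, columns=FREQ_COLUMNS).to_csv(path, index=False)


def load_str_database(path) -> StrAlleleDatabase:
    """Load an STR allele sequence database TSV (locus_id, allele_seq, allele_name, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, ["locus_id", "allele_seq"], path)
    db = StrAlleleDatabase()
    for row in df.itertuples(index=False):
        source = getattr(row, "source", None) or StrAlleleDatabase.POPULATION
        db.add(row.locus_id, row.allele_seq, source)
    return db


def write_str_database(db: StrAlleleDatabase, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(STR_DB_COLUMNS) + "\n")
        for locus in sorted(db._entries):
            for seq, source in db._entries[locus].items():
                fh.write(f"{locus}\t{seq}\t\t{source}\n")
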