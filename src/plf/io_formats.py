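"""Reading and writing the pipeline's external artifacts.

Covers SwissProt-style FASTA databases, exported peptide spectral-count
tables (delimited text, layout-agnostic via a column map), residue-level
site annotations (cleavage sites, domain boundaries), region result tables
and flat run configuration files.

All residue coordinates in this package are 1-based and inclusive
(SwissProt convention).  Region ``k`` of a protein covers residues
``[50k+1, 50k+50]`` for the default region size of 50.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
#: tolerated non-standard codes: unknown, selenocysteine, Asx, Glx
EXTENDED_RESIDUES = STANDARD_RESIDUES | set("XUBZ")

#: modification type -> residues it may sit on
MOD_RESIDUES = {
    "deamidation": set("NQ"),
    "oxidation_M": set("M"),
    "oxidation_K": set("K"),
    "oxidation_P": set("P"),  # hydroxyproline
    "carbamidomethyl": set("C"),
}


class FormatError(ValueError):
    """Malformed external input (FASTA, table, annotation or config)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database protein; the coordinate frame for every region index."""

    accession: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.accession!r}")
        bad = set(self.sequence) - EXTENDED_RESIDUES
        if bad:
            raise FormatError(
                f"{self.accession}: unexpected residue codes {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_nonstandard(self) -> bool:
        return bool(set(self.sequence) - STANDARD_RESIDUES)


@dataclass(frozen=True)
class ModificationSite:
    """A PTM on one residue of a peptide, 1-based within the peptide."""

    residue: str
    position_in_peptide: int
    mod_type: str

    def __post_init__(self) -> None:
        allowed = MOD_RESIDUES.get(self.mod_type)
        if allowed is None:
            raise FormatError(f"unknown modification type {self.mod_type!r}")
        if self.residue not in allowed:
            raise FormatError(
                f"{self.mod_type} not permitted on residue {self.residue!r}"
            )
        if self.position_in_peptide < 1:
            raise FormatError("modification position must be >= 1")


@dataclass(frozen=True)
class PeptideObservation:
    """One row of a sample's exported peptide list."""

    sample_id: str
    protein_accession: str
    peptide_sequence: str
    spectral_count: int
    modifications: tuple[ModificationSite, ...] = ()

    def __post_init__(self) -> None:
        if not self.peptide_sequence:
            raise FormatError("empty peptide sequence")
        if self.spectral_count < 0:
            raise FormatError("negative spectral count")
        for site in self.modifications:
            if site.position_in_peptide > len(self.peptide_sequence):
                raise FormatError(
                    f"modification position {site.position_in_peptide} outside "
                    f"peptide of length {len(self.peptide_sequence)}"
                )
            if self.peptide_sequence[site.position_in_peptide - 1] != site.residue:
                raise FormatError(
                    f"modification residue {site.residue} does not match peptide "
                    f"{self.peptide_sequence} at {site.position_in_peptide}"
                )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str    # e.g. juvenile | adult
    stratum: str  # e.g. male | female


@dataclass(frozen=True)
class StudyDesign:
    """Sample sheet: a between-sample group factor stratified by a second factor."""

    samples: tuple[SampleMeta, ...]
    group_factor: str = "age"
    strata_factor: str = "sex"

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate sample_id in study design")

    @property
    def group_levels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.group, None)
        return tuple(seen)

    @property
    def strata(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.stratum, None)
        return tuple(seen)

    def samples_in(self, stratum: str | None = None,
                   group: str | None = None) -> tuple[SampleMeta, ...]:
        out = [
            s for s in self.samples
            if (stratum is None or s.stratum == stratum)
            and (group is None or s.group == group)
        ]
        return tuple(out)

    def validate_counts(self, min_per_group: int = 2) -> None:
        for stratum in self.strata:
            for group in self.group_levels:
                n = len(self.samples_in(stratum, group))
                if n < min_per_group:
                    raise FormatError(
                        f"stratum {stratum!r} group {group!r} has {n} samples "
                        f"(need >= {min_per_group})"
                    )


@dataclass(frozen=True)
class SiteAnnotation:
    """A labelled residue position (e.g. an MMP cleavage site)."""

    protein_accession: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError("annotation position must be >= 1")


# ---------------------------------------------------------------------------
# FASTA

_SP_HEADER = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|]+)\|(?P<name>\S+)")


def _parse_header(header: str) -> tuple[str, str]:
    m = _SP_HEADER.match(header)
    if m:
        return m.group("acc"), m.group("name")
    # bare ">ACC optional description"
    parts = header.split(None, 1)
    return parts[0], parts[1] if len(parts) > 1 else parts[0]


def read_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a FASTA database into an accession-keyed mapping.

    Accepts the SwissProt ``sp|ACC|NAME`` header dialect as well as bare
    ``>ACC`` headers.  Wrapped sequence lines are concatenated.  Duplicate
    accessions and empty sequences are errors.
    """
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc, name = _parse_header(rec.description)
        if acc in records:
            raise FormatError(f"duplicate accession {acc!r} in {path}")
        records[acc] = ProteinRecord(acc, name, str(rec.seq).upper())
    return records


def write_fasta(records: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
                path: str | Path) -> None:
    if isinstance(records, Mapping):
        records = records.values()
    seq_records = [
        SeqRecord(Seq(r.sequence), id=f"sp|{r.accession}|{r.name}", description="")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# peptide tables

#: required semantic columns for a peptide table
REQUIRED_COLUMNS = ("sample", "accession", "peptide", "count")

DEFAULT_COLUMN_MAP = {
    "sample": "sample_id",
    "accession": "protein_accession",
    "peptide": "peptide_sequence",
    "count": "spectral_count",
    "modifications": "modifications",
}


@dataclass
class PeptideTable:
    """Accepted observations plus a rejects report (never silently dropped)."""

    observations: list[PeptideObservation]
    rejects: pd.DataFrame  # columns: row, reason, raw fields
    zero_count_rows: int = 0
    mod_warnings: list[str] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(o.spectral_count for o in self.observations)


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_peptide_table(path: str | Path,
                       column_map: Mapping[str, str] | None = None,
                       delimiter: str | None = None,
                       mod_dialect: str = "scaffold") -> PeptideTable:
    """Read an exported peptide spectral-count table.

    ``column_map`` binds semantic names (``sample``, ``accession``,
    ``peptide``, ``count``, optional ``modifications``) to the file's
    header names, keeping ingestion layout-agnostic.  Malformed rows land
    in the rejects report with a reason; zero-count rows are retained but
    counted.  The delimiter is auto-detected among comma/tab unless given.
    """
    from .ptm_regional import parse_modifications

    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    missing = [k for k in REQUIRED_COLUMNS if cmap[k] not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) "
            f"{[cmap[k] for k in missing]} (have {list(df.columns)})"
        )
    has_mods = cmap.get("modifications") in df.columns

    observations: list[PeptideObservation] = []
    rejects: list[dict] = []
    warnings: list[str] = []
    zero_rows = 0
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        try:
            count_str = raw[cmap["count"]].strip()
            try:
                count = int(count_str)
            except ValueError:
                raise FormatError(f"non-integer count {count_str!r}")
            if count < 0:
                raise FormatError("negative count")
            peptide = raw[cmap["peptide"]].strip().upper()
            mods: tuple[ModificationSite, ...] = ()
            if has_mods and raw[cmap["modifications"]].strip():
                sites, warns = parse_modifications(
                    raw[cmap["modifications"]], dialect=mod_dialect,
                    peptide=peptide,
                )
                mods = tuple(sites)
                warnings.extend(f"row {i}: {w}" for w in warns)
            obs = PeptideObservation(
                sample_id=raw[cmap["sample"]].strip(),
                protein_accession=raw[cmap["accession"]].strip(),
                peptide_sequence=peptide,
                spectral_count=count,
                modifications=mods,
            )
        except FormatError as exc:
            rejects.append({"row": i, "reason": str(exc), **raw})
            continue
        if count == 0:
            zero_rows += 1
        observations.append(obs)

    rej = pd.DataFrame(rejects, columns=["row", "reason", *df.columns])
    return PeptideTable(observations, rej, zero_rows, warnings)


def observations_to_frame(observations: Sequence[PeptideObservation]) -> pd.DataFrame:
    """Flatten observations to a tidy frame (modifications re-serialized)."""
    rows = []
    for o in observations:
        rows.append({
            "sample_id": o.sample_id,
            "protein_accession": o.protein_accession,
            "peptide_sequence": o.peptide_sequence,
            "spectral_count": o.spectral_count,
            "modifications": "; ".join(
                f"{_MOD_LABEL[s.mod_type]} {s.residue}{s.position_in_peptide}"
                for s in o.modifications
            ),
        })
    return pd.DataFrame(
        rows, columns=["sample_id", "protein_accession", "peptide_sequence",
                       "spectral_count", "modifications"])


_MOD_LABEL = {
    "deamidation": "Deamidated (+1)",
    "oxidation_M": "Oxidation (+16)",
    "oxidation_K": "Oxidation (+16)",
    "oxidation_P": "Oxidation (+16)",
    "carbamidomethyl": "Carbamidomethyl (+57)",
}


def write_peptide_table(observations: Sequence[PeptideObservation],
                        path: str | Path, delimiter: str = ",") -> None:
    observations_to_frame(observations).to_csv(path, index=False, sep=delimiter)


# ---------------------------------------------------------------------------
# design / annotations

def read_design(path: str | Path) -> StudyDesign:
    """Sample sheet CSV with columns sample_id, group, stratum."""
    df = pd.read_csv(path, dtype=str)
    need = {"sample_id", "group", "stratum"}
    if not need <= set(df.columns):
        raise FormatError(f"design file needs columns {sorted(need)}")
    samples = tuple(
        SampleMeta(r.sample_id, r.group, r.stratum)
        for r in df.itertuples(index=False)
    )
    return StudyDesign(samples)


def write_design(design: StudyDesign, path: str | Path) -> None:
    pd.DataFrame(
        [{"sample_id": s.sample_id, "group": s.group, "stratum": s.stratum}
         for s in design.samples]
    ).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Annotation CSV with columns accession, position, label."""
    df = pd.read_csv(path, dtype={"accession": str, "label": str})
    need = {"accession", "position", "label"}
    if not need <= set(df.columns):
        raise FormatError(f"annotation file needs columns {sorted(need)}")
    return [
        SiteAnnotation(str(r.accession), int(r.position), str(r.label))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# region results

RESULT_COLUMNS = [
    "protein_accession", "stratum", "region_index", "region_start", "region_end",
    "mean_norm_group1", "mean_norm_group2", "delta_avg_psc", "raw_diff",
    "F_stat", "p_raw", "p_adjusted", "star_level",
    "pass_alpha", "pass_diff", "pass_min_norm", "flagged",
]


def write_region_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write the per-(protein, stratum, region) result table; round-trippable."""
    if results is None or len(results) == 0:
        raise FormatError("refusing to write empty results table")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise FormatError(f"results table missing columns {missing}")
    results.loc[:, RESULT_COLUMNS].to_csv(path, index=False,
                                          quoting=csv.QUOTE_MINIMAL)


def read_region_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results table missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# flat run configuration

DEFAULT_CONFIG = {
    "region_size": 50,
    "overlap_policy": "full",
    "occurrence_policy": "first",
    "alpha": 0.05,
    "min_psc_difference": 2.0,
    "min_norm_psc_both_groups": 1.0,
    "transform": "sqrt",
    "seed": 0,
}


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise FormatError("config must be a flat key-value mapping")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(loaded)
    return cfg


def write_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
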