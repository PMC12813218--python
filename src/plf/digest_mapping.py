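"""In-silico tryptic digestion and mapping of peptides onto 50aa regions.

Trypsin cleaves C-terminal of lysine (K) or arginine (R), suppressed when
the next residue is proline.  Observed peptides are located in their parent
protein by exact substring match and their spectral counts accumulated into
fixed-size primary-structure regions (default 50 residues).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PeptideObservation, ProteinRecord, StudyDesign

logger = logging.getLogger(__name__)

OverlapPolicy = Literal["full", "proportional", "start"]
OccurrencePolicy = Literal["first", "all", "error"]


@dataclass(frozen=True)
class DigestParams:
    """Tryptic digest settings.

    ``detectable_length`` reflects the practical LC-MS/MS detection window:
    peptides shorter than ~6 or longer than ~25 residues are rarely
    identified (charge-state and m/z limits), so the simulated observable
    digest is restricted to that window by default.
    """

    max_missed_cleavages: int = 1
    detectable_length: tuple[int, int] = (6, 25)
    apply_length_filter: bool = True

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        lo, hi = self.detectable_length
        if lo > hi or lo < 1:
            raise ValueError("empty detectable length range")


@dataclass(frozen=True)
class LocatedPeptide:
    """A peptide placed at [start, end] (1-based, inclusive) in its protein."""

    protein_accession: str
    start: int
    end: int
    peptide_sequence: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid peptide span")
        if self.end - self.start + 1 != len(self.peptide_sequence):
            raise ValueError("span does not match peptide length")


@dataclass(frozen=True)
class RegionAssignment:
    region_index: int          # 0-based
    overlap_residues: int      # >= 1
    weight: float              # in (0, 1]


class PeptideNotFound(KeyError):
    pass


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1 (KP rule)."""
    return [
        i for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(sequence: str,
                   params: DigestParams = DigestParams()) -> list[LocatedPeptide]:
    """Enumerate tryptic peptides of ``sequence`` with missed cleavages.

    Every returned peptide is bounded by the protein termini or permitted
    cleavage points and contains at most ``max_missed_cleavages`` uncut
    internal K/R sites.  With ``apply_length_filter`` the result is
    restricted to the detectable length window.  Accession is left empty;
    callers attach it when the parent protein is known.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    bounds = [0] + [i + 1 for i in cleavage_sites(sequence)] + [len(sequence)]
    lo, hi = params.detectable_length
    out: list[LocatedPeptide] = []
    for i in range(len(bounds) - 1):
        for mc in range(params.max_missed_cleavages + 1):
            j = i + 1 + mc
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            length = end - start
            if params.apply_length_filter and not (lo <= length <= hi):
                continue
            out.append(LocatedPeptide("", start + 1, end, sequence[start:end]))
    return out


def locate_peptide(protein: ProteinRecord, peptide_sequence: str,
                   policy: OccurrencePolicy = "first") -> list[LocatedPeptide]:
    """Exact substring placement of a peptide in its parent protein.

    Collagens carry repetitive G-X-Y motifs, so multiple occurrences are a
    real possibility; ``policy`` selects first occurrence (default, logged),
    all occurrences, or an error.
    """
    if not peptide_sequence:
        raise ValueError("empty peptide sequence")
    hits: list[LocatedPeptide] = []
    pos = protein.sequence.find(peptide_sequence)
    while pos != -1:
        hits.append(LocatedPeptide(protein.accession, pos + 1,
                                   pos + len(peptide_sequence), peptide_sequence))
        pos = protein.sequence.find(peptide_sequence, pos + 1)
    if not hits:
        raise PeptideNotFound(
            f"peptide {peptide_sequence!r} not found in {protein.accession}")
    if len(hits) > 1:
        if policy == "error":
            raise ValueError(
                f"peptide {peptide_sequence!r} occurs {len(hits)} times in "
                f"{protein.accession}")
        if policy == "first":
            logger.warning("peptide %s occurs %d times in %s; using first",
                           peptide_sequence, len(hits), protein.accession)
            return hits[:1]
    return hits if policy == "all" else hits[:1]


def region_count(protein_length: int, region_size: int = 50) -> int:
    return math.ceil(protein_length / region_size)


def region_bounds(region_index: int, region_size: int,
                  protein_length: int) -> tuple[int, int]:
    """1-based inclusive residue bounds of a region (last one may be short)."""
    start = region_index * region_size + 1
    end = min((region_index + 1) * region_size, protein_length)
    return start, end


def assign_regions(peptide: LocatedPeptide, region_size: int = 50,
                   overlap_policy: OverlapPolicy = "full") -> list[RegionAssignment]:
    """Assign a located peptide to the region(s) its span overlaps.

    full:         full weight 1 to every overlapped region (a peptide
                  evidences every region it touches)
    proportional: weight split by residue overlap (sums to 1; conserves
                  total spectral count across regions)
    start:        all weight to the region containing the start residue
    """
    if region_size < 1:
        raise ValueError("region_size must be >= 1")
    first = (peptide.start - 1) // region_size
    last = (peptide.end - 1) // region_size
    length = peptide.end - peptide.start + 1
    if overlap_policy == "start":
        return [RegionAssignment(first, length, 1.0)]
    out = []
    for k in range(first, last + 1):
        r_start, r_end = k * region_size + 1, (k + 1) * region_size
        overlap = min(peptide.end, r_end) - max(peptide.start, r_start) + 1
        weight = 1.0 if overlap_policy == "full" else overlap / length
        out.append(RegionAssignment(k, overlap, weight))
    return out


@dataclass
class RegionMatrix:
    """samples x regions array of summed (possibly weighted) spectral counts.

    ``totals`` are the unweighted per-sample total spectral counts for the
    protein (the denominator of the median normalization).
    """

    protein_accession: str
    sample_ids: list[str]
    values: np.ndarray          # shape (n_samples, n_regions)
    totals: np.ndarray          # shape (n_samples,)
    region_size: int = 50
    protein_length: int = 0

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


@dataclass
class MappingResult:
    matrices: dict[str, RegionMatrix]
    #: observations that could not be placed, with reasons (never dropped silently)
    rejects: pd.DataFrame
    located: dict[tuple[str, str], LocatedPeptide] = field(default_factory=dict)

    @property
    def n_unlocatable(self) -> int:
        return len(self.rejects)


def build_region_matrix(observations: Sequence[PeptideObservation],
                        proteins: Mapping[str, ProteinRecord],
                        design: StudyDesign,
                        region_size: int = 50,
                        overlap_policy: OverlapPolicy = "full",
                        occurrence_policy: OccurrencePolicy = "first",
                        ) -> MappingResult:
    """Locate every observation and accumulate counts per 50aa region.

    ``values[s, k]`` sums ``spectral_count * weight`` over located peptides of
    sample ``s`` overlapping region ``k``; ``totals[s]`` sums raw spectral
    counts (unweighted), so under the proportional policy each row of
    ``values`` sums exactly to its total.  Observations whose accession is
    missing from the database or whose sequence cannot be placed go to the
    rejects report.
    """
    sample_ids = [s.sample_id for s in design.samples]
    sample_pos = {sid: i for i, sid in enumerate(sample_ids)}
    matrices: dict[str, RegionMatrix] = {}
    located_cache: dict[tuple[str, str], LocatedPeptide | None] = {}
    rejects: list[dict] = []

    for obs in observations:
        if obs.sample_id not in sample_pos:
            rejects.append({"sample_id": obs.sample_id,
                            "protein_accession": obs.protein_accession,
                            "peptide_sequence": obs.peptide_sequence,
                            "reason": "sample not in design"})
            continue
        protein = proteins.get(obs.protein_accession)
        if protein is None:
            rejects.append({"sample_id": obs.sample_id,
                            "protein_accession": obs.protein_accession,
                            "peptide_sequence": obs.peptide_sequence,
                            "reason": "accession not in FASTA"})
            continue
        key = (obs.protein_accession, obs.peptide_sequence)
        if key not in located_cache:
            try:
                located_cache[key] = locate_peptide(
                    protein, obs.peptide_sequence, occurrence_policy)[0]
            except PeptideNotFound:
                located_cache[key] = None
        located = located_cache[key]
        if located is None:
            rejects.append({"sample_id": obs.sample_id,
                            "protein_accession": obs.protein_accession,
                            "peptide_sequence": obs.peptide_sequence,
                            "reason": "peptide not found in protein"})
            continue

        mat = matrices.get(obs.protein_accession)
        if mat is None:
            n_reg = region_count(protein.length, region_size)
            mat = RegionMatrix(obs.protein_accession, list(sample_ids),
                               np.zeros((len(sample_ids), n_reg)),
                               np.zeros(len(sample_ids)),
                               region_size, protein.length)
            matrices[obs.protein_accession] = mat
        s = sample_pos[obs.sample_id]
        mat.totals[s] += obs.spectral_count
        for assn in assign_regions(located, region_size, overlap_policy):
            mat.values[s, assn.region_index] += obs.spectral_count * assn.weight

    rej = pd.DataFrame(rejects, columns=["sample_id", "protein_accession",
                                         "peptide_sequence", "reason"])
    located_ok = {k: v for k, v in located_cache.items() if v is not None}
    return MappingResult(matrices, rej, located_ok)
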