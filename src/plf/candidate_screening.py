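"""Biomarker-candidate screening over regional test results.

A 50aa region is flagged when all three criteria hold on the adjusted
scale: adjusted p <= alpha, absolute difference of group-mean normalized
PSC >= a minimum number of peptides, and a minimum mean normalized PSC in
*both* groups (so significance cannot be driven by a group with missing
values).  A protein becomes a candidate for a stratum only if it carries at
least one flagged region and was observed in every sample of that stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import PeptideObservation, StudyDesign
from .regional_statistics import NormalizedRegionMatrix, ProteinAnovaResult


@dataclass(frozen=True)
class ScreeningThresholds:
    """All three thresholds are inclusive (>= / <=) at their boundary."""

    alpha: float = 0.05
    min_psc_difference: float = 2.0
    min_norm_psc_both_groups: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.min_psc_difference,
               self.min_norm_psc_both_groups) <= 0:
            raise ValueError("screening thresholds must be strictly positive")


@dataclass
class RegionFlags:
    region_index: int
    pass_alpha: bool
    pass_diff: bool
    pass_min_norm: bool

    @property
    def flagged(self) -> bool:
        return self.pass_alpha and self.pass_diff and self.pass_min_norm


@dataclass
class CandidateProtein:
    accession: str
    stratum: str
    flagged_regions: list[int]
    presence_ok: bool
    region_flags: list[RegionFlags] = field(default_factory=list)

    @property
    def is_candidate(self) -> bool:
        return self.presence_ok and bool(self.flagged_regions)


def presence_in_all_samples(observations: Iterable[PeptideObservation],
                            design: StudyDesign, stratum: str,
                            accession: str) -> bool:
    """True iff the protein has >=1 nonzero-count observation in every
    sample of the stratum."""
    needed = {s.sample_id for s in design.samples_in(stratum)}
    seen = {o.sample_id for o in observations
            if o.protein_accession == accession and o.spectral_count > 0
            and o.sample_id in needed}
    return seen == needed


def screen_protein(result: ProteinAnovaResult,
                   presence_ok: bool,
                   thresholds: ScreeningThresholds = ScreeningThresholds(),
                   ) -> CandidateProtein:
    """Apply the three regional criteria to one protein-stratum result."""
    flags: list[RegionFlags] = []
    for r in result.regions:
        means = list(r.mean_norm.values())
        flags.append(RegionFlags(
            region_index=r.region_index,
            pass_alpha=r.p_adjusted <= thresholds.alpha,
            pass_diff=abs(r.delta_avg_psc) >= thresholds.min_psc_difference,
            pass_min_norm=min(means) >= thresholds.min_norm_psc_both_groups,
        ))
    flagged = [f.region_index for f in flags if f.flagged]
    return CandidateProtein(result.protein_accession, result.stratum,
                            flagged, presence_ok, flags)


def screen(results: Sequence[ProteinAnovaResult],
           observations: Iterable[PeptideObservation],
           design: StudyDesign,
           thresholds: ScreeningThresholds = ScreeningThresholds(),
           ) -> list[CandidateProtein]:
    """Screen every protein-stratum result; returns all, candidates or not."""
    obs = list(observations)
    out = []
    for res in results:
        ok = presence_in_all_samples(obs, design, res.stratum,
                                     res.protein_accession)
        out.append(screen_protein(res, ok, thresholds))
    return out


@dataclass
class UniquePeptidePartition:
    """Peptide sequences seen only in one group's samples, per protein.

    Identity is the bare sequence: modified forms collapse.  The three sets
    are disjoint and cover every sequence observed for the protein in the
    stratum.
    """

    accession: str
    stratum: str
    group_a: str
    group_b: str
    unique_to_a: set[str]
    unique_to_b: set[str]
    shared: set[str]


def unique_peptides(observations: Iterable[PeptideObservation],
                    design: StudyDesign, stratum: str,
                    ) -> dict[str, UniquePeptidePartition]:
    """Partition each protein's peptide sequences by group membership.

    A sequence belongs to a group if it has a nonzero spectral count in at
    least one of that group's samples within the stratum.
    """
    g1, g2 = design.group_levels
    meta = {s.sample_id: s for s in design.samples}
    seen: dict[str, dict[str, set[str]]] = {}
    for o in observations:
        s = meta.get(o.sample_id)
        if s is None or s.stratum != stratum or o.spectral_count <= 0:
            continue
        bucket = seen.setdefault(o.protein_accession, {g1: set(), g2: set()})
        bucket[s.group].add(o.peptide_sequence)
    out = {}
    for acc, bucket in seen.items():
        a, b = bucket[g1], bucket[g2]
        out[acc] = UniquePeptidePartition(
            acc, stratum, g1, g2,
            unique_to_a=a - b, unique_to_b=b - a, shared=a & b)
    return out


@dataclass
class VennPartition:
    only_first: set[str]
    only_second: set[str]
    shared: set[str]
    overlap_with_external: set[str]


def compare_candidate_sets(set_a: Iterable[str], set_b: Iterable[str],
                           external: Iterable[str] = ()) -> VennPartition:
    """Venn partition of two candidate accession sets, plus overlap of their
    union with an external (e.g. abundance-based) biomarker list."""
    a, b, e = set(set_a), set(set_b), set(external)
    return VennPartition(a - b, b - a, a & b, (a | b) & e)


def candidates_to_frame(cands: Sequence[CandidateProtein]) -> pd.DataFrame:
    rows = [{
        "protein_accession": c.accession,
        "stratum": c.stratum,
        "presence_ok": c.presence_ok,
        "n_flagged_regions": len(c.flagged_regions),
        "flagged_regions": ";".join(map(str, c.flagged_regions)),
        "is_candidate": c.is_candidate,
    } for c in cands]
    return pd.DataFrame(rows, columns=["protein_accession", "stratum",
                                       "presence_ok", "n_flagged_regions",
                                       "flagged_regions", "is_candidate"])
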