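"""End-to-end orchestration: observations -> region results -> candidates.

Each stratum (e.g. male, female) is analyzed separately: its samples are
median-normalized, tested and screened independently, and the per-stratum
candidate sets are then compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .candidate_screening import (CandidateProtein, ScreeningThresholds,
                                  UniquePeptidePartition, screen_protein,
                                  presence_in_all_samples, unique_peptides)
from .digest_mapping import (MappingResult, OccurrencePolicy, OverlapPolicy,
                             build_region_matrix)
from .io_formats import PeptideObservation, ProteinRecord, StudyDesign
from .ptm_regional import (PTM_TYPES, PtmComparison, compare_ptm,
                           regional_ptm_counts)
from .regional_statistics import (AllTotalsZero, NormalizedRegionMatrix,
                                  ProteinAnovaResult, Transform,
                                  median_normalize, region_anova, star_level)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    region_size: int = 50
    overlap_policy: OverlapPolicy = "full"
    occurrence_policy: OccurrencePolicy = "first"
    transform: Transform = "sqrt"
    thresholds: ScreeningThresholds = ScreeningThresholds()
    normalize: bool = True
    min_per_group: int = 2
    ptm_types: tuple[str, ...] = tuple(t for t in PTM_TYPES
                                       if t != "carbamidomethyl")


@dataclass
class StratumResult:
    stratum: str
    anova: dict[str, ProteinAnovaResult]
    norm: dict[str, NormalizedRegionMatrix]
    candidates: list[CandidateProtein]
    unique: dict[str, UniquePeptidePartition]
    ptm: list[PtmComparison]
    skipped: list[tuple[str, str]]          # (accession, reason)
    mapping: MappingResult
    #: per accession, per region: group mean difference on the raw scale
    #: (reported alongside the normalized-scale difference)
    raw_diffs: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def candidate_accessions(self) -> set[str]:
        return {c.accession for c in self.candidates if c.is_candidate}

    def results_frame(self) -> pd.DataFrame:
        rows = []
        flags_by_acc = {c.accession: {f.region_index: f for f in c.region_flags}
                        for c in self.candidates}
        for acc, res in self.anova.items():
            g1, g2 = res.group_levels
            for r in res.regions:
                f = flags_by_acc.get(acc, {}).get(r.region_index)
                rows.append({
                    "protein_accession": acc,
                    "stratum": self.stratum,
                    "region_index": r.region_index,
                    "region_start": r.region_start,
                    "region_end": r.region_end,
                    "mean_norm_group1": r.mean_norm[g1],
                    "mean_norm_group2": r.mean_norm[g2],
                    "delta_avg_psc": r.delta_avg_psc,
                    "raw_diff": self.raw_diffs.get(acc, {}).get(
                        r.region_index, float("nan")),
                    "F_stat": r.F_stat,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "star_level": star_level(r.p_adjusted),
                    "pass_alpha": f.pass_alpha if f else False,
                    "pass_diff": f.pass_diff if f else False,
                    "pass_min_norm": f.pass_min_norm if f else False,
                    "flagged": f.flagged if f else False,
                })
        return pd.DataFrame(rows)


@dataclass
class StudyResult:
    strata: dict[str, StratumResult]

    def results_frame(self) -> pd.DataFrame:
        frames = [r.results_frame() for r in self.strata.values()
                  if r.anova]
        return (pd.concat(frames, ignore_index=True)
                if frames else pd.DataFrame())


def run_stratum(observations: Sequence[PeptideObservation],
                proteins: Mapping[str, ProteinRecord],
                design: StudyDesign, stratum: str,
                params: PipelineParams = PipelineParams()) -> StratumResult:
    """Analyze one stratum: map, normalize, test, screen, count PTMs."""
    stratum_samples = {s.sample_id for s in design.samples_in(stratum)}
    obs = [o for o in observations if o.sample_id in stratum_samples]
    mapping = build_region_matrix(obs, proteins, design,
                                  region_size=params.region_size,
                                  overlap_policy=params.overlap_policy,
                                  occurrence_policy=params.occurrence_policy)
    sample_ids = [s.sample_id for s in design.samples_in(stratum)]

    anova: dict[str, ProteinAnovaResult] = {}
    norms: dict[str, NormalizedRegionMatrix] = {}
    candidates: list[CandidateProtein] = []
    ptm_comps: list[PtmComparison] = []
    skipped: list[tuple[str, str]] = []
    raw_diffs: dict[str, dict[int, float]] = {}

    for acc, matrix in sorted(mapping.matrices.items()):
        try:
            if params.normalize:
                nm = median_normalize(matrix, sample_ids)
            else:
                nm = _identity_normalize(matrix, sample_ids)
        except AllTotalsZero as exc:
            skipped.append((acc, str(exc)))
            logger.info("skipping %s: %s", acc, exc)
            continue
        try:
            res = region_anova(nm, design, stratum, transform=params.transform,
                               min_per_group=params.min_per_group)
        except ValueError as exc:
            skipped.append((acc, str(exc)))
            logger.info("skipping %s: %s", acc, exc)
            continue
        meta = {s.sample_id: s for s in design.samples}
        codes = np.array([meta[s].group for s in nm.sample_ids])
        sel1, sel2 = (codes == res.group_levels[0],
                      codes == res.group_levels[1])
        raw_by_region = {
            r.region_index: float(nm.values[sel1][:, r.region_index].mean()
                                  - nm.values[sel2][:, r.region_index].mean())
            for r in res.regions}
        anova[acc] = res
        norms[acc] = nm
        raw_diffs[acc] = raw_by_region
        presence = presence_in_all_samples(obs, design, stratum, acc)
        candidates.append(screen_protein(res, presence, params.thresholds))

        protein_lengths = {acc: proteins[acc].length}
        for ptm_type in params.ptm_types:
            counts = regional_ptm_counts(
                [o for o in obs if o.protein_accession == acc],
                mapping.located, ptm_type, nm.sample_ids, protein_lengths,
                params.region_size)
            if acc in counts:
                ptm_comps.extend(compare_ptm(counts[acc], nm, design, stratum,
                                             transform=params.transform))

    uniq = unique_peptides(obs, design, stratum)
    return StratumResult(stratum, anova, norms, candidates, uniq,
                         ptm_comps, skipped, mapping, raw_diffs)


def _identity_normalize(matrix, sample_ids) -> NormalizedRegionMatrix:
    """Bypass normalization (scale factors 1); for sensitivity analysis."""
    idx = [matrix.sample_index(s) for s in sample_ids]
    totals = matrix.totals[idx]
    keep = totals > 0
    if not keep.any():
        raise AllTotalsZero(f"{matrix.protein_accession}: all totals zero")
    kept_ids = [s for s, k in zip(sample_ids, keep) if k]
    kept_idx = [i for i, k in zip(idx, keep) if k]
    values = matrix.values[kept_idx]
    return NormalizedRegionMatrix(
        matrix.protein_accession, kept_ids, values.copy(), values.copy(),
        matrix.totals[kept_idx].copy(), np.ones(len(kept_idx)),
        matrix.region_size, matrix.protein_length,
        [s for s, k in zip(sample_ids, keep) if not k])


def run_study(observations: Sequence[PeptideObservation],
              proteins: Mapping[str, ProteinRecord],
              design: StudyDesign,
              params: PipelineParams = PipelineParams(),
              strata: Sequence[str] | None = None) -> StudyResult:
    """Run every stratum's pipeline separately (the sexes are never pooled)."""
    if strata is None:
        strata = design.strata
    return StudyResult({st: run_stratum(observations, proteins, design, st,
                                        params) for st in strata})
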