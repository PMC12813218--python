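"""Regional counting and comparison of post-translational modifications.

Parses the modification annotations carried by exported peptide rows
(deamidation of N/Q, oxidation of M, K [hydroxylysine] and P
[hydroxyproline], carbamidomethyl C), maps each site into the parent
protein's 50aa regions via the peptide's located span, accumulates
per-sample site counts weighted by the carrying observation's spectral
count, normalizes with the same per-sample scale factors as the PSC
normalization, and compares group medians per region with the same
contrast machinery used for spectral counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digest_mapping import LocatedPeptide, RegionMatrix, region_count
from .io_formats import (FormatError, ModificationSite, PeptideObservation,
                         StudyDesign)
from .regional_statistics import (NormalizedRegionMatrix, ProteinAnovaResult,
                                  Transform, region_anova)

PTM_TYPES = ("deamidation", "oxidation_M", "oxidation_K", "oxidation_P",
             "carbamidomethyl")

# Scaffold-style token: "Oxidation (+16) M12" / "Deamidated (+1) N3"
_SCAFFOLD = re.compile(
    r"(?P<name>[A-Za-z]+)\s*\(\+?(?P<mass>\d+)\)\s*(?P<res>[A-Z])(?P<pos>\d+)")
# compact token: "M12(ox)" / "N3(deam)" / "C4(cam)"
_COMPACT = re.compile(r"(?P<res>[A-Z])(?P<pos>\d+)\((?P<tag>[a-z]+)\)")

_NAME_TO_TYPE = {
    ("deamidated", "N"): "deamidation",
    ("deamidated", "Q"): "deamidation",
    ("oxidation", "M"): "oxidation_M",
    ("oxidation", "K"): "oxidation_K",
    ("oxidation", "P"): "oxidation_P",
    ("carbamidomethyl", "C"): "carbamidomethyl",
}
_TAG_TO_NAME = {"ox": "oxidation", "deam": "deamidated",
                "cam": "carbamidomethyl"}


def parse_modifications(mod_string: str, dialect: str = "scaffold",
                        peptide: str | None = None,
                        ) -> tuple[list[ModificationSite], list[str]]:
    """Parse a modification annotation string into sites plus warnings.

    Unknown tokens and out-of-range positions are collected as warnings,
    never fatal.  When ``peptide`` is given, positions are validated
    against its length and residue identity.
    """
    sites: list[ModificationSite] = []
    warnings: list[str] = []
    if not mod_string or not mod_string.strip():
        return sites, warnings
    if dialect not in ("scaffold", "compact"):
        raise ValueError(f"unknown modification dialect {dialect!r}")
    pattern = _SCAFFOLD if dialect == "scaffold" else _COMPACT
    for token in re.split(r"[,;]", mod_string):
        token = token.strip()
        if not token:
            continue
        m = pattern.fullmatch(token)
        if not m:
            warnings.append(f"unrecognized modification token {token!r}")
            continue
        res, pos = m.group("res"), int(m.group("pos"))
        name = (m.group("name") if dialect == "scaffold"
                else _TAG_TO_NAME.get(m.group("tag"), m.group("tag")))
        mod_type = _NAME_TO_TYPE.get((name.lower(), res))
        if mod_type is None:
            warnings.append(f"unknown modification {name!r} on {res}{pos}")
            continue
        if peptide is not None:
            if pos > len(peptide):
                warnings.append(
                    f"{token!r}: position {pos} outside peptide of length "
                    f"{len(peptide)}")
                continue
            if peptide[pos - 1] != res:
                warnings.append(
                    f"{token!r}: residue mismatch (peptide has "
                    f"{peptide[pos - 1]} at {pos})")
                continue
        try:
            sites.append(ModificationSite(res, pos, mod_type))
        except FormatError as exc:
            warnings.append(str(exc))
    return sites, warnings


@dataclass
class PtmRegionCounts:
    """Per-sample, per-region counts of one PTM type for one protein.

    Raw counts weigh each modified residue by the spectral count of the
    observation carrying it (counts measure evidence depth, mirroring PSC).
    """

    protein_accession: str
    ptm_type: str
    sample_ids: list[str]
    counts: np.ndarray          # samples x regions, raw weighted site counts
    region_size: int
    protein_length: int


def regional_ptm_counts(observations: Sequence[PeptideObservation],
                        located: Mapping[tuple[str, str], LocatedPeptide],
                        ptm_type: str,
                        sample_ids: Sequence[str],
                        protein_length: Mapping[str, int],
                        region_size: int = 50,
                        weight_by_count: bool = True,
                        ) -> dict[str, PtmRegionCounts]:
    """Accumulate modified-residue counts into regions.

    A site's protein position is ``peptide start + position_in_peptide - 1``;
    a single residue maps to exactly one region.  Observations whose peptide
    has no location entry are skipped (they were already reported as
    unlocatable during mapping).
    """
    if ptm_type not in PTM_TYPES:
        raise ValueError(f"unknown ptm_type {ptm_type!r}")
    pos_of = {sid: i for i, sid in enumerate(sample_ids)}
    out: dict[str, PtmRegionCounts] = {}
    for obs in observations:
        if obs.sample_id not in pos_of or not obs.modifications:
            continue
        loc = located.get((obs.protein_accession, obs.peptide_sequence))
        if loc is None:
            continue
        acc = obs.protein_accession
        if acc not in out:
            n_reg = region_count(protein_length[acc], region_size)
            out[acc] = PtmRegionCounts(acc, ptm_type, list(sample_ids),
                                       np.zeros((len(sample_ids), n_reg)),
                                       region_size, protein_length[acc])
        weight = obs.spectral_count if weight_by_count else 1
        s = pos_of[obs.sample_id]
        for site in obs.modifications:
            if site.mod_type != ptm_type:
                continue
            protein_pos = loc.start + site.position_in_peptide - 1
            out[acc].counts[s, (protein_pos - 1) // region_size] += weight
    return out


def normalize_ptm_counts(ptm: PtmRegionCounts,
                         norm: NormalizedRegionMatrix) -> NormalizedRegionMatrix:
    """Scale PTM counts with the protein's PSC scale factors.

    Uses the identical per-sample factors as the spectral-count
    normalization for the same protein-stratum, so PTM differences are
    read on the same abundance-corrected scale.
    """
    idx = [ptm.sample_ids.index(s) for s in norm.sample_ids]
    counts = ptm.counts[idx]
    return NormalizedRegionMatrix(
        ptm.protein_accession, list(norm.sample_ids), counts.copy(),
        counts * norm.scale_factors[:, None], norm.totals.copy(),
        norm.scale_factors.copy(), ptm.region_size, ptm.protein_length,
        list(norm.excluded_samples))


@dataclass
class PtmComparison:
    protein_accession: str
    stratum: str
    ptm_type: str
    region_index: int
    median_norm: dict[str, float]
    mean_norm: dict[str, float]
    median_difference: float       # first group minus second
    p_raw: float
    p_adjusted: float


def compare_ptm(ptm: PtmRegionCounts, norm: NormalizedRegionMatrix,
                design: StudyDesign, stratum: str,
                transform: Transform = "sqrt") -> list[PtmComparison]:
    """Group medians, median difference and contrast p-values per region.

    With only a handful of samples per group median and mean are nearly
    degenerate; both are reported.  p-values reuse the regional contrast
    machinery applied to the normalized PTM counts.
    """
    ptm_norm = normalize_ptm_counts(ptm, norm)
    if ptm_norm.norm_values.sum() == 0:
        return []
    res: ProteinAnovaResult = region_anova(ptm_norm, design, stratum,
                                           transform=transform)
    meta = {s.sample_id: s for s in design.samples}
    g1, g2 = design.group_levels
    ids = ptm_norm.sample_ids
    codes = np.array([meta[s].group for s in ids])
    N = ptm_norm.norm_values
    out = []
    for r in res.regions:
        k = r.region_index
        a, b = N[codes == g1, k], N[codes == g2, k]
        out.append(PtmComparison(
            ptm.protein_accession, stratum, ptm.ptm_type, k,
            median_norm={g1: float(np.median(a)), g2: float(np.median(b))},
            mean_norm={g1: float(a.mean()), g2: float(b.mean())},
            median_difference=float(np.median(a) - np.median(b)),
            p_raw=r.p_raw, p_adjusted=r.p_adjusted))
    return out


def ptm_comparisons_to_frame(comps: Iterable[PtmComparison]) -> pd.DataFrame:
    rows = []
    for c in comps:
        (ga, ma), (gb, mb) = c.median_norm.items()
        rows.append({
            "protein_accession": c.protein_accession, "stratum": c.stratum,
            "ptm_type": c.ptm_type, "region_index": c.region_index,
            f"median_{ga}": ma, f"median_{gb}": mb,
            "median_difference": c.median_difference,
            "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
        })
    return pd.DataFrame(rows)
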