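"""Regional spectral-count statistics.

Median normalization of regional counts against total protein abundance,
per-region group comparison within a two-way mixed (repeated-measures)
ANOVA, Bonferroni correction over the protein's tested regions, and the
per-region difference of group means (Δavg.PSC, first group minus second).

The mixed design treats the sample group (e.g. juvenile vs adult) as the
between-sample factor and the 50aa region as the within-sample repeated
factor.  Per-region significance uses the classical Bonferroni post-test
construction: a group contrast at each region whose error term pools the
subjects-within-groups and subject-by-region error strata of the ANOVA
decomposition.  Because spectral counts are heteroscedastic (variance
roughly proportional to the mean), the contrast is computed by default on
square-root transformed normalized counts, which stabilizes the null
variance across regions and keeps the pooled error term honest; the
reported group means and Δavg.PSC stay on the normalized-count scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .digest_mapping import RegionMatrix, region_bounds
from .io_formats import StudyDesign

logger = logging.getLogger(__name__)

Transform = Literal["sqrt", "none", "log"]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_level(p_adjusted: float) -> str:
    """Significance stars on the adjusted p: * <=0.05, ** <=0.01, *** <=0.001."""
    for cut, stars in STAR_THRESHOLDS:
        if p_adjusted <= cut:
            return stars
    return ""


def bonferroni(p_values: Sequence[float] | np.ndarray, m: int) -> np.ndarray:
    """p_adj = min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


@dataclass
class NormalizedRegionMatrix:
    """A RegionMatrix scaled so every sample carries the median total PSC.

    scale factor f_s = median over included samples of totals / totals[s];
    samples with zero total are excluded (listed in ``excluded_samples``).
    """

    protein_accession: str
    sample_ids: list[str]
    values: np.ndarray        # raw, samples x regions (included samples only)
    norm_values: np.ndarray   # values * f_s
    totals: np.ndarray
    scale_factors: np.ndarray
    region_size: int
    protein_length: int
    excluded_samples: list[str]


class AllTotalsZero(ValueError):
    pass


def median_normalize(matrix: RegionMatrix,
                     sample_ids: Sequence[str] | None = None,
                     ) -> NormalizedRegionMatrix:
    """Median-normalize a protein's regional counts against its total PSC.

    Removes whole-protein abundance differences between samples so that
    regional comparisons reflect distribution across the structure, not
    amount of protein.  The median is taken over the samples included in
    the current comparison only (pass ``sample_ids`` to restrict to a
    stratum).  Samples with a zero total are excluded and listed.
    """
    if sample_ids is None:
        sample_ids = matrix.sample_ids
    idx = [matrix.sample_index(s) for s in sample_ids]
    totals = matrix.totals[idx]
    keep = totals > 0
    excluded = [s for s, k in zip(sample_ids, keep) if not k]
    if not keep.any():
        raise AllTotalsZero(
            f"{matrix.protein_accession}: all sample totals are zero")
    kept_ids = [s for s, k in zip(sample_ids, keep) if k]
    kept_idx = [i for i, k in zip(idx, keep) if k]
    totals = matrix.totals[kept_idx]
    values = matrix.values[kept_idx]
    factors = np.median(totals) / totals
    return NormalizedRegionMatrix(
        matrix.protein_accession, kept_ids, values.copy(),
        values * factors[:, None], totals.copy(), factors,
        matrix.region_size, matrix.protein_length, excluded)


@dataclass
class MixedAnovaTable:
    """Omnibus two-way mixed ANOVA (group between, region within)."""

    ss_group: float
    ss_subjects_within: float
    ss_region: float
    ss_interaction: float
    ss_error: float
    df_group: int
    df_subjects_within: int
    df_region: int
    df_interaction: int
    df_error: int

    @property
    def F_group(self) -> float:
        return _f_ratio(self.ss_group, self.df_group,
                        self.ss_subjects_within, self.df_subjects_within)

    @property
    def F_region(self) -> float:
        return _f_ratio(self.ss_region, self.df_region,
                        self.ss_error, self.df_error)

    @property
    def F_interaction(self) -> float:
        return _f_ratio(self.ss_interaction, self.df_interaction,
                        self.ss_error, self.df_error)

    @property
    def p_group(self) -> float:
        return _f_p(self.F_group, self.df_group, self.df_subjects_within)

    @property
    def p_region(self) -> float:
        return _f_p(self.F_region, self.df_region, self.df_error)

    @property
    def p_interaction(self) -> float:
        return _f_p(self.F_interaction, self.df_interaction, self.df_error)


def _f_ratio(ss_num: float, df_num: int, ss_den: float, df_den: int) -> float:
    if df_num <= 0 or df_den <= 0:
        return float("nan")
    ms_den = ss_den / df_den
    if ms_den <= 0:
        return 0.0
    return (ss_num / df_num) / ms_den


def _f_p(F: float, df1: int, df2: int) -> float:
    if not math.isfinite(F):
        return 1.0
    return float(stats.f.sf(F, df1, df2))


@dataclass
class RegionTestResult:
    """Per-region outcome of the group comparison for one protein-stratum."""

    region_index: int
    region_start: int
    region_end: int
    mean_norm: dict[str, float]     # group level -> mean normalized PSC
    delta_avg_psc: float            # first group minus second
    F_stat: float
    p_raw: float
    p_adjusted: float
    m: int                          # Bonferroni divisor (tested regions)

    @property
    def star(self) -> str:
        return star_level(self.p_adjusted)


@dataclass
class ProteinAnovaResult:
    protein_accession: str
    stratum: str
    group_levels: tuple[str, str]
    omnibus: MixedAnovaTable
    regions: list[RegionTestResult]
    tested_regions: list[int]


def mixed_anova_decomposition(Y: np.ndarray, groups: np.ndarray) -> MixedAnovaTable:
    """Explicit sums-of-squares decomposition of a two-way mixed design.

    ``Y`` is subjects x within-levels; ``groups`` codes the between factor.
    Balanced or unbalanced group sizes are handled by per-cell means with
    group-size weighting of the between sums.
    """
    n, K = Y.shape
    levels = np.unique(groups)
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    ss_subj_total = K * float(((subj_means - grand) ** 2).sum())
    ss_group = 0.0
    for g in levels:
        sel = groups == g
        ss_group += K * sel.sum() * float((subj_means[sel].mean() - grand) ** 2)
    ss_subjects_within = ss_subj_total - ss_group

    region_means = Y.mean(axis=0)
    ss_region = n * float(((region_means - grand) ** 2).sum())
    ss_cells = 0.0
    for g in levels:
        sel = groups == g
        cell = Y[sel].mean(axis=0)
        ss_cells += sel.sum() * float(((cell - grand) ** 2).sum())
    ss_interaction = ss_cells - ss_group - ss_region
    ss_total = float(((Y - grand) ** 2).sum())
    ss_error = ss_total - ss_subj_total - ss_region - ss_interaction

    a = len(levels)
    return MixedAnovaTable(
        ss_group=ss_group,
        ss_subjects_within=ss_subjects_within,
        ss_region=ss_region,
        ss_interaction=ss_interaction,
        ss_error=max(ss_error, 0.0),
        df_group=a - 1,
        df_subjects_within=n - a,
        df_region=K - 1,
        df_interaction=(a - 1) * (K - 1),
        df_error=(n - a) * (K - 1),
    )


def pooled_contrast_error(table: MixedAnovaTable) -> tuple[float, int]:
    """Pooled error MS and df for between-group contrasts at single regions.

    Pools the subjects-within-groups and subject-by-region error strata, the
    standard error term for Bonferroni post-tests comparing groups at one
    level of the within factor in a mixed design.
    """
    ss = table.ss_subjects_within + table.ss_error
    df = table.df_subjects_within + table.df_error
    return (ss / df if df > 0 else float("nan")), df


def _apply_transform(Y: np.ndarray, transform: Transform) -> np.ndarray:
    if transform == "sqrt":
        return np.sqrt(Y)
    if transform == "log":
        return np.log1p(Y)
    if transform == "none":
        return Y
    raise ValueError(f"unknown transform {transform!r}")


def region_anova(norm: NormalizedRegionMatrix, design: StudyDesign,
                 stratum: str, transform: Transform = "sqrt",
                 min_per_group: int = 2) -> ProteinAnovaResult:
    """Two-way mixed RM-ANOVA and per-region Bonferroni group contrasts.

    Regions with no observed peptides in either group are excluded from the
    test and from the Bonferroni divisor ``m`` (untestable cells would
    dilute the correction); regions with zero variance across all samples
    but nonzero counts get ``p_raw = 1``.  Requires >= ``min_per_group``
    samples per group in the stratum.
    """
    meta = {s.sample_id: s for s in design.samples}
    groups_all = design.group_levels
    if len(groups_all) != 2:
        raise ValueError("exactly two group levels are required")
    g1, g2 = groups_all

    sample_ids = [s for s in norm.sample_ids
                  if meta[s].stratum == stratum or stratum == "all"]
    group_codes = np.array([meta[s].group for s in sample_ids])
    n1 = int((group_codes == g1).sum())
    n2 = int((group_codes == g2).sum())
    if min(n1, n2) < min_per_group:
        raise ValueError(
            f"{norm.protein_accession}/{stratum}: {n1} vs {n2} samples "
            f"(need >= {min_per_group} per group)")

    idx = [norm.sample_ids.index(s) for s in sample_ids]
    N = norm.norm_values[idx]
    sel1, sel2 = group_codes == g1, group_codes == g2

    observed = N.sum(axis=0) > 0
    tested = [int(k) for k in np.flatnonzero(observed)]
    if not tested:
        raise ValueError(f"{norm.protein_accession}/{stratum}: no observed regions")
    m = len(tested)

    Y = _apply_transform(N[:, tested], transform)
    if Y.shape[1] >= 2:
        table = mixed_anova_decomposition(Y, group_codes)
        ms_pool, df_pool = pooled_contrast_error(table)
    else:
        # single-region protein: contrast degenerates to a two-sample test
        table = MixedAnovaTable(0, 0, 0, 0, 0, 1, len(sample_ids) - 2, 0, 0, 0)
        y = Y[:, 0]
        ss = float(((y[sel1] - y[sel1].mean()) ** 2).sum()
                   + ((y[sel2] - y[sel2].mean()) ** 2).sum())
        df_pool = len(sample_ids) - 2
        ms_pool = ss / df_pool if df_pool else float("nan")

    results: list[RegionTestResult] = []
    p_raws = np.ones(m)
    Fs = np.zeros(m)
    for j, k in enumerate(tested):
        diff_t = Y[sel1, j].mean() - Y[sel2, j].mean()
        if ms_pool > 0 and df_pool > 0:
            se = math.sqrt(ms_pool * (1.0 / n1 + 1.0 / n2))
            t = diff_t / se
            p = 2.0 * float(stats.t.sf(abs(t), df_pool))
            Fs[j] = t * t
            p_raws[j] = p
        else:
            # no residual variance anywhere: identical data -> null identity
            Fs[j] = 0.0
            p_raws[j] = 1.0
    p_adj = bonferroni(p_raws, m)

    for j, k in enumerate(tested):
        start, end = region_bounds(k, norm.region_size, norm.protein_length)
        results.append(RegionTestResult(
            region_index=k,
            region_start=start,
            region_end=end,
            mean_norm={g1: float(N[sel1][:, k].mean()),
                       g2: float(N[sel2][:, k].mean())},
            delta_avg_psc=float(N[sel1][:, k].mean() - N[sel2][:, k].mean()),
            F_stat=float(Fs[j]),
            p_raw=float(p_raws[j]),
            p_adjusted=float(p_adj[j]),
            m=m,
        ))
    return ProteinAnovaResult(norm.protein_accession, stratum, (g1, g2),
                              table, results, tested)


def delta_avg_psc(norm: NormalizedRegionMatrix, design: StudyDesign,
                  stratum: str) -> np.ndarray:
    """Per-region difference of group means of normalized PSC (Δavg.PSC).

    Sign convention: first group level minus second (juvenile − adult in
    the default design).
    """
    meta = {s.sample_id: s for s in design.samples}
    g1, g2 = design.group_levels
    sample_ids = [s for s in norm.sample_ids
                  if meta[s].stratum == stratum or stratum == "all"]
    codes = np.array([meta[s].group for s in sample_ids])
    idx = [norm.sample_ids.index(s) for s in sample_ids]
    N = norm.norm_values[idx]
    if not (codes == g1).any() or not (codes == g2).any():
        raise ValueError("both group levels must be present")
    return N[codes == g1].mean(axis=0) - N[codes == g2].mean(axis=0)
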