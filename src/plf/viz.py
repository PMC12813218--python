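"""Per-protein visualization of regional fingerprinting results.

Three aligned panels over the 50aa regions of one protein: bars of average
normalized PSC per group with standard-deviation whiskers, a relative-PSC
heatmap strip, and the Δavg.PSC line with significance stars at flagged
regions and vertical markers at annotated sites (e.g. protease cleavage
sites).  The plotting layer never recomputes statistics: every glyph is
sourced from the result objects, and the assembled data payload is
returned so tests can assert the correspondence before rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io_formats import SiteAnnotation, StudyDesign
from .pipeline import StratumResult
from .regional_statistics import star_level


@dataclass
class ProteinPlotData:
    """Everything the figure draws, extracted from result objects."""

    accession: str
    stratum: str
    group_levels: tuple[str, str]
    region_indices: list[int]
    mean_norm: dict[str, list[float]]     # group -> per-region means
    sd_norm: dict[str, list[float]]       # group -> per-region sd
    relative_psc: list[float]             # heatmap strip, max-scaled
    delta_avg_psc: list[float]
    stars: dict[int, str]                 # region -> star string
    annotation_positions: list[tuple[float, str]] = field(default_factory=list)


def build_plot_data(accession: str, result: StratumResult,
                    design: StudyDesign,
                    annotations: Sequence[SiteAnnotation] = (),
                    ) -> ProteinPlotData:
    if accession not in result.anova:
        raise KeyError(f"{accession} was not analyzed in stratum "
                       f"{result.stratum}")
    res = result.anova[accession]
    nm = result.norm[accession]
    g1, g2 = res.group_levels
    regions = [r.region_index for r in res.regions]

    mean_norm: dict[str, list[float]] = {g1: [], g2: []}
    sd_norm: dict[str, list[float]] = {g1: [], g2: []}
    # group membership per included sample, from the study design order
    for r in res.regions:
        for g in (g1, g2):
            mean_norm[g].append(r.mean_norm[g])
    meta = {s.sample_id: s for s in design.samples}
    codes = np.array([meta[sid].group for sid in nm.sample_ids])
    for k in regions:
        col = nm.norm_values[:, k]
        sd_norm[g1].append(float(col[codes == g1].std(ddof=1)))
        sd_norm[g2].append(float(col[codes == g2].std(ddof=1)))

    overall = [(a + b) / 2 for a, b in zip(mean_norm[g1], mean_norm[g2])]
    top = max(overall) if overall and max(overall) > 0 else 1.0
    stars = {r.region_index: star_level(r.p_adjusted)
             for r in res.regions if star_level(r.p_adjusted)}
    ann = [((a.position - 1) / nm.region_size, a.label)
           for a in annotations if a.protein_accession == accession]
    return ProteinPlotData(
        accession, result.stratum, (g1, g2), regions,
        mean_norm, sd_norm, [v / top for v in overall],
        [r.delta_avg_psc for r in res.regions], stars, ann)


def plot_protein(accession: str, result: StratumResult,
                 design: StudyDesign,
                 annotations: Sequence[SiteAnnotation] = (),
                 out_path: str | Path | None = None,
                 ) -> tuple[ProteinPlotData, "plt.Figure"]:
    """Render the three-panel regional fingerprint for one protein."""
    data = build_plot_data(accession, result, design, annotations)
    g1, g2 = data.group_levels
    x = np.asarray(data.region_indices, dtype=float)

    fig, (ax_bar, ax_heat, ax_delta) = plt.subplots(
        3, 1, figsize=(max(6.0, 0.3 * len(x)), 6.5), sharex=True,
        gridspec_kw={"height_ratios": [3, 0.5, 2.5]})

    width = 0.4
    ax_bar.bar(x - width / 2, data.mean_norm[g1], width,
               yerr=data.sd_norm[g1], capsize=2, label=g1, color="#4878a8")
    ax_bar.bar(x + width / 2, data.mean_norm[g2], width,
               yerr=data.sd_norm[g2], capsize=2, label=g2, color="#b55a45")
    ax_bar.set_ylabel("avg. normalized PSC")
    ax_bar.legend(frameon=False, fontsize=8)
    ax_bar.set_title(f"{data.accession} — {data.stratum}")

    ax_heat.imshow(np.asarray(data.relative_psc)[None, :], aspect="auto",
                   cmap="Reds", extent=(x.min() - 0.5, x.max() + 0.5, 0, 1))
    ax_heat.set_yticks([])

    ax_delta.plot(x, data.delta_avg_psc, "-o", ms=3, color="#333333")
    ax_delta.axhline(0.0, lw=0.6, color="grey")
    for k, s in data.stars.items():
        j = data.region_indices.index(k)
        ax_delta.annotate(s, (k, data.delta_avg_psc[j]),
                          textcoords="offset points", xytext=(0, 6),
                          ha="center", color="#b02020", fontsize=10)
    for pos, label in data.annotation_positions:
        for ax in (ax_bar, ax_delta):
            ax.axvline(pos, color="gold", lw=1.2, zorder=0)
    ax_delta.set_xlabel("50aa region index")
    ax_delta.set_ylabel(f"Δavg.PSC ({g1} − {g2})")

    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return data, fig
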