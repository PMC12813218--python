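"""Operating characteristics of the screening pipeline, by simulation.

Runs many seeded single-stratum studies through the full pipeline
(digest -> detect -> count -> map -> normalize -> test -> screen) and
measures type-I error, planted-effect recovery power and the effect of
the median normalization on whole-protein abundance confounds.  These are
the quantities that qualify the screen before it is pointed at real data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .pipeline import PipelineParams, run_stratum
from .synthetic_data import (SimulationConfig, abundance_confound_config,
                             generate_proteome, null_config,
                             regional_effect_config, simulate_study,
                             PLANTED_WINDOW)

#: the stratum the operating-characteristic runs analyze (3 vs 3 samples)
_STRATUM = "male"


def _derive_seeds(base_seed: int, n: int, stream: int) -> np.ndarray:
    """Independent per-replicate seeds below 2**31, reproducible in base."""
    ss = np.random.SeedSequence([base_seed, stream])
    return ss.generate_state(n) % (2 ** 31)


@dataclass
class RunOutcome:
    flagged_regions: list[int]          # all screening criteria met
    significant_regions: list[int]      # adjusted p <= alpha only
    tested_regions: int
    candidate: bool


def run_once(config: SimulationConfig,
             params: PipelineParams = PipelineParams()) -> RunOutcome | None:
    """One simulated study through the full pipeline, first-protein outcome.

    Returns None when the stratum could not be analyzed (e.g. a zero-total
    sample), which the aggregate rates simply skip.
    """
    proteome = generate_proteome(config)
    observations, design, _ = simulate_study(proteome, config,
                                             collect_ptms=False)
    res = run_stratum(observations, proteome, design, _STRATUM, params)
    acc = next(iter(proteome))
    if acc not in res.anova:
        return None
    cand = next(c for c in res.candidates if c.accession == acc)
    sig = [r.region_index for r in res.anova[acc].regions
           if r.p_adjusted <= params.thresholds.alpha]
    return RunOutcome(cand.flagged_regions, sig,
                      len(res.anova[acc].tested_regions), cand.is_candidate)


@dataclass
class TypeIResult:
    n_runs: int
    n_significant: int        # >=1 region with adjusted p <= alpha
    n_flagged: int            # >=1 region passing all screening criteria

    @property
    def fwer(self) -> float:
        return self.n_significant / self.n_runs

    @property
    def flag_rate(self) -> float:
        return self.n_flagged / self.n_runs

    @property
    def fwer_bound(self) -> float:
        """Nominal level plus two binomial standard errors."""
        se = np.sqrt(0.05 * 0.95 / self.n_runs)
        return 0.05 + 2 * se


def type_i_error(n_reps: int = 500, base_seed: int = 0,
                 params: PipelineParams = PipelineParams()) -> TypeIResult:
    """Null simulations: no planted effect, 3 vs 3 samples per replicate."""
    seeds = _derive_seeds(base_seed, n_reps, stream=101)
    n_sig = n_flag = n_ok = 0
    for s in seeds:
        out = run_once(null_config(int(s)), params)
        if out is None:
            continue
        n_ok += 1
        n_sig += bool(out.significant_regions)
        n_flag += bool(out.flagged_regions)
    return TypeIResult(n_ok, n_sig, n_flag)


@dataclass
class PowerResult:
    fold_change: float
    n_runs: int
    n_recovered: int

    @property
    def power(self) -> float:
        return self.n_recovered / self.n_runs


def _recovered(out: RunOutcome, window: tuple[int, int]) -> bool:
    """A planted window counts as recovered when a flagged region carries
    planted signal: the window itself or an adjacent region reached by
    boundary-spanning peptides under the full overlap policy."""
    reach = set(range(window[0] - 1, window[1] + 2))
    return bool(reach & set(out.flagged_regions))


def power_at(fold: float, n_reps: int = 200, base_seed: int = 0,
             params: PipelineParams = PipelineParams()) -> PowerResult:
    """Recovery power for a fold change planted on the canonical window."""
    seeds = _derive_seeds(base_seed, n_reps, stream=211)
    n_ok = n_hit = 0
    for s in seeds:
        cfg = regional_effect_config(int(s), fold=fold)
        cfg = replace(cfg, n_proteins=1,
                      protein_lengths=cfg.protein_lengths[:1])
        out = run_once(cfg, params)
        if out is None:
            continue
        n_ok += 1
        n_hit += _recovered(out, PLANTED_WINDOW)
    return PowerResult(fold, n_ok, n_hit)


def power_curve(folds: Sequence[float] = (1.5, 2.0, 3.0, 5.0),
                n_reps: int = 200, base_seed: int = 0,
                params: PipelineParams = PipelineParams()) -> list[PowerResult]:
    return [power_at(f, n_reps, base_seed, params) for f in folds]


@dataclass
class ConfoundResult:
    n_runs: int
    n_flagged_normalized: int
    n_flagged_unnormalized: int

    @property
    def flag_rate_normalized(self) -> float:
        return self.n_flagged_normalized / self.n_runs

    @property
    def flag_rate_unnormalized(self) -> float:
        return self.n_flagged_unnormalized / self.n_runs


def confound_rates(n_reps: int = 100, base_seed: int = 0,
                   confound: float = 3.0,
                   params: PipelineParams = PipelineParams()) -> ConfoundResult:
    """Pure abundance shift: flag rates with and without normalization.

    The same simulated studies are analyzed twice, once through the median
    normalization and once with it disabled, so the contrast isolates what
    the normalization buys.
    """
    seeds = _derive_seeds(base_seed, n_reps, stream=307)
    raw_params = replace(params, normalize=False)
    n_ok = n_norm = n_raw = 0
    for s in seeds:
        cfg = abundance_confound_config(int(s), confound=confound)
        out_norm = run_once(cfg, params)
        out_raw = run_once(cfg, raw_params)
        if out_norm is None or out_raw is None:
            continue
        n_ok += 1
        n_norm += bool(out_norm.flagged_regions)
        n_raw += bool(out_raw.flagged_regions)
    return ConfoundResult(n_ok, n_norm, n_raw)
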