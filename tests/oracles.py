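"""Independent brute-force oracles the test suite checks the package against.

These deliberately share no code with the implementation: the digest oracle
enumerates every substring and checks cleavage legality directly, and the
ANOVA oracle computes sums of squares from residuals instead of the
decomposition-by-subtraction the package uses.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def oracle_digest(sequence: str, max_missed: int,
                  length_range: tuple[int, int] | None = None) -> set[tuple[int, int]]:
    """All (start, end) 1-based substring spans that are legal tryptic
    peptides: both boundaries at termini or permitted cleavage points
    (after K/R not followed by P) and at most ``max_missed`` uncut internal
    sites."""
    n = len(sequence)
    cut_after = [
        i for i in range(n - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]  # 0-based: cut between i and i+1
    cut_set = set(cut_after)
    # prefix[i] = number of cut points strictly before position i
    prefix = np.zeros(n + 1, dtype=int)
    for i in cut_after:
        prefix[i + 1] += 1
    prefix = np.cumsum(prefix)

    out = set()
    for start in range(n):          # 0-based inclusive
        if not (start == 0 or (start - 1) in cut_set):
            continue
        for end in range(start, n):  # 0-based inclusive
            if not (end == n - 1 or end in cut_set):
                continue
            length = end - start + 1
            if length_range and not (length_range[0] <= length <= length_range[1]):
                continue
            internal = prefix[end] - prefix[start]  # cuts within (start, end)
            if internal <= max_missed:
                out.add((start + 1, end + 1))
    return out


def oracle_mixed_anova(Y: np.ndarray, groups: np.ndarray) -> dict:
    """Residual-based sums of squares for the two-way mixed design plus the
    pooled-error group contrast at every within level."""
    n, K = Y.shape
    levels = sorted(set(groups))
    assert len(levels) == 2
    g1, g2 = levels
    sel1 = np.array([g == g1 for g in groups])
    sel2 = ~sel1
    n1, n2 = int(sel1.sum()), int(sel2.sum())

    grand = Y.mean()
    subj_mean = Y.mean(axis=1)
    group_mean = {g1: Y[sel1].mean(), g2: Y[sel2].mean()}
    cell_mean = {g1: Y[sel1].mean(axis=0), g2: Y[sel2].mean(axis=0)}
    region_mean = Y.mean(axis=0)

    ss_group = K * sum(
        (sel.sum()) * (Y[sel].mean() - grand) ** 2
        for sel in (sel1, sel2))
    ss_subj_within = K * sum(
        (subj_mean[i] - group_mean[g1 if sel1[i] else g2]) ** 2
        for i in range(n))
    ss_region = n * float(((region_mean - grand) ** 2).sum())
    ss_inter = 0.0
    for g, sel in ((g1, sel1), (g2, sel2)):
        ss_inter += sel.sum() * float(
            ((cell_mean[g] - region_mean - group_mean[g] + grand) ** 2).sum())
    ss_err = 0.0
    for i in range(n):
        g = g1 if sel1[i] else g2
        for k in range(K):
            ss_err += (Y[i, k] - subj_mean[i] - cell_mean[g][k]
                       + group_mean[g]) ** 2

    df_sw, df_err = n - 2, (n - 2) * (K - 1)
    ms_pool = (ss_subj_within + ss_err) / (df_sw + df_err)
    df_pool = df_sw + df_err
    contrasts = []
    for k in range(K):
        diff = cell_mean[g1][k] - cell_mean[g2][k]
        se = np.sqrt(ms_pool * (1 / n1 + 1 / n2))
        t = diff / se
        contrasts.append((t * t, 2 * float(stats.t.sf(abs(t), df_pool))))
    return {
        "ss_group": float(ss_group),
        "ss_subjects_within": float(ss_subj_within),
        "ss_region": float(ss_region),
        "ss_interaction": float(ss_inter),
        "ss_error": float(ss_err),
        "F_group": float((ss_group / 1) / (ss_subj_within / df_sw)),
        "F_region": float((ss_region / (K - 1)) / (ss_err / df_err)),
        "F_interaction": float((ss_inter / (K - 1)) / (ss_err / df_err)),
        "contrasts": contrasts,
    }
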