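# Methods

## The model

A bottom-up LC-MS/MS experiment observes, per biological sample, a list
of proteotypic tryptic peptides with exclusive spectral counts (PSC).
Peptide location fingerprinting treats each protein's primary sequence as
a coordinate axis, splits it into consecutive 50-residue regions (the
last region may be shorter; its width is recorded), and asks whether the
*regional distribution* of spectral counts differs between two sample
groups after whole-protein abundance has been factored out.  A regional
excess of tryptic peptides is read as locally increased trypsin
accessibility — typically downstream proteolysis (e.g. MMP cleavage
creating soluble fragments) or conformational change — and a regional
deficit as the converse.  All residue coordinates are 1-based and
inclusive; region `k` covers residues `[50k+1, 50k+50]`.

## Pipeline stages and the choices behind them

**Digestion and location.** Trypsin cleaves C-terminal of K/R except
before proline.  Observed peptides are located in the database protein by
exact substring match rather than by trusting exported coordinates, so
ingestion is export-dialect independent.  Repeated occurrences are real
in collagens (G-X-Y repeats); the default takes the first occurrence and
logs the ambiguity (`all`/`error` selectable).

**Region assignment.** A peptide spanning a region boundary is assigned,
by default, with full weight to every region it touches (`full`): a
peptide is evidence for each region it covers, which matches the
screening goal of flagging any affected region.  Under `proportional`
the count is split by residue overlap, which conserves each sample's
total PSC across regions exactly and is used as a conservation check;
`start` assigns everything to the start region.

**Median normalization.** For one protein and the samples of the current
comparison, sample `s` is scaled by `f_s = median(totals) / totals_s`
where `totals_s` is the sample's total PSC for that protein.  After
scaling, every sample carries the median total, so pure whole-protein
abundance differences cancel.  Samples with zero total are excluded and
listed.  Normalization (and every later stage) runs within each stratum
separately — the male and female comparisons never share scale factors.
A known systematic consequence: a very large single-region effect
inflates the affected group's totals, so normalization redistributes a
small opposite-signed shift across the remaining regions.  This is
inherent to abundance correction, and it is why screening requires a
minimum absolute difference rather than significance alone.

**The test.** The design is mixed: age group varies between samples,
region within samples.  The omnibus table (group, region, interaction)
is computed from explicit sums of squares; an independent residual-based
oracle and pingouin's `mixed_anova` pin it in the tests.  Per-region
significance uses the classical Bonferroni post-test construction after
such an ANOVA: a group contrast at each region whose error term pools
the subjects-within-groups and subject-by-region error strata
(`df = (n−2) + (n−2)(K−1)`), Bonferroni-corrected by the number of
regions tested for that protein.  Regions with no observed peptide in
either group are excluded from the test and from the correction divisor;
regions with counts but no variance anywhere yield p = 1.

Spectral counts are heteroscedastic — the regional variance grows
roughly in proportion to the regional mean — and a pooled error term on
the raw scale is therefore anticonservative for high-count regions.  The
contrast is consequently computed on square-root transformed normalized
counts by default, which stabilizes the null variance across regions
(for counts with variance ∝ mean, `Var(√X)` is approximately constant).
Simulation at the default generator settings gives a protein-level
family-wise error of ≈ 0.05 with the transform and ≈ 0.09 without it;
`transform="none"` and `"log"` remain available for sensitivity
analysis.  Reported group means, their difference Δavg.PSC
(juvenile − adult by convention) and all screening thresholds stay on
the normalized-count scale.  Alternatives considered: the per-region
two-sample t-test with its own 4-df variance is far too weak at n = 3
per group (fold-3 recovery power ≈ 0.15), and empirical-Bayes variance
moderation on the raw scale sits at the edge of validity without
matching the pooled contrast's power.  No sphericity correction is
applied; the per-region contrasts do not rest on the omnibus
within-subject F.

**Screening.** A region is a hit iff (i) adjusted p ≤ 0.05, (ii)
|Δavg.PSC| ≥ 2 and (iii) mean normalized PSC ≥ 1 in *both* groups —
criterion (iii) prevents significance driven by missingness in one
group.  All three boundaries are inclusive.  The difference criterion is
applied on the normalized scale (the scale the means are reported on);
the raw-scale difference is also emitted so the alternative reading can
be audited.  A protein is a candidate for a stratum only if it has ≥ 1
hit region and ≥ 1 nonzero-count observation in *every* sample of that
stratum.  Peptide uniqueness (group-unique vs shared peptides) is
decided on bare sequence; modified forms collapse.

**PTMs.** Modification annotations (deamidated N/Q; oxidized M; oxidized
K = hydroxylysine; oxidized P = hydroxyproline) are parsed from either a
Scaffold-style (`"Oxidation (+16) M12"`) or compact (`"M12(ox)"`)
dialect.  A site's protein position is `peptide start + position − 1`
and maps to exactly one region.  Sites are weighted by the carrying
observation's spectral count (counts measure evidence depth, mirroring
PSC; one-per-peptide counting is available), normalized with the
identical scale factors as the PSC matrix, and compared with the same
contrast machinery; group medians and means are both reported because at
n = 3 they are nearly degenerate.

## The synthetic generator

The generator emulates the screening study end to end.  Defaults, chosen
once to represent the target experiment:

| parameter | default | rationale |
|---|---|---|
| design | 2 groups × 2 strata × 3 replicates | the study layout (6 juvenile, 6 adult, both sexes) |
| K+R frequency | 0.11 | tryptic-proteome realism; yields ~9-residue mean fragments |
| protein lengths | 300–1500 (fixtures pin a 1372-aa planted protein) | spans small regulators to fibrillar collagens; the planted window at regions 20–21 mirrors a C-terminal collagen remodelling signal (aa 1001–1100) |
| digest | ≤ 1 missed cleavage, 6–25 aa window | search settings and the LC-MS/MS detection window |
| detection probability | 0.7 per peptide per sample | mid-range identification rates; generates realistic missingness |
| spectral counts | negative binomial, mean 5, size 2 | overdispersed counts (variance = μ + μ²/2); Poisson in the size → ∞ limit |
| abundance multipliers | lognormal, σ = 0.25 per sample | whole-protein abundance variation the normalization must remove |
| PTM background rates | deamidation 0.03, ox-M 0.08, ox-K 0.02, ox-P 0.05 per eligible residue | sparse background against which planted excesses are read |

Planted regional effects multiply the expected PSC of every peptide whose
span intersects the target window, in the affected group (optionally one
stratum) — the simplest generative stand-in for cleavage-created
fragments becoming trypsin-accessible.  Under the `full` overlap policy
this also leaks planted signal into the regions adjacent to the window
through boundary-spanning peptides, so recovery is scored as a flagged
region within the window ± 1.  The four canonical fixtures are: null,
regional effect (3× on the window), pure abundance confound (juvenile
×3 whole-protein), and hydroxyproline excess (5× rate in the window).
Everything is deterministic in the seed (byte-identical files).

What the generator does *not* model: spectrum-level identification,
retention time and ionization, FDR filtering, shared (non-proteotypic)
peptides, I/L ambiguity, correlated peptide detectability, and real
protein sequence composition (collagen G-X-Y periodicity, compositional
bias).  Passing tests therefore show the pipeline's statistical
machinery behaves as designed under controlled overdispersed-count
conditions — not that any particular biological dataset will yield
calibrated discoveries.

## Operating characteristics (recomputed by `scripts/acceptance.py`)

At the default settings, simulation gives: protein-level family-wise
error ≈ 0.04–0.06 over 500 null studies; fold-change recovery power
rising monotonically across {1.5, 2, 3, 5} to ≈ 1 at fold 5 with ≈ 0.7–
0.85 at fold 3 depending on seed; a pure 3× abundance confound flagged in ≤ 5% of runs
with normalization and ≈ 100% without it.  At these exact study
conditions (3 vs 3, NB size 2, detection 0.7) the fold-3 power of every
*calibrated* contrast we evaluated plateaus near 0.75–0.8; only
anticonservative variants exceed it, and validity was given priority.
The problem sizes above (single-protein operating runs, 100–500
replicates, 200-residue digest-oracle sequences) are the package's
standard verification sizes.

## Numerical notes and edge cases

- Oracle comparisons in tests use 1e-8 relative tolerance; conservation
  checks use 1e-9 absolute.
- Bonferroni is capped at 1; stars (* / ** / ***) are assigned on the
  adjusted p at 0.05 / 0.01 / 0.001, inclusive.
- Proteins observed in fewer than 2 samples per group, or with all-zero
  totals, are skipped with a logged reason, never silently dropped; the
  same applies to unlocatable peptides and malformed table rows (rejects
  reports).
- Single-region proteins degenerate to a plain pooled two-sample
  contrast.
- Sequences containing X/U/B/Z are retained in the database but excluded
  from simulated digestion (undefined tryptic behaviour).
- Zero-count rows are retained as presence information but contribute 0
  to every sum and do not establish presence for the candidate filter.

## Known limitations

The per-region contrast shares one pooled error across regions; under
strong region-to-region variance differences beyond what the square-root
transform stabilizes, per-region calibration is approximate even though
the family-wise rate is controlled at the protein level.  The screen is
two-group only; multi-age-group designs would need a trend contrast.
Region boundaries are fixed at multiples of 50 residues, so effects
centred on a boundary dilute across two regions.
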