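"""Synthetic bottom-up-proteomics study generator.

Builds complete, fully deterministic synthetic studies — a protein
database, a 2 group x 2 stratum x 3 replicate sample design, per-sample
proteotypic peptide tables with overdispersed spectral counts, optional
whole-protein abundance differences, planted region-localized fold
changes, and PTM sites at background or planted-excess rates — together
with the ground-truth record needed for recovery testing.

The default parameters emulate the screening study the pipeline is built
for: trypsin-digestible sequences at a lysine+arginine frequency of 0.11,
detectable peptides of 6-25 residues with at most one missed cleavage,
negative-binomially distributed spectral counts (mean 5 per detected
peptide, size 2), 70% per-sample peptide detection, and juvenile/adult
groups split by sex with three biological replicates each.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digest_mapping import DigestParams, LocatedPeptide, tryptic_digest
from .io_formats import (ModificationSite, PeptideObservation, ProteinRecord,
                         SampleMeta, StudyDesign, write_design, write_fasta,
                         write_peptide_table)

#: rng stream offsets, so each operation draws from its own stream
_PROTEOME_STREAM = 11
_STUDY_STREAM = 29

#: residues eligible for each simulated PTM type
_PTM_ELIGIBLE = {
    "deamidation": "NQ",
    "oxidation_M": "M",
    "oxidation_K": "K",
    "oxidation_P": "P",
}

DEFAULT_PTM_BACKGROUND = {
    "deamidation": 0.03,
    "oxidation_M": 0.08,
    "oxidation_K": 0.02,
    "oxidation_P": 0.05,
}


@dataclass(frozen=True)
class PlantedEffect:
    """A region-localized fold change on expected peptide spectral counts.

    Applies to peptides whose located span intersects the region window
    ``[start_region, end_region]`` (0-based, inclusive), in samples of the
    affected group (optionally restricted to one stratum).  Models
    cleavage-style events that change regional trypsin accessibility.
    """

    protein_index: int
    window: tuple[int, int]
    fold_change: float
    group: str
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.window[0] > self.window[1] or self.window[0] < 0:
            raise ValueError("invalid region window")


@dataclass(frozen=True)
class PlantedPtmEffect:
    """A multiplicative excess of one PTM type inside a region window."""

    protein_index: int
    window: tuple[int, int]
    ptm_type: str
    rate_multiplier: float
    group: str
    stratum: str | None = None


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_proteins: int = 6
    length_range: tuple[int, int] = (300, 1500)
    #: explicit lengths for the first proteins (fixtures pin the planted one)
    protein_lengths: tuple[int, ...] | None = None
    kr_freq: float = 0.11
    groups: tuple[str, str] = ("juvenile", "adult")
    strata: tuple[str, ...] = ("male", "female")
    replicates: int = 3
    baseline_mean: float = 5.0
    dispersion: float = 2.0          # negative-binomial size; Poisson as -> inf
    detection_prob: float = 0.7      # per peptide per sample
    abundance_sigma: float = 0.25    # lognormal sd of per-sample multipliers
    #: systematic whole-protein abundance multiplier per group (confounds)
    group_abundance: Mapping[str, float] = field(default_factory=dict)
    planted_effects: tuple[PlantedEffect, ...] = ()
    ptm_background: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PTM_BACKGROUND))
    planted_ptm_effects: tuple[PlantedPtmEffect, ...] = ()
    digest: DigestParams = DigestParams()

    def __post_init__(self) -> None:
        if not 0 <= self.detection_prob <= 1:
            raise ValueError("detection_prob must lie in [0, 1]")
        for rate in self.ptm_background.values():
            if not 0 <= rate <= 1:
                raise ValueError("PTM background rates must lie in [0, 1]")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion and baseline_mean must be > 0")
        for mult in self.group_abundance.values():
            if mult <= 0:
                raise ValueError("abundance multipliers must be > 0")


def make_design(config: SimulationConfig) -> StudyDesign:
    samples = []
    for stratum in config.strata:
        for group in config.groups:
            for r in range(config.replicates):
                samples.append(SampleMeta(f"{group}_{stratum}_{r + 1}",
                                          group, stratum))
    return StudyDesign(tuple(samples))


def _accession(i: int) -> str:
    return f"SYN{i + 1:04d}"


def generate_proteome(config: SimulationConfig) -> dict[str, ProteinRecord]:
    """Draw i.i.d. sequences hitting the K/R target frequency.

    K and R each get half the target frequency; the other 18 standard
    residues share the remainder equally.  Fully determined by the seed.
    """
    rng = np.random.default_rng([config.seed, _PROTEOME_STREAM])
    others = sorted(set("ACDEFGHIKLMNPQRSTVWY") - set("KR"))
    alphabet = np.array(["K", "R", *others])
    probs = np.array([config.kr_freq / 2, config.kr_freq / 2,
                      *[(1 - config.kr_freq) / len(others)] * len(others)])
    out: dict[str, ProteinRecord] = {}
    for i in range(config.n_proteins):
        if config.protein_lengths is not None and i < len(config.protein_lengths):
            length = config.protein_lengths[i]
        else:
            length = int(rng.integers(config.length_range[0],
                                      config.length_range[1] + 1))
        seq = "".join(rng.choice(alphabet, p=probs, size=length))
        acc = _accession(i)
        out[acc] = ProteinRecord(acc, f"{acc}_SYN", seq)
    return out


@dataclass
class SyntheticTruth:
    """The planted effects a run embeds, resolved per protein accession."""

    config: SimulationConfig
    accessions: tuple[str, ...]

    def _matches(self, effect, acc: str, group: str, stratum: str) -> bool:
        return (self.accessions[effect.protein_index] == acc
                and effect.group == group
                and (effect.stratum is None or effect.stratum == stratum))

    def expected_fold(self, acc: str, region: int, group: str,
                      stratum: str) -> float:
        fold = 1.0
        for e in self.config.planted_effects:
            if self._matches(e, acc, group, stratum) \
                    and e.window[0] <= region <= e.window[1]:
                fold *= e.fold_change
        return fold

    def ptm_rate_multiplier(self, acc: str, region: int, ptm_type: str,
                            group: str, stratum: str) -> float:
        mult = 1.0
        for e in self.config.planted_ptm_effects:
            if self._matches(e, acc, group, stratum) \
                    and e.ptm_type == ptm_type \
                    and e.window[0] <= region <= e.window[1]:
                mult *= e.rate_multiplier
        return mult

    @property
    def planted_accessions(self) -> set[str]:
        return {self.accessions[e.protein_index]
                for e in self.config.planted_effects}

    def to_records(self) -> list[dict]:
        recs = []
        for e in self.config.planted_effects:
            recs.append({"kind": "psc", "accession":
                         self.accessions[e.protein_index],
                         "window": list(e.window), "fold": e.fold_change,
                         "group": e.group, "stratum": e.stratum})
        for e in self.config.planted_ptm_effects:
            recs.append({"kind": "ptm", "accession":
                         self.accessions[e.protein_index],
                         "window": list(e.window), "ptm_type": e.ptm_type,
                         "fold": e.rate_multiplier,
                         "group": e.group, "stratum": e.stratum})
        return recs


def _peptide_fold(peptide: LocatedPeptide, effects: Sequence[PlantedEffect],
                  accessions: Sequence[str], group: str, stratum: str,
                  region_size: int = 50) -> float:
    fold = 1.0
    for e in effects:
        if accessions[e.protein_index] != peptide.protein_accession:
            continue
        if e.group != group or (e.stratum is not None and e.stratum != stratum):
            continue
        w_start = e.window[0] * region_size + 1
        w_end = (e.window[1] + 1) * region_size
        if peptide.start <= w_end and peptide.end >= w_start:
            fold *= e.fold_change
    return fold


def simulate_study(proteome: Mapping[str, ProteinRecord],
                   config: SimulationConfig,
                   collect_ptms: bool = True,
                   ) -> tuple[list[PeptideObservation], StudyDesign,
                              SyntheticTruth]:
    """Simulate per-sample peptide observations for a whole study.

    Per sample and protein the detectable tryptic digest is enumerated,
    each peptide is detected independently with ``detection_prob``, and a
    detected peptide's spectral count is negative binomial with mean
    ``baseline_mean x sample abundance multiplier x planted fold change``.
    PTM sites are sampled per eligible residue of each detected peptide at
    the background rate, inflated inside planted PTM windows.  The result
    is deterministic in the seed.  ``collect_ptms=False`` skips PTM
    sampling (used by the large operating-characteristic simulations).
    """
    rng = np.random.default_rng([config.seed, _STUDY_STREAM])
    design = make_design(config)
    accessions = tuple(proteome.keys())
    truth = SyntheticTruth(config, accessions)

    mults = {
        s.sample_id: float(np.exp(rng.normal(0.0, config.abundance_sigma))
                           * config.group_abundance.get(s.group, 1.0))
        for s in design.samples
    }
    digests = {acc: tryptic_digest(proteome[acc].sequence, config.digest)
               for acc in accessions}
    for acc, peps in digests.items():
        digests[acc] = [replace(p, protein_accession=acc) for p in peps]
    r = config.dispersion

    observations: list[PeptideObservation] = []
    for sample in design.samples:
        mult = mults[sample.sample_id]
        for acc in accessions:
            protein = proteome[acc]
            if protein.has_nonstandard:
                continue  # undefined tryptic behaviour
            peps = digests[acc]
            detected = rng.random(len(peps)) < config.detection_prob
            for pep, keep in zip(peps, detected):
                if not keep:
                    continue
                mu = config.baseline_mean * mult * _peptide_fold(
                    pep, config.planted_effects, accessions,
                    sample.group, sample.stratum)
                count = int(rng.negative_binomial(r, r / (r + mu)))
                mods: tuple[ModificationSite, ...] = ()
                if collect_ptms and config.ptm_background:
                    mods = _sample_ptms(rng, pep, truth, sample, config)
                observations.append(PeptideObservation(
                    sample.sample_id, acc, pep.peptide_sequence, count, mods))
    return observations, design, truth


def _sample_ptms(rng: np.random.Generator, pep: LocatedPeptide,
                 truth: SyntheticTruth, sample: SampleMeta,
                 config: SimulationConfig,
                 region_size: int = 50) -> tuple[ModificationSite, ...]:
    sites = []
    for ptm_type, base_rate in config.ptm_background.items():
        eligible = _PTM_ELIGIBLE.get(ptm_type, "")
        for offset, residue in enumerate(pep.peptide_sequence):
            if residue not in eligible:
                continue
            protein_pos = pep.start + offset
            region = (protein_pos - 1) // region_size
            rate = min(1.0, base_rate * truth.ptm_rate_multiplier(
                pep.protein_accession, region, ptm_type,
                sample.group, sample.stratum))
            if rng.random() < rate:
                sites.append(ModificationSite(residue, offset + 1, ptm_type))
    return tuple(sites)


# ---------------------------------------------------------------------------
# canonical fixture studies

#: collagen-like length for the planted protein: the fibrillar collagens at
#: the centre of the screening use-case are ~1370-1460 residues, and a
#: planted two-region window around aa1000-1100 mirrors the archetypal
#: C-terminal remodelling signal such a screen is meant to catch.
PLANTED_PROTEIN_LENGTH = 1372
PLANTED_WINDOW = (20, 21)


def null_config(seed: int) -> SimulationConfig:
    """Single-protein study with no planted effect (type-I error fixture)."""
    return SimulationConfig(seed=seed, n_proteins=1,
                            protein_lengths=(PLANTED_PROTEIN_LENGTH,))


def regional_effect_config(seed: int, fold: float = 3.0) -> SimulationConfig:
    """Three-protein study with a fold change planted on the long protein."""
    return SimulationConfig(
        seed=seed, n_proteins=3,
        protein_lengths=(PLANTED_PROTEIN_LENGTH, 820, 460),
        planted_effects=(PlantedEffect(0, PLANTED_WINDOW, fold, "juvenile"),))


def abundance_confound_config(seed: int,
                              confound: float = 3.0) -> SimulationConfig:
    """Pure whole-protein abundance shift between groups, no regional effect."""
    return SimulationConfig(seed=seed, n_proteins=1,
                            protein_lengths=(PLANTED_PROTEIN_LENGTH,),
                            group_abundance={"juvenile": confound})


def ptm_effect_config(seed: int, multiplier: float = 5.0) -> SimulationConfig:
    """Hydroxyproline excess planted in the window for the adult group."""
    return SimulationConfig(
        seed=seed, n_proteins=1, protein_lengths=(PLANTED_PROTEIN_LENGTH,),
        planted_ptm_effects=(PlantedPtmEffect(
            0, PLANTED_WINDOW, "oxidation_P", multiplier, "adult"),))


FIXTURE_FACTORIES = {
    "null": null_config,
    "regional": regional_effect_config,
    "confound": abundance_confound_config,
    "ptm": ptm_effect_config,
}


def write_study(out_dir: str | Path, config: SimulationConfig) -> Path:
    """Materialize one study on disk: FASTA, peptide CSV, design, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteome = generate_proteome(config)
    observations, design, truth = simulate_study(proteome, config)
    write_fasta(proteome, out / "proteome.fasta")
    write_peptide_table(observations, out / "peptides.csv")
    write_design(design, out / "design.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump({"seed": config.seed, "effects": truth.to_records()},
                  fh, indent=1)
    return out


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Emit the four canonical studies: null, regional-effect,
    abundance-confound and PTM-effect, each with its truth file."""
    out = Path(out_dir)
    paths = {}
    for name, factory in FIXTURE_FACTORIES.items():
        paths[name] = write_study(out / name, factory(seed))
    return paths
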