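import numpy as np
import pytest

from plf.io_formats import PeptideObservation, ProteinRecord, SampleMeta, StudyDesign


@pytest.fixture
def design_3v3() -> StudyDesign:
    """One stratum, juvenile vs adult, three replicates each."""
    samples = [SampleMeta(f"{g}_male_{i}", g, "male")
               for g in ("juvenile", "adult") for i in (1, 2, 3)]
    return StudyDesign(tuple(samples))


@pytest.fixture
def design_two_strata() -> StudyDesign:
    samples = [SampleMeta(f"{g}_{st}_{i}", g, st)
               for st in ("male", "female")
               for g in ("juvenile", "adult") for i in (1, 2, 3)]
    return StudyDesign(tuple(samples))


@pytest.fixture
def toy_protein() -> ProteinRecord:
    # 120 residues, cleavage sites scattered so peptides span the 50aa
    # region boundaries at 50/100
    rng = np.random.default_rng(42)
    aa = list("ACDEFGHILMNPQSTVWY")
    seq = "".join(
        "K" if (i + 1) % 9 == 0 else aa[rng.integers(len(aa))]
        for i in range(120))
    return ProteinRecord("TOY00001", "TOY00001_SYN", seq)


def obs(sample, acc, pep, count, mods=()):
    return PeptideObservation(sample, acc, pep, count, tuple(mods))
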