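"""Generate the four canonical synthetic studies.

Writes a null study, a regional-effect study (3x fold change on a
two-region window of a collagen-length protein), a whole-protein
abundance-confound study and a hydroxyproline-excess study, each with its
ground-truth record, under results/studies/.
"""

from pathlib import Path

from plf.synthetic_data import make_fixture_suite

OUT = Path(__file__).resolve().parent.parent / "results" / "studies"

if __name__ == "__main__":
    paths = make_fixture_suite(OUT, seed=0)
    for name, p in paths.items():
        n_rows = sum(1 for _ in open(p / "peptides.csv")) - 1
        print(f"{name:10s} -> {p}  ({n_rows} peptide rows)")
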