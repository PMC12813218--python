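"""Regional PTM comparison on the hydroxyproline-excess study.

Counts modified residues (deamidation, oxidized M/K/P) per 50aa region,
normalizes them with the same scale factors as the spectral counts, and
reports the regions with the strongest group differences in median
normalized hydroxyproline count.
"""

from pathlib import Path

from plf import io_formats as iof
from plf.pipeline import run_study
from plf.ptm_regional import ptm_comparisons_to_frame

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = ROOT / "studies" / "ptm"

if __name__ == "__main__":
    proteome = iof.read_fasta(STUDY / "proteome.fasta")
    table = iof.read_peptide_table(STUDY / "peptides.csv")
    design = iof.read_design(STUDY / "design.csv")
    result = run_study(table.observations, proteome, design)

    frames = [ptm_comparisons_to_frame(r.ptm)
              for r in result.strata.values() if r.ptm]
    import pandas as pd
    ptm = pd.concat(frames, ignore_index=True)
    ptm.to_csv(ROOT / "ptm_comparisons.csv", index=False)

    hyp = ptm[ptm.ptm_type == "oxidation_P"]
    top = hyp.reindex(hyp.median_difference.abs()
                      .sort_values(ascending=False).index).head(5)
    print("strongest hydroxyproline differences (juvenile - adult):")
    print(top.to_string(index=False))
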