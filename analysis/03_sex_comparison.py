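"""Candidate screening per sex and the male/female comparison.

Applies the three screening criteria (adjusted p <= 0.05, mean normalized
PSC difference >= 2, minimum mean normalized PSC of 1 in both groups) plus
the presence-in-every-sample rule within each sex, partitions each
protein's peptides into group-unique and shared sets, and writes the
male/female candidate Venn partition.
"""

from pathlib import Path

import pandas as pd

from plf import io_formats as iof
from plf.candidate_screening import candidates_to_frame, compare_candidate_sets
from plf.pipeline import run_study

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = ROOT / "studies" / "regional"

if __name__ == "__main__":
    proteome = iof.read_fasta(STUDY / "proteome.fasta")
    table = iof.read_peptide_table(STUDY / "peptides.csv")
    design = iof.read_design(STUDY / "design.csv")
    result = run_study(table.observations, proteome, design)

    frames, uniq_rows = [], []
    for stratum, res in result.strata.items():
        frames.append(candidates_to_frame(res.candidates))
        for acc, part in sorted(res.unique.items()):
            uniq_rows.append({
                "protein_accession": acc, "stratum": stratum,
                "unique_juvenile": len(part.unique_to_a),
                "unique_adult": len(part.unique_to_b),
                "shared": len(part.shared)})
    cands = pd.concat(frames, ignore_index=True)
    cands.to_csv(ROOT / "candidates.csv", index=False)
    pd.DataFrame(uniq_rows).to_csv(ROOT / "unique_peptides.csv", index=False)

    male = set(cands.query("stratum == 'male' and is_candidate")
               .protein_accession)
    female = set(cands.query("stratum == 'female' and is_candidate")
                 .protein_accession)
    venn = compare_candidate_sets(male, female)
    print(f"male-only candidates:   {sorted(venn.only_first)}")
    print(f"female-only candidates: {sorted(venn.only_second)}")
    print(f"shared candidates:      {sorted(venn.shared)}")
    for r in uniq_rows:
        print(f"{r['protein_accession']}/{r['stratum']}: "
              f"{r['unique_juvenile']} juvenile-unique, "
              f"{r['unique_adult']} adult-unique, {r['shared']} shared")
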