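"""Predict alternative translation start sites rescuing an N-terminal
frameshift.

A frameshift at codon 7 (L7Qfs*21) destroys the annotated reading frame,
but translation can re-initiate at a downstream in-frame ATG in a strong
Kozak context (purine at -3 and G at +4). The scan runs on a synthetic
coding sequence with strong contexts planted at codons 152 and 275 — the
coordinate structure of the two alternative starts reported for Astrin —
and reports the truncated isoforms they would produce.
"""

from civa.isoform import kozak_scan, predicted_mass, truncation_report
from civa.simulate import make_kozak_cds
from civa.variants import parse_hgvs_p

variant = parse_hgvs_p("L7Qfs*21")
print(f"Variant: frameshift at residue {variant.first_affected_residue}; "
      f"predicted truncated product of {variant.truncated_total_length} aa "
      f"({variant.retained_wt_length} wild-type + {variant.novel_tail_length} novel).")

cds = make_kozak_cds([152, 275], length_codons=400, seed=0)
sites = kozak_scan(cds, min_codon=variant.first_affected_residue + 1,
                   stringency="strong")
print(f"\n{len(sites)} strong in-frame start sites downstream of the variant:")
for s in sites:
    print(f"  nt {s.nt_position:4d} (codon {s.codon_index:3d})  "
          f"context {s.context}  consensus score {s.consensus_score:.2f}")
# nt = 3*(codon-1)+1: codon 152 -> nt 454, codon 275 -> nt 823. Initiation
# at codon 152 yields an isoform missing the first 151 residues.

rep = truncation_report(variant, [("coiled-coil", 465, 850), ("C-term tail", 1120, 1193)],
                        protein_length=1193)
print(f"\nFeatures removed by the truncation: {[f[0] for f in rep.removed_features]}")
print(f"(every feature past residue {rep.retained_range[1]} is lost)")

mass = predicted_mass("M" + "A" * 1041)  # ~1042-aa truncated isoform stand-in
print(f"\nIllustrative predicted mass of a 1042-aa isoform: {mass:.1f} kDa")
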