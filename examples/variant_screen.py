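"""Screen a multi-database variant table for CIVa candidates.

Builds a small table mixing the two Astrin (SPAG5) loss-of-function
variants with bystander missense variants, merges the per-database counts
without pooling overlapping cohorts, and applies the prevalence filter:
truncating consequence, carried by at least two individuals.
"""

from civa.variants import (
    VariantRecord, allele_frequency, civa_filter, lollipop_export, merge_databases,
)

tables = [
    ("GH", [
        VariantRecord("SPAG5", "L7Qfs*21", {"GH": (134, 1)}),
        VariantRecord("SPAG5", "Q1012*", {"GH": (2, 0)}),
        VariantRecord("SPAG5", "V5M", {"GH": (40, 0)}),
        VariantRecord("SKA3", "Q70Kfs*7", {"GH": (1906, 2)}),
    ]),
    ("gnomAD", [
        VariantRecord("SPAG5", "L7Qfs*21", {"gnomAD": (320, 6)}),
        VariantRecord("SPAG5", "R27*", {"gnomAD": (1, 0)}),
    ]),
    ("GenomeAsia", [
        VariantRecord("SPAG5", "L7Qfs*21", {"GenomeAsia": (13, 0)}),
    ]),
]

merged = merge_databases(tables)
print(f"{len(merged)} distinct variants after merging 3 databases")

candidates = civa_filter(merged, min_individuals=2)
print(f"{len(candidates)} CIVa candidates (truncating, >= 2 carriers in one database):")
for c in candidates:
    af = allele_frequency(*c.variant.counts.get("gnomAD", c.variant.counts["GH"]),
                          n_individuals=70000)
    print(f"  {c.variant.gene_symbol:6s} {c.variant.hgvs_p:12s} "
          f"carriers={c.n_individuals:5d} homozygous_seen={c.homozygous_observed} "
          f"(illustrative AF {af:.2e})")

# R27* (1 carrier) and V5M (missense) are excluded: the filter demands a
# truncating consequence seen in at least two individuals of one cohort.
print("\nLollipop table for SPAG5 (position, category, carriers, homozygotes):")
print(lollipop_export("SPAG5", [r for r in merged if r.gene_symbol == "SPAG5"])
      .to_string(index=False))
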