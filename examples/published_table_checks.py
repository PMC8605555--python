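"""Aggregate the published camelid TE count tables and check their totals.

The published survey reports per-superfamily counts for four camelid
genomes.  This script re-derives every per-species total from the row
counts with the package's aggregation helpers, alongside the structural
LTR-candidate retention percentages (retained / found after homology
screening, whole percent).
"""

from te_prospector import reported

print("LTR superfamily totals:       ", dict(reported.species_totals(reported.LTR_SUPERFAMILY_COUNTS)))
print("non-LTR clade totals:         ", dict(reported.species_totals(reported.NONLTR_CLADE_COUNTS)))
print("Class II family totals (rows):", dict(reported.species_totals(reported.CLASS2_FAMILY_COUNTS)))
print("Helitron *_DR sums:           ", dict(reported.helitron_dr_sums()))
print(
    "LTR candidate retention %:    ",
    {sp: reported.retention_percent(sp) for sp in reported.SPECIES},
)
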