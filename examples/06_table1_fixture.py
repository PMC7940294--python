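"""Work with the packaged regional species table.

The package ships a transcription of the study's species table (totals,
habitat occurrence, sex ratios, egg counts, reproductive mode per region).
This script reproduces the headline community composition numbers from it.
"""

from oribatida import habitat_shares, load_table1, mode_shares

table1 = load_table1()

sch = table1.mode_totals("SCH")
print(f"SCH individuals: sexual {sch['sexual']} + parthenogenetic "
      f"{sch['parthenogenetic']} = {sch.sum()} (printed total "
      f"{table1.region_total('SCH')})")

shares = habitat_shares(table1).set_index(["region", "habitat"])
for region in ("ALB", "SCH"):
    pct = shares.loc[(region, "forest"), "pct_individuals"]
    print(f"{region}: {pct:.1f}% of individuals in forests")

modes = mode_shares(table1).set_index(["region", "habitat", "mode"])
pct = modes.loc[("SCH", "forest", "parthenogenetic"), "pct_individuals"]
print(f"SCH forests: {pct:.1f}% of individuals are parthenogenetic")
# Schorfheide forests are the one group where parthenogens dominate; in all
# other region x habitat groups sexual species hold about three quarters.
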