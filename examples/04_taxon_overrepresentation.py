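"""Test subfamilies for taxonomic overrepresentation on the packaged census.

Loads the species x subfamily gene-count table that ships with the package,
restricts the universe to the two Dikarya groups, and runs one-sided Fisher's
exact tests for every subfamily x group pair.
"""

from npsphylome import fisher_overrepresentation, fisher_scan, load_table1

cm = load_table1()
print(f"{len(cm.species)} species, {len(cm.subfamilies)} subfamily columns, "
      f"{int(cm.counts.values.sum())} genes")

groups = ["Euascomycota", "Basidiomycota"]
for subfamily in ("EAS", "PKS;NRPS", "NPS12/ETP mod 2"):
    for group in groups:
        odds, p, table = fisher_overrepresentation(cm, group, subfamily, groups=groups)
        flag = "*" if p < 0.05 else " "
        print(f"{subfamily:18s} in {group:14s} a={table.a:3d} b={table.b:2d} "
              f"OR={odds:7.2f} p={p:.2e} {flag}")

scan = fisher_scan(cm, groups=groups)
print("\nsignificant at 0.05:")
print(scan[scan.significant][["group", "subfamily", "a", "b", "p_value"]]
      .to_string(index=False))

# The euascomycete-only multimodular subfamily (EAS) and the hybrid
# PKS;NRPS group are overrepresented in euascomycetes; the standalone-A
# NPS12-like group is overrepresented in basidiomycetes (driven by the eight
# P. placenta copies). AAR also surfaces in basidiomycetes: because their
# NRPS complements are tiny, the single universal lysine-pathway gene is a
# large share of their genes — the test is about proportions, not counts.
# a = genes in the subfamily inside the group, b = outside it; the odds
# ratio uses the Haldane continuity correction on zero cells.
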