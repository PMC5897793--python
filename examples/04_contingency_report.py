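"""Enrichment arithmetic for a genome-scale screen.

Given per-query spuriousness calls at the 0.8 threshold and a binary
annotation flag (e.g. "has a protein-family match"), the 2x2 contingency
table quantifies how much more often unannotated proteins are called
spurious.  Here the table is filled with the counts of a published
100,000-protein survey to show the derived rates.
"""

from orfscreen import ContingencyTable, pct_spurious_per_submitted, rates

table = ContingencyTable(a=551, b=193, c=13_863, d=75_638, threshold=0.8)
r = rates(table)

print(f"called queries: {table.total}; spurious calls: {table.n_spurious}")
print(f"spurious among unannotated: {r['pct_spurious_no_annot']:.1f}%")
print(f"spurious among annotated:   {r['pct_spurious_annot']:.2f}%")
print(f"enrichment ratio:           {r['enrichment_ratio']:.0f}x")
print(f"overall spurious (called):  {r['pct_spurious_overall']:.2f}%")
print(f"overall spurious (of 100,000 submitted, no-calls included): "
      f"{pct_spurious_per_submitted(table, 100_000):.2f}%")
print(f"annotated among spurious:   {r['pct_annot_among_spurious']:.0f}%")

print("\nUnannotated proteins are ~15x more likely to be called spurious — "
      "the\nexpected behaviour if most spurious gene calls fall outside "
      "known families.")
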