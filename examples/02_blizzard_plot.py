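"""Draw blizzard plots for a spurious ORF and a true gene.

Each row is one homologous DNA match (best E-value on top), each column one
query residue.  White pixels are stop codons in the implied translation —
snow across the plot marks a spurious call — red pixels are methionines and
black pixels whole-codon deletions.
"""

from orfscreen import Cell, GeneratorProfile, build_matrix, generate, render

for regime, fname in (("spurious_neutral", "blizzard_spurious.png"),
                      ("coding", "blizzard_real.png")):
    d = generate(GeneratorProfile(regime=regime, n_homologs=25,
                                  query_length_aa=200, subst_rate=0.3,
                                  indel_rate=0.02, seed=7))
    matrix = build_matrix(d.hitsets()[0])
    render(matrix, fname)
    print(f"{fname}: {matrix.n_rows} rows x {matrix.n_cols} columns, "
          f"{matrix.count(Cell.STOP)} stop pixels, "
          f"{matrix.count(Cell.DELETION)} deletion pixels")

print("\nThe spurious plot is snow-filled; the real gene's plot is almost "
      "stop-free\n(deletion dots in multiples of three bases are themselves "
      "evidence of coding).")
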