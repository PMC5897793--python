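# orfscreen

**orfscreen** flags spurious prokaryotic gene predictions — "gene
unprediction". Most protein sequences in public databases come from gene
callers, not experiments, and even a small false-positive rate leaves tens of
thousands of phantom proteins in the archives. orfscreen scores each
predicted protein's probability of being such a phantom from a single strong
signal: **stop codons in the translations of homologous DNA**.

If a predicted protein is real, the DNA regions homologous to it in other
genomes are under protein-level selection, so their reading frames stay open.
If the prediction is spurious — a mistranslated repeat, an ORF shadowing a
real gene on the opposite strand, a pseudogene — the homologous DNA evolves
neutrally and, with 3 of the 64 codons being stops, in-frame stop codons
accumulate quickly.

It is written for genome-annotation and database-curation work: screening a
proteome for dubious gene calls, quality-checking submitted annotations, or
triaging short hypothetical proteins.

## Method

A query protein is searched with `tblastn` (translated homology search, any
nucleotide database) and the matches at E-value ≤ 10 are summarised by three
features:

```
F1 = log( (number of stop codons across all matched sequences + 1)
          / total number of amino acids in all matched sequences )
F2 = log( number of homologous sequence hits )
F3 = log( query sequence length )
```

Stop codons are counted only in the body of each match — not within the
first or last 10 alignment columns — because local alignments over-extend
into non-homologous sequence; the `+1` pseudocount keeps F1 defined when no
stop is seen. A Gaussian-process classifier (RBF kernel, Laplace
approximation, z-scored features) maps (F1, F2, F3) to P(spurious); scores
≥ 0.8 are called spurious. Genomes that recode UGA as tryptophan
(translation table 4, Mycoplasma-like bacteria) are searched with the
correct code so their TGA codons do not masquerade as stops. Queries with no
homologs at all are reported as no-calls, never scored.

The evidence is visualised as a **blizzard plot**: one row per hit, one
column per query residue, stop codons as white pixels (spurious queries look
snowed-in), methionines red, whole-codon deletions black, and each row
coloured by match significance on a rainbow −log10(E-value) scale.

Because the original training corpora (curated spurious families plus
reviewed proteins vs a 1,507-genome collection) are external downloads, the
package ships a first-class synthetic generator instead: true genes with
silently diverged homologs, neutrally evolving spurious ORFs, shadow ORFs
antisense to real genes, UGA=Trp genomes, and selenoprotein-like conserved
stop columns — all with known truth alignments, so the whole pipeline is
testable offline, and with hooks (`orfscreen train`) to retrain on your own
labeled data.

## Worked example

`examples/01_score_a_gene_call.py` trains a model on a small synthetic
benchmark, then scores a real gene and a spurious ORF (120 aa, 15 homologs,
30% divergence each):

```
q_coding_42: 0 body stops in 1800 aligned aa over 15 hits -> P(spurious) = 0.153 -> call: real
q_spurious_neutral_42: 56 body stops in 1800 aligned aa over 15 hits -> P(spurious) = 0.898 -> call: spurious
```

The real gene's homologs contain no in-frame stops (F1 = log(1/1800) ≈
−7.5), the spurious ORF's homologs carry 56 (F1 ≈ −3.5), and the classifier
turns that gap into probabilities on either side of the 0.8 threshold. The
other examples render blizzard plots, run the cross-validated benchmark, and
reproduce the contingency arithmetic of a genome-scale screen.

The same pipeline is available from the shell:

```bash
orfscreen synth --n-per-class 50 --seed 1 --out-dir data
orfscreen features --hits data/hits.tab --query data/queries.faa --out features.csv
orfscreen train --features features.csv --labels data/labels.csv --seed 1 --out model.joblib
orfscreen score --features features.csv --model model.joblib --out scores.csv
orfscreen plot --hits data/hits.tab --query data/queries.faa --query-id q0000_real_coding --out blizzard.png
orfscreen search --query proteins.faa --db mygenomes --out hits.tab   # live tblastn
```

## Layout

- `src/orfscreen/searchio.py` — queries, hits, the tabular dialect, live tblastn
- `src/orfscreen/features.py` — F1/F2/F3 extraction and the edge-trim rule
- `src/orfscreen/model.py` — GP classifier, CV, metrics, persistence
- `src/orfscreen/blizzard.py` — blizzard matrices and rendering
- `src/orfscreen/synthetic.py` — ground-truth generator (five regimes)
- `src/orfscreen/report.py` — threshold calls and contingency rates
- `docs/methods.md` — model assumptions, parameter choices, limitations
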