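# Methods

## The signal and its assumptions

orfscreen decides whether a predicted prokaryotic protein is a spurious gene
call by asking whether the DNA homologous to it elsewhere keeps its reading
frame open. Under protein-level purifying selection, nonsense substitutions
are purged; without it, stop codons appear at the neutral acceptance
fraction (3/64 of codons under the standard bacterial code). The method
therefore assumes that homologous DNA can be found at all, that the
translated-search alignment frames are correct, and that in-frame stops in
homologs are evidence against coding rather than artifacts. Three known
violations are handled or documented:

- **UGA = Trp genomes** (translation table 4, Mycoplasma-like bacteria):
  routed into a separate search pass with the correct code, so TGA never
  counts as a stop for those subjects.
- **Selenoproteins**: a genuinely conserved UGA (selenocysteine) column
  looks exactly like a stop column and inflates the score. This is a known
  failure mode; no correction is attempted, and the synthetic
  `selenoprotein_like` regime exists precisely to exhibit it.
- **Sequencing errors and genuine pseudogenes** contribute background stops
  even for real genes; the classifier, not a hard cutoff on stop counts,
  absorbs that background.

## Features

For a query of length L with hits H (each a local alignment whose subject
translation uses `*` for stops):

- `F1 = ln((S + 1) / A)`, where `S` is the number of `*` characters falling
  in the *body* of each alignment — alignment-column index ≥ 10 and
  < n_columns − 10 — and `A` is the total number of non-gap subject
  characters over all hits, untrimmed. The trim guards against homologous
  over-extension at alignment ends; the asymmetric treatment (trimmed
  numerator, untrimmed denominator) is deliberate. Alignments of ≤ 20
  columns have no body and contribute zero stops. The trim is measured in
  alignment columns, gap columns included — a defensible alternative would
  trim 10 *query residues*; with gaps near edges the two differ slightly.
- `F2 = ln(n_hits)`, counting retained HSPs (not distinct subject
  sequences; a subject with two local alignments contributes two hits).
- `F3 = ln(L)`.

Natural logarithm throughout; the base is a monotone rescaling absorbed by
feature normalisation, but it is frozen and recorded in saved models. A
query with zero hits gets a `no_homologs` status and is excluded from
scoring and from contingency tables (its count is reported separately).

## Hit acquisition

The tabular dialect (`# orfscreen-tab v1`) is a 9-column outfmt-6-style
table — qseqid, sseqid, evalue, qstart, qend, sstart, send, qseq, sseq —
plus an optional 10th `gcode` column recording the subject's translation
table, which the writer always emits so that write→parse round-trips are
lossless. Raw `tblastn -outfmt "6 qseqid sseqid evalue qstart qend sstart
send qseq sseq"` output parses unchanged. BLAST conventions are preserved
(1-based inclusive coordinates, minus strand signalled by sstart > send);
internal arithmetic converts through one pair of helpers. Each row is
checked against the alignment invariants (equal aligned lengths, no
dual-gap columns, query segment matching the query sequence, 3 nucleotides
per aligned residue); violations raise with the line number rather than
being dropped, since a silently skipped row would bias F1 downward.

Defaults: E-value threshold 10 (chosen as the precision/recall balance for
this problem), at most 500 hits per query (bounded memory; matches common
search-engine defaults), self-hits retained (an exclusion flag exists).
Hits are sorted by (E-value, subject id, subject start) so every downstream
artifact is deterministic. Duplicate or overlapping HSPs from one subject
are all kept.

## Classifier

A Gaussian-process classifier over z-scored (F1, F2, F3): kernel
`constant × RBF` with one isotropic length-scale, logistic link, Laplace
approximation, hyperparameters by marginal-likelihood optimisation with 3
restarts under a caller seed (scikit-learn's implementation). Spurious is
the positive class. Normalisation statistics come from the training set
only and are persisted in the model archive together with a format version,
the log base and the trim width; a stored model predicts deterministically,
and loading rejects missing normalisation blocks or version mismatches.
Calls use P(spurious) ≥ 0.8 by default — "at or above", so 0.80 is
spurious and 0.79 is not. The threshold is operational, not probabilistic
dogma; the calibration table lets users pick their own.

Cross-validation is stratified k-fold (default k = 8), shuffled under the
given seed, with per-fold ROC/PR curves and a pooled out-of-fold
calibration table (10 equal-width bins). For a balanced corpus of 2 × 3,107
samples this partition yields test folds of 776/777 and training
complements up to 5,438. Accuracy is measured at the 0.5 probability cut;
AUC by trapezoidal integration of the empirical ROC.

No pretrained model file ships with the repository; `examples/` and the
`orfscreen train` command give a deterministic one-command recipe to train
on the synthetic benchmark or on user-supplied labeled features.

## Synthetic data: what it emulates, and what it does not

The generator produces query proteins and homolog sets by *mutating the
query's own back-translated DNA*, so truth alignments are known without a
search engine (a live-tblastn integration test confirms a real search
recovers ≥ 90% of truth subjects on these genomes). Substitutions are
uniform over the three alternative nucleotides (Jukes–Cantor-like), which
makes the per-codon stop probability exactly enumerable — the simulation is
tested against that enumeration. Regimes:

- `coding`: mutations applied, then any codon that became a stop is
  reverted (purifying selection); translations stay internally stop-free.
- `spurious_neutral`: no codon-level constraint; stops accumulate at the
  neutral fraction.
- `shadow_orf`: the query frame is antisense to a real gene; selection is
  applied on the *sense* strand only, so sense-tolerated changes freely
  create antisense stops. Query back-translation avoids the three codons
  whose reverse complement is a stop, keeping both frames initially open.
- `code4_coding`: ~70% of tryptophans encoded as TGA; homologs mutate under
  code-4 constraints; hits carry `genetic_code=4`.
- `selenoprotein_like`: coding homologs plus one conserved TGA column
  (placed inside the trimmed body), the query carrying `U` there.

E-values are assigned deterministically as a decreasing function of
alignment identity (`10^(2 − 0.35·n_identities)`, clipped to [1e-180,
9.5] and rounded to 3 significant figures so files round-trip exactly).
Homolog DNA is embedded in random flanks, half on the minus strand.

The default benchmark is balanced: real = 3:1 coding : code-4,
spurious = 3:1 neutral : shadow; per-query homolog counts uniform in
[5, 40], divergence uniform in [0.1, 0.4] substitutions/site, whole-codon
deletion rate 0.02 per codon; query lengths uniform in 30–650 aa for real
and 30–150 aa for spurious queries, reflecting where spurious gene calls
concentrate. These are field-plausible settings chosen once; the benchmark
is regenerated byte-identically from (n_per_class, seed).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: phylogenetic correlation among homologs (each
homolog is an independent draw from the query, so effective evidence per
hit is optimistic), frameshifting indels (all indels are whole-codon
deletions; real pseudogenes frameshift, which tblastn handles by splitting
HSPs), sequencing error, compositional bias, and the adversarial cases the
original corpora contain (degraded transposon families, annotation
artifacts). Cross-validated accuracy on this benchmark (~99% at 200 per
class) is therefore a correctness check of the pipeline under its own
assumptions, not an estimate of field performance, which published work on
real corpora puts in the mid-90s.

## Blizzard plots

`build_matrix` maps each alignment onto query coordinates: columns that
consume a query residue map one-to-one to matrix columns; subject
insertions are not drawn; subject gaps are DELETION pixels (in protein
space every subject gap is a multiple of three nucleotides). The matrix
shows **all** stops, untrimmed — plot and feature counts intentionally
differ at alignment edges. Row order is the hit-set order (ascending
E-value, deterministic ties); row colour is −log10(E-value) clipped to
[0, 50] on a rainbow colormap; stop/methionine/deletion pixels are pure
white/red/black so pixel counts can be checked against matrix cell counts
exactly.

## Numerical and degenerate-input choices

- Zero E-values (reported by search engines for overwhelming matches) map
  to the top of the significance scale rather than infinity.
- Feature extraction is exact integer counting plus one `log`; no
  tolerance is involved. Model training involves an optimiser; determinism
  is guaranteed only at fixed seed and library versions, which the tests
  exercise.
- Per-feature standard deviations of zero (degenerate training sets) are
  replaced by 1 before z-scoring.
- Duplicated training samples shift GP predictions slightly (the marginal
  likelihood optimum moves); the tests bound the shift rather than assert
  identity.
- `rates()` recomputes every rate from counts and raises a named error on
  any zero denominator, including a zero annotated-spurious rate that
  would make the enrichment ratio undefined.
- Two "overall spurious" rates exist: per-called (excluding no-calls) and
  per-submitted; both are available and labeled.

## Known limitations

Beyond the generator gaps above: taxonomy-based routing of genetic codes is
not implemented (codes are per-subject annotations supplied by the user);
no correction for selenocysteine/pyrrolysine recoding; no copy-number or
indel-count features (transposon-family false positives remain); HSP
deduplication is not attempted. The search engine is treated as pluggable —
any tool that can emit the 9-column dialect works.
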