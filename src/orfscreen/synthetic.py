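"""Ground-truth generator for homologous-DNA hit sets.

Real training corpora for the spurious-gene problem (curated spurious
families plus reviewed proteins, searched against a large genome collection)
are external resources; this module generates labeled stand-ins with known
truth, emulating the biological regimes that drive the stop-codon signal:

* ``coding`` — a true gene whose homologs diverged under purifying selection:
  nucleotides mutate but codons that would become stops are rejected, so the
  implied translations are internally stop-free.
* ``spurious_neutral`` — a spurious ORF: the "homologous" DNA is not under
  protein-level selection, so substitutions are accepted blindly and stop
  codons accumulate at the neutral rate (3 of the 64 codons are stops under
  table 11).
* ``shadow_orf`` — an ORF antisense to a real gene.  Selection acts on the
  sense strand; mutations silent in the sense frame freely create stops in
  the antisense reading.
* ``code4_coding`` — a true gene from a UGA=Trp genome (translation table 4):
  tryptophans are encoded by TGA, which reads as ``'*'`` under the standard
  code but ``'W'`` under code 4.
* ``selenoprotein_like`` — a true gene with one conserved internal UGA
  (selenocysteine) column, the known failure mode of stop-codon screening.

Because homologs are produced by mutating the query's own DNA, the true
alignments are known without running a search engine; they are emitted
directly in the orfscreen-tab dialect, with E-values assigned as a
deterministic decreasing function of alignment identity.  Substitutions are
uniform over the three alternative nucleotides (Jukes-Cantor-like), which
keeps the per-codon stop probability exactly enumerable.  Indels are
whole-codon deletions only; frameshifts are not modelled.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .searchio import (AlignmentHit, HitSet, QueryProtein, write_hits)

REGIMES = ("coding", "spurious_neutral", "shadow_orf", "code4_coding",
           "selenoprotein_like")
REAL_REGIMES = ("coding", "code4_coding", "selenoprotein_like")

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_NT_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _NT_INDEX[_b] = _i

#: codons whose reverse complement is a stop (excluded from shadow-ORF
#: back-translation so both strands stay open)
_ANTISENSE_STOPS = frozenset({"TTA", "CTA", "TCA"})

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def stop_codons(code: int = 11) -> frozenset[str]:
    """Stop codons of an NCBI translation table (code 4: TGA is Trp)."""
    table = CodonTable.unambiguous_dna_by_id[code]
    return frozenset(table.stop_codons)


def _codon_choices(code: int, avoid_antisense_stops: bool = False
                   ) -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[code]
    choices: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        if avoid_antisense_stops and codon in _ANTISENSE_STOPS:
            continue
        choices.setdefault(aa, []).append(codon)
    choices["U"] = ["TGA"]  # selenocysteine
    return choices


def random_protein(length: int, rng: np.random.Generator,
                   start_met: bool = True) -> str:
    """Uniform random amino-acid sequence (optionally starting with Met)."""
    aas = rng.choice(list(_AA_ORDER), size=length)
    seq = "".join(aas)
    if start_met:
        seq = "M" + seq[1:]
    return seq


def back_translate(protein: str, rng: np.random.Generator, code: int = 11,
                   avoid_antisense_stops: bool = False) -> str:
    """Encode a protein as DNA, codons drawn uniformly per residue."""
    choices = _codon_choices(code, avoid_antisense_stops)
    codons = []
    for aa in protein:
        opts = choices[aa.upper()]
        codons.append(opts[rng.integers(len(opts))])
    return "".join(codons)


def _stop_ints(code: int) -> np.ndarray:
    return np.array(sorted(
        _NT_INDEX[np.frombuffer(c.encode(), dtype=np.uint8)]
        @ np.array([16, 4, 1])
        for c in stop_codons(code)))


def mutate_dna(dna: str, rate: float, rng: np.random.Generator,
               forbid_stops_code: int | None = None) -> str:
    """Substitute each site with probability ``rate``.

    A substituted site takes each of the three alternative nucleotides with
    equal probability.  With ``forbid_stops_code`` set, any complete frame-0
    codon that becomes a stop under that table is reverted to its original
    codon (purifying selection against nonsense changes); with ``None`` the
    process is neutral and stops accumulate.
    """
    arr = np.frombuffer(dna.encode(), dtype=np.uint8).copy()
    orig = arr.copy()
    idx = _NT_INDEX[arr]
    if (idx < 0).any():
        raise ValueError("DNA contains characters outside ACGT")
    mask = rng.random(arr.size) < rate
    shift = rng.integers(1, 4, size=arr.size)
    new_idx = (idx + shift) % 4
    arr[mask] = _NT[new_idx[mask]]
    if forbid_stops_code is not None and arr.size >= 3:
        n_codons = arr.size // 3
        cod = arr[: 3 * n_codons].reshape(n_codons, 3)
        cod_int = _NT_INDEX[cod] @ np.array([16, 4, 1])
        bad = np.isin(cod_int, _stop_ints(forbid_stops_code))
        if bad.any():
            cod[bad] = orig[: 3 * n_codons].reshape(n_codons, 3)[bad]
    return arr.tobytes().decode()


def translate(dna: str, code: int = 11) -> str:
    """Translate frame 0 with ``'*'`` for stop codons."""
    return str(Seq(dna).translate(table=code))


def revcomp(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


@dataclass(frozen=True)
class GeneratorProfile:
    """Conditions for one query and its homolog set."""

    regime: str
    n_homologs: int = 20
    query_length_aa: int = 150
    subst_rate: float = 0.3
    indel_rate: float = 0.0  # per-codon whole-codon deletion probability
    seed: int = 0
    tga_trp_fraction: float = 0.7  # code4: fraction of Trp encoded as TGA
    forced_stop_columns: tuple[int, ...] = ()  # selenoprotein-like only

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        for name in ("subst_rate", "indel_rate", "tga_trp_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_homologs < 1:
            raise ValueError("n_homologs must be >= 1")
        if self.query_length_aa < 10:
            raise ValueError("query_length_aa must be >= 10")
        if self.forced_stop_columns and self.regime != "selenoprotein_like":
            raise ValueError(
                f"regime {self.regime!r} cannot force stop columns: "
                "contradictory profile")
        for c in self.forced_stop_columns:
            if not 1 <= c <= self.query_length_aa:
                raise ValueError(f"forced stop column {c} outside query")


@dataclass
class SyntheticDataset:
    """Queries, truth alignments, genomes and labels, plus provenance."""

    queries: list[QueryProtein]
    hits: list[AlignmentHit]
    genomes: dict[str, str]
    labels: dict[str, str]  # query_id -> "real" | "spurious"
    provenance: dict

    def hitsets(self) -> list[HitSet]:
        by_q: dict[str, list[AlignmentHit]] = {q.id: [] for q in self.queries}
        for h in self.hits:
            by_q[h.query_id].append(h)
        out = []
        for q in self.queries:
            hits = sorted(by_q[q.id],
                          key=lambda h: (h.evalue, h.subject_id, h.s_start))
            out.append(HitSet(query=q, hits=hits))
        return out

    def write(self, outdir: str | os.PathLike) -> None:
        """Write queries.faa, genomes.fna, hits.tab, labels.csv,
        provenance.yaml (byte-identical under a repeated profile + seed)."""
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "queries.faa"), "w") as fh:
            for q in self.queries:
                fh.write(f">{q.id}\n")
                for i in range(0, q.length, 60):
                    fh.write(q.sequence[i:i + 60] + "\n")
        with open(os.path.join(outdir, "genomes.fna"), "w") as fh:
            for sid in sorted(self.genomes):
                fh.write(f">{sid}\n")
                g = self.genomes[sid]
                for i in range(0, len(g), 60):
                    fh.write(g[i:i + 60] + "\n")
        write_hits(self.hits, os.path.join(outdir, "hits.tab"))
        with open(os.path.join(outdir, "labels.csv"), "w") as fh:
            fh.write("query_id,label\n")
            for q in self.queries:
                fh.write(f"{q.id},{self.labels[q.id]}\n")
        with open(os.path.join(outdir, "provenance.yaml"), "w") as fh:
            yaml.safe_dump(self.provenance, fh, sort_keys=True)

    def merge(self, other: "SyntheticDataset") -> "SyntheticDataset":
        return SyntheticDataset(
            queries=self.queries + other.queries,
            hits=self.hits + other.hits,
            genomes={**self.genomes, **other.genomes},
            labels={**self.labels, **other.labels},
            provenance={"merged": [self.provenance, other.provenance]},
        )


def _truth_evalue(q_seq: str, s_aln: str) -> float:
    """Deterministic E-value: decreasing in the number of identities."""
    n_id = sum(1 for q, s in zip(q_seq, s_aln) if s != "-" and q == s)
    e = 10.0 ** max(-180.0, 2.0 - 0.35 * n_id)
    return float(f"{min(e, 9.5):.3g}")


def _embed(hom_dna: str, rng: np.random.Generator,
           minus: bool) -> tuple[str, int, int]:
    """Place homolog DNA in random flanks; return (genome, s_start, s_end)."""
    left = "".join(rng.choice(list("ACGT"), size=rng.integers(20, 120)))
    right = "".join(rng.choice(list("ACGT"), size=rng.integers(20, 120)))
    insert = revcomp(hom_dna) if minus else hom_dna
    genome = left + insert + right
    start = len(left) + 1
    end = len(left) + len(hom_dna)
    return (genome, end, start) if minus else (genome, start, end)


def _homolog_from_query_frame(query_dna: str, profile: GeneratorProfile,
                              rng: np.random.Generator,
                              ) -> tuple[str, np.ndarray]:
    """Mutate (and delete codons from) the query-frame DNA of one homolog.

    Returns the homolog DNA (deletions applied) and the boolean keep-mask
    over query codon positions.
    """
    regime = profile.regime
    if regime == "coding":
        dna = mutate_dna(query_dna, profile.subst_rate, rng,
                         forbid_stops_code=11)
    elif regime == "spurious_neutral":
        dna = mutate_dna(query_dna, profile.subst_rate, rng,
                         forbid_stops_code=None)
    elif regime == "code4_coding":
        codons = [query_dna[i:i + 3] for i in range(0, len(query_dna), 3)]
        for i, c in enumerate(codons):
            if c == "TGG" and rng.random() < profile.tga_trp_fraction:
                codons[i] = "TGA"
        dna = mutate_dna("".join(codons), profile.subst_rate, rng,
                         forbid_stops_code=4)
    elif regime == "selenoprotein_like":
        dna = mutate_dna(query_dna, profile.subst_rate, rng,
                         forbid_stops_code=11)
        codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
        for col in profile.forced_stop_columns:
            codons[col - 1] = "TGA"  # conserved selenocysteine column
        dna = "".join(codons)
    elif regime == "shadow_orf":
        # selection acts on the sense strand; the query frame is antisense
        sense = revcomp(query_dna)
        sense_mut = mutate_dna(sense, profile.subst_rate, rng,
                               forbid_stops_code=11)
        dna = revcomp(sense_mut)
    else:  # pragma: no cover
        raise AssertionError(regime)

    n_codons = len(dna) // 3
    keep = rng.random(n_codons) >= profile.indel_rate
    for col in profile.forced_stop_columns:
        keep[col - 1] = True
    if not keep.any():
        keep[0] = True
    if not keep.all():
        dna = "".join(dna[3 * i:3 * i + 3]
                      for i in range(n_codons) if keep[i])
    return dna, keep


def generate(profile: GeneratorProfile,
             query_id: str | None = None) -> SyntheticDataset:
    """Generate one query plus its homolog hit set under a profile."""
    rng = np.random.default_rng(profile.seed)
    regime = profile.regime
    L = profile.query_length_aa

    prof = profile
    if regime == "selenoprotein_like" and not profile.forced_stop_columns:
        # one conserved UGA column, inside the trimmed body
        lo, hi = 12, L - 12
        if hi <= lo:
            raise ValueError("selenoprotein_like query too short for an "
                             "internal stop column")
        col = int(rng.integers(lo, hi + 1))
        prof = GeneratorProfile(**{**asdict(profile),
                                   "forced_stop_columns": (col,)})

    protein = random_protein(L, rng)
    if regime == "code4_coding":
        # guarantee tryptophans for TGA recoding to act on
        n_w = max(3, L // 25)
        pos = rng.choice(np.arange(1, L), size=n_w, replace=False)
        p = list(protein)
        for i in pos:
            p[i] = "W"
        protein = "".join(p)
    elif regime == "selenoprotein_like":
        p = list(protein)
        for col in prof.forced_stop_columns:
            p[col - 1] = "U"
        protein = "".join(p)

    qid = query_id or f"q_{regime}_{profile.seed}"
    query = QueryProtein(id=qid, sequence=protein)
    query_dna = back_translate(
        protein, rng, code=4 if regime == "code4_coding" else 11,
        avoid_antisense_stops=(regime == "shadow_orf"))

    code = 4 if regime == "code4_coding" else 11
    hits: list[AlignmentHit] = []
    genomes: dict[str, str] = {}
    for j in range(prof.n_homologs):
        hom_dna, keep = _homolog_from_query_frame(query_dna, prof, rng)
        aa = translate(hom_dna, code=code)
        s_aln_chars = []
        it = iter(aa)
        for k in keep:
            s_aln_chars.append(next(it) if k else "-")
        s_aln = "".join(s_aln_chars)
        sid = f"{qid}_hom{j:03d}"
        minus = bool(rng.random() < 0.5)
        genome, s_start, s_end = _embed(hom_dna, rng, minus)
        genomes[sid] = genome
        hits.append(AlignmentHit(
            query_id=qid, subject_id=sid,
            evalue=_truth_evalue(protein, s_aln),
            q_start=1, q_end=L, s_start=s_start, s_end=s_end,
            q_aln=protein, s_aln=s_aln, genetic_code=code))

    label = "real" if regime in REAL_REGIMES else "spurious"
    prov = asdict(prof)
    prov["forced_stop_columns"] = list(prov["forced_stop_columns"])
    return SyntheticDataset(
        queries=[query], hits=hits, genomes=genomes,
        labels={qid: label},
        provenance={"profile": prov},
    )


# benchmark composition: regime cycle per class, one entry per query
_REAL_CYCLE = ("coding", "coding", "coding", "code4_coding")
_SPURIOUS_CYCLE = ("spurious_neutral", "spurious_neutral",
                   "spurious_neutral", "shadow_orf")

# spurious gene calls concentrate at short lengths; real genes span the
# typical bacterial range
LENGTH_RANGE_REAL = (30, 650)
LENGTH_RANGE_SPURIOUS = (30, 150)
HOMOLOG_RANGE = (5, 40)
SUBST_RATE_RANGE = (0.1, 0.4)
BENCHMARK_INDEL_RATE = 0.02


def generate_benchmark(n_per_class: int, seed: int = 0) -> SyntheticDataset:
    """Balanced labeled benchmark mixing regimes.

    Real queries are coding (3/4) and code-4 coding (1/4); spurious queries
    are neutrally-evolving ORFs (3/4) and shadow ORFs (1/4).  Per-query
    homolog counts, lengths and divergence are drawn from the ranges above.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if n_per_class < 8:
        warnings.warn(
            f"n_per_class={n_per_class} is too small for stratified "
            "8-fold cross-validation", stacklevel=2)
    rng = np.random.default_rng(seed)
    dataset: SyntheticDataset | None = None
    specs = []
    for i in range(n_per_class):
        specs.append(("real", _REAL_CYCLE[i % len(_REAL_CYCLE)], i))
        specs.append(("spurious",
                      _SPURIOUS_CYCLE[i % len(_SPURIOUS_CYCLE)], i))
    for label, regime, i in specs:
        lo, hi = (LENGTH_RANGE_REAL if label == "real"
                  else LENGTH_RANGE_SPURIOUS)
        profile = GeneratorProfile(
            regime=regime,
            n_homologs=int(rng.integers(*HOMOLOG_RANGE, endpoint=True)),
            query_length_aa=int(rng.integers(lo, hi, endpoint=True)),
            subst_rate=float(rng.uniform(*SUBST_RATE_RANGE)),
            indel_rate=BENCHMARK_INDEL_RATE,
            seed=int(rng.integers(2 ** 31)),
        )
        d = generate(profile, query_id=f"q{i:04d}_{label}_{regime}")
        dataset = d if dataset is None else dataset.merge(d)
    assert dataset is not None
    dataset.provenance = {"benchmark": {"n_per_class": n_per_class,
                                        "seed": seed}}
    return dataset
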