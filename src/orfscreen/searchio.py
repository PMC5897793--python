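"""Acquire and normalise translated-homology search results.

A query protein is searched against a nucleotide database with ``tblastn``
(six-frame translated search); each high-scoring segment pair (HSP) carries the
aligned query string and the aligned *translated* subject string, in which stop
codons appear as ``'*'``.  The rest of the pipeline only ever works with these
alignment strings, so precomputed tabular files substitute fully for a live
search.

Tabular dialect ("orfscreen-tab v1"): tab-separated, first line
``# orfscreen-tab v1``, columns ``qseqid sseqid evalue qstart qend sstart send
qseq sseq [gcode]``.  ``qseq``/``sseq`` are the aligned strings with ``'-'``
gaps; ``sseq`` uses ``'*'`` for stops.  The optional ``gcode`` column records
the translation table used for the subject (11 default, 4 where UGA = Trp);
raw 9-column ``tblastn -outfmt 6`` output with the same column order parses
unchanged.
"""

from __future__ import annotations

import glob
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace

import yaml
from Bio import SeqIO

TAB_HEADER = "# orfscreen-tab v1"
TAB_COLUMNS = ("qseqid", "sseqid", "evalue", "qstart", "qend",
               "sstart", "send", "qseq", "sseq")

DEFAULT_EVALUE_THRESHOLD = 10.0
DEFAULT_MAX_HITS = 500
DEFAULT_GENETIC_CODE = 11

#: residues accepted in a query protein: the 20 standard amino acids plus
#: ambiguity codes B/Z/X and selenocysteine U.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XUBZ")

_KNOWN_TABLES = frozenset({1, 2, 3, 4, 5, 6, 9, 10, 11, 12, 13, 14, 15, 16,
                           21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 33})


class SearchUnavailableError(RuntimeError):
    """The external search binary cannot be run; use precomputed-input mode."""


class TabFormatError(ValueError):
    """A row of a tabular hits file is malformed or violates an invariant."""


def default_evalue_threshold() -> float:
    """E-value cutoff balancing precision and recall for homolog harvesting."""
    return DEFAULT_EVALUE_THRESHOLD


def ungapped(aln: str) -> str:
    """Strip alignment gaps from an aligned string."""
    return aln.replace("-", "")


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> 0-based half-open [start, end)."""
    return start - 1, end


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive [start, end]."""
    return start + 1, end


@dataclass(frozen=True)
class QueryProtein:
    """A predicted protein to be screened, as read from FASTA."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"query {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"query {self.id!r}: invalid residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """One translated-search HSP.

    Coordinates follow BLAST conventions: 1-based inclusive; ``q_start``/
    ``q_end`` are amino-acid positions in the query, ``s_start``/``s_end``
    nucleotide positions in the subject with ``s_start > s_end`` on the minus
    strand.  ``s_aln`` is the subject's translation with ``'*'`` for stop
    codons.
    """

    query_id: str
    subject_id: str
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    q_aln: str
    s_aln: str
    genetic_code: int = DEFAULT_GENETIC_CODE

    @property
    def minus_strand(self) -> bool:
        return self.s_start > self.s_end

    @property
    def n_columns(self) -> int:
        return len(self.q_aln)

    def validate(self, query: QueryProtein | None = None) -> None:
        """Raise ``TabFormatError`` naming the first violated invariant."""
        if self.evalue < 0:
            raise TabFormatError(f"hit {self.subject_id}: negative E-value")
        if len(self.q_aln) != len(self.s_aln):
            raise TabFormatError(
                f"hit {self.subject_id}: aligned strings differ in length "
                f"({len(self.q_aln)} vs {len(self.s_aln)})")
        if self.q_start > self.q_end or self.q_start < 1:
            raise TabFormatError(
                f"hit {self.subject_id}: bad query coordinates "
                f"[{self.q_start}, {self.q_end}]")
        for q, s in zip(self.q_aln, self.s_aln):
            if q == "-" and s == "-":
                raise TabFormatError(
                    f"hit {self.subject_id}: column gapped in both strings")
        n_q = len(ungapped(self.q_aln))
        if n_q != self.q_end - self.q_start + 1:
            raise TabFormatError(
                f"hit {self.subject_id}: query span {self.q_start}-"
                f"{self.q_end} does not cover {n_q} aligned residues")
        n_s = len(ungapped(self.s_aln))
        if abs(self.s_end - self.s_start) + 1 != 3 * n_s:
            raise TabFormatError(
                f"hit {self.subject_id}: subject span is not 3 nucleotides "
                f"per aligned residue (|{self.s_end} - {self.s_start}| + 1 "
                f"!= 3 * {n_s})")
        if query is not None:
            expect = query.sequence[self.q_start - 1:self.q_end].upper()
            if ungapped(self.q_aln).upper() != expect:
                raise TabFormatError(
                    f"hit {self.subject_id}: aligned query segment does not "
                    f"match query {query.id!r} at [{self.q_start}, "
                    f"{self.q_end}]")


@dataclass
class HitSet:
    """A query plus its significance-filtered homologous hits.

    ``hits`` are sorted by ascending E-value (ties by subject id then subject
    start) so that downstream row order is deterministic.
    """

    query: QueryProtein
    hits: list[AlignmentHit]
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD

    @property
    def n_hits(self) -> int:
        return len(self.hits)


@dataclass
class GeneticCodeMap:
    """Routes subjects to translation tables (11 default; 4 for UGA=Trp)."""

    default_code: int = DEFAULT_GENETIC_CODE
    overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, code in self.overrides.items():
            if code not in _KNOWN_TABLES:
                raise ValueError(
                    f"override for {sid!r}: unknown translation table {code}")
        if self.default_code not in _KNOWN_TABLES:
            raise ValueError(
                f"unknown default translation table {self.default_code}")

    def code_for(self, subject_id: str) -> int:
        return self.overrides.get(subject_id, self.default_code)

    def codes_in_use(self) -> list[int]:
        return sorted({self.default_code, *self.overrides.values()})


@dataclass
class SearchConfig:
    """Runtime options for hit acquisition, loadable from YAML."""

    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD
    max_hits: int = DEFAULT_MAX_HITS
    code_overrides: dict[str, int] = field(default_factory=dict)
    exclude_self_hits: bool = False

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SearchConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"evalue_threshold", "max_hits", "code_overrides",
                 "exclude_self_hits"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def codes(self) -> GeneticCodeMap:
        return GeneticCodeMap(overrides=dict(self.code_overrides))


def read_query_fasta(path: str | os.PathLike) -> list[QueryProtein]:
    """Load query proteins from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [QueryProtein(id=r.id, sequence=str(r.seq)) for r in records]


# ---------------------------------------------------------------------------
# tabular dialect


def write_hits(hits: list[AlignmentHit], path: str | os.PathLike) -> None:
    """Write hits in the orfscreen-tab v1 dialect (with the gcode column)."""
    with open(path, "w") as fh:
        fh.write(TAB_HEADER + "\n")
        for h in hits:
            fh.write("\t".join([
                h.query_id, h.subject_id, format(h.evalue, ".3g"),
                str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end),
                h.q_aln, h.s_aln, str(h.genetic_code),
            ]) + "\n")


def _parse_row(line: str, lineno: int, codes: GeneticCodeMap) -> AlignmentHit:
    parts = line.rstrip("\n").split("\t")
    if len(parts) not in (9, 10):
        raise TabFormatError(
            f"line {lineno}: expected 9 or 10 tab-separated fields, "
            f"got {len(parts)}")
    try:
        hit = AlignmentHit(
            query_id=parts[0], subject_id=parts[1], evalue=float(parts[2]),
            q_start=int(parts[3]), q_end=int(parts[4]),
            s_start=int(parts[5]), s_end=int(parts[6]),
            q_aln=parts[7], s_aln=parts[8],
            genetic_code=(int(parts[9]) if len(parts) == 10
                          else codes.code_for(parts[1])),
        )
    except ValueError as exc:
        raise TabFormatError(f"line {lineno}: {exc}") from exc
    return hit


def parse_search_output(
    path: str | os.PathLike,
    queries: list[QueryProtein],
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    *,
    codes: GeneticCodeMap | None = None,
    max_hits: int = DEFAULT_MAX_HITS,
    exclude_self_hits: bool = False,
) -> list[HitSet]:
    """Parse a tabular hits file into one :class:`HitSet` per query.

    Hits above ``evalue_threshold`` are dropped; each retained row is checked
    against the alignment invariants (malformed rows raise
    :class:`TabFormatError` naming the line, never silently dropped).  Hits
    are sorted ascending by E-value with (subject_id, s_start) tie-breaks and
    capped at ``max_hits`` per query.
    """
    codes = codes or GeneticCodeMap()
    by_query: dict[str, QueryProtein] = {}
    for q in queries:
        if q.id in by_query:
            raise ValueError(f"duplicate query id {q.id!r}")
        by_query[q.id] = q
    buckets: dict[str, list[AlignmentHit]] = {q.id: [] for q in queries}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            hit = _parse_row(line, lineno, codes)
            if hit.query_id not in by_query:
                raise TabFormatError(
                    f"line {lineno}: unknown query id {hit.query_id!r}")
            try:
                hit.validate(by_query[hit.query_id])
            except TabFormatError as exc:
                raise TabFormatError(f"line {lineno}: {exc}") from exc
            if hit.evalue > evalue_threshold:
                continue
            if exclude_self_hits and hit.subject_id == hit.query_id:
                continue
            buckets[hit.query_id].append(hit)

    hitsets = []
    for q in queries:
        hits = sorted(buckets[q.id],
                      key=lambda h: (h.evalue, h.subject_id, h.s_start))
        hitsets.append(HitSet(query=q, hits=hits[:max_hits],
                              evalue_threshold=evalue_threshold))
    return hitsets


# ---------------------------------------------------------------------------
# live search (external tblastn)


def _require_binary(name: str) -> str:
    exe = shutil.which(name)
    if exe is None:
        raise SearchUnavailableError(
            f"external search unavailable: {name!r} not found on PATH; "
            "run the search elsewhere and supply its tabular output in "
            "precomputed-input mode")
    return exe


def make_blast_db(fasta_path: str | os.PathLike,
                  db_path: str | os.PathLike) -> str:
    """Format a nucleotide FASTA into a BLAST database at ``db_path``."""
    exe = _require_binary("makeblastdb")
    if not os.path.exists(fasta_path) or os.path.getsize(fasta_path) == 0:
        raise ValueError(f"empty or missing database FASTA: {fasta_path}")
    subprocess.run(
        [exe, "-dbtype", "nucl", "-in", str(fasta_path),
         "-out", str(db_path)],
        check=True, capture_output=True, text=True)
    return str(db_path)


def _db_is_formatted(db_path: str | os.PathLike) -> bool:
    return bool(glob.glob(str(db_path) + ".n*"))


def run_search(
    queries: list[QueryProtein] | QueryProtein,
    db_path: str | os.PathLike,
    codes: GeneticCodeMap | None = None,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    *,
    out_path: str | os.PathLike | None = None,
    max_target_seqs: int = DEFAULT_MAX_HITS,
) -> str:
    """Run tblastn against a formatted nucleotide database.

    One search is run per genetic code in use (``-db_gencode``); rows from the
    code-4 pass are kept only for subjects routed to code 4 and vice versa, so
    UGA-recoding genomes are translated with UGA = Trp.  Returns the path of
    the concatenated orfscreen-tab v1 output.
    """
    if isinstance(queries, QueryProtein):
        queries = [queries]
    codes = codes or GeneticCodeMap()
    exe = _require_binary("tblastn")
    if not _db_is_formatted(db_path):
        raise ValueError(
            f"database {db_path} is missing or not formatted; run "
            "make_blast_db first")
    if out_path is None:
        fd, out_path = tempfile.mkstemp(suffix=".tab", prefix="orfscreen-")
        os.close(fd)

    with tempfile.NamedTemporaryFile(
            "w", suffix=".faa", delete=False) as qf:
        for q in queries:
            qf.write(f">{q.id}\n{q.sequence}\n")
        query_fasta = qf.name

    rows: list[AlignmentHit] = []
    try:
        for code in codes.codes_in_use():
            proc = subprocess.run(
                [exe, "-query", query_fasta, "-db", str(db_path),
                 "-evalue", str(evalue_threshold),
                 "-db_gencode", str(code),
                 "-max_target_seqs", str(max_target_seqs),
                 "-outfmt", "6 " + " ".join(TAB_COLUMNS)],
                check=True, capture_output=True, text=True)
            for lineno, line in enumerate(proc.stdout.splitlines(), start=1):
                if not line.strip():
                    continue
                hit = _parse_row(line, lineno, codes)
                if codes.code_for(hit.subject_id) == code:
                    rows.append(replace(hit, genetic_code=code))
    finally:
        os.unlink(query_fasta)

    write_hits(rows, out_path)
    return str(out_path)
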