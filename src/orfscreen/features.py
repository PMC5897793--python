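"""Stop-codon features extracted from a set of homologous hits.

Three features summarise a hit set, all on a natural-log scale:

* ``f1 = log((n_stops + 1) / n_aligned_aa)`` — the relative amount of stop
  codons in the presumed translations of homologous DNA.  The ``+1``
  pseudocount keeps the logarithm defined when no stops are seen.  Stop
  codons are counted only in the *body* of each alignment — not within the
  first or last 10 alignment columns — because local alignments tend to
  over-extend into non-homologous flanking sequence.  The denominator counts
  every aligned subject position, untrimmed.
* ``f2 = log(n_hits)`` — how many homologous HSPs were found.
* ``f3 = log(query length in aa)``.

Together f2 and f3 describe the dimensions of the blizzard plot and f1 its
"snowfall".  A query with no homologs at all yields no features; it is a
no-call, not a score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .searchio import AlignmentHit, HitSet

DEFAULT_EDGE_WIDTH = 10


class NoHomologsError(ValueError):
    """The query has no hits, so its spuriousness cannot be assessed."""


@dataclass(frozen=True)
class TrimPolicy:
    """Edge trim for stop counting, in alignment columns (default 10)."""

    edge_width: int = DEFAULT_EDGE_WIDTH

    def __post_init__(self) -> None:
        if self.edge_width < 0:
            raise ValueError("edge_width must be >= 0")


@dataclass(frozen=True)
class FeatureVector:
    """The (f1, f2, f3) triple plus the raw counts behind it."""

    f1: float
    f2: float
    f3: float
    n_stops: int
    n_aligned_aa: int
    n_hits: int

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f1, self.f2, self.f3)


def count_body_stops(hit: AlignmentHit,
                     policy: TrimPolicy = TrimPolicy()) -> int:
    """Count ``'*'`` columns in the trimmed body of one hit.

    Columns are alignment columns (gaps included in the indexing); a column
    is in the body when ``edge_width <= i < n_columns - edge_width``.
    Alignments no longer than twice the edge width have no body and
    contribute zero.
    """
    w = policy.edge_width
    n = hit.n_columns
    if n <= 2 * w:
        return 0
    return hit.s_aln.count("*", w, n - w)


def aligned_aa_count(hits: list[AlignmentHit]) -> int:
    """Total aligned subject positions (non-gap characters, untrimmed)."""
    if not hits:
        raise ValueError("aligned_aa_count requires at least one hit")
    return sum(len(h.s_aln) - h.s_aln.count("-") for h in hits)


def extract_features(hitset: HitSet,
                     policy: TrimPolicy = TrimPolicy()) -> FeatureVector:
    """Turn a hit set into its feature vector.

    Raises :class:`NoHomologsError` for an empty hit set: such queries are
    excluded from scoring rather than given any probability.
    """
    if not hitset.hits:
        raise NoHomologsError(
            f"query {hitset.query.id!r}: no homologous sequences; excluded")
    n_stops = sum(count_body_stops(h, policy) for h in hitset.hits)
    n_aa = aligned_aa_count(hitset.hits)
    n_hits = len(hitset.hits)
    return FeatureVector(
        f1=math.log((n_stops + 1) / n_aa),
        f2=math.log(n_hits),
        f3=math.log(hitset.query.length),
        n_stops=n_stops,
        n_aligned_aa=n_aa,
        n_hits=n_hits,
    )


def features_table(hitsets: list[HitSet],
                   policy: TrimPolicy = TrimPolicy()) -> pd.DataFrame:
    """Per-query feature rows; empty hit sets get status ``no_homologs``."""
    rows = []
    for hs in hitsets:
        try:
            fv = extract_features(hs, policy)
            rows.append(dict(query_id=hs.query.id, n_hits=fv.n_hits,
                             n_aligned_aa=fv.n_aligned_aa,
                             n_stops=fv.n_stops, f1=fv.f1, f2=fv.f2,
                             f3=fv.f3, status="ok"))
        except NoHomologsError:
            rows.append(dict(query_id=hs.query.id, n_hits=0,
                             n_aligned_aa=0, n_stops=0, f1=float("nan"),
                             f2=float("nan"), f3=float("nan"),
                             status="no_homologs"))
    return pd.DataFrame(rows, columns=["query_id", "n_hits", "n_aligned_aa",
                                       "n_stops", "f1", "f2", "f3",
                                       "status"])
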