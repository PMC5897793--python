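"""Aggregate spuriousness predictions into summary statistics.

Calls at a probability threshold (default 0.8, with "at or above" semantics)
are crossed against an external binary annotation flag per query — typically
whether the protein matches a curated protein-family database — giving a 2x2
contingency table from which enrichment rates are derived.  Queries with no
homologs are no-calls: they are excluded from the table but their count is
reported alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import DEFAULT_THRESHOLD, Prediction


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of called predictions by (annotation flag, score >= t).

    a: no annotation, score >= t      b: annotation, score >= t
    c: no annotation, score <  t      d: annotation, score <  t
    """

    a: int
    b: int
    c: int
    d: int
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_spurious(self) -> int:
        return self.a + self.b


def tabulate(predictions: list[Prediction],
             annotation_flags: dict[str, bool],
             t: float = DEFAULT_THRESHOLD
             ) -> tuple[ContingencyTable, int]:
    """Cross predictions with annotation flags at threshold ``t``.

    Returns the table over called predictions plus the number of no-calls
    excluded.  Every called prediction must have a flag; missing ids raise.
    """
    missing = sorted({p.query_id for p in predictions
                      if p.call != "no_call"
                      and p.query_id not in annotation_flags})
    if missing:
        raise KeyError(f"ids missing from annotation flags: {missing}")
    a = b = c = d = n_no_call = 0
    for p in predictions:
        if p.call == "no_call":
            n_no_call += 1
            continue
        annotated = annotation_flags[p.query_id]
        if p.p_spurious >= t:
            b += annotated
            a += not annotated
        else:
            d += annotated
            c += not annotated
    return ContingencyTable(a, b, c, d, threshold=t), n_no_call


def rates(table: ContingencyTable) -> dict[str, float]:
    """Derived percentages and the enrichment ratio (recomputed, not stored).

    Percentages are on the 0-100 scale at full precision; round for display.
    """
    for name, denom in (("pct_spurious_no_annot", table.a + table.c),
                        ("pct_spurious_annot", table.b + table.d),
                        ("pct_spurious_overall", table.total),
                        ("pct_annot_among_spurious", table.n_spurious)):
        if denom == 0:
            raise ZeroDivisionError(f"rate {name} undefined: zero denominator")
    pct_no_annot = 100.0 * table.a / (table.a + table.c)
    pct_annot = 100.0 * table.b / (table.b + table.d)
    if pct_annot == 0:
        raise ZeroDivisionError(
            "rate enrichment_ratio undefined: no annotated query scored "
            "at or above the threshold")
    return {
        "pct_spurious_overall": 100.0 * table.n_spurious / table.total,
        "pct_spurious_no_annot": pct_no_annot,
        "pct_spurious_annot": pct_annot,
        "enrichment_ratio": pct_no_annot / pct_annot,
        "pct_annot_among_spurious": 100.0 * table.b / table.n_spurious,
    }


def pct_spurious_per_submitted(table: ContingencyTable,
                               n_submitted: int) -> float:
    """Overall spurious percentage against the full submitted set.

    The per-called overall rate uses only queries that produced homologs;
    this variant divides by everything submitted, no-calls included.
    """
    if n_submitted <= 0:
        raise ZeroDivisionError(
            "rate pct_spurious_per_submitted undefined: zero denominator")
    return 100.0 * table.n_spurious / n_submitted
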