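"""Blizzard plots: per-hit, per-residue rasters of translated homology.

One row per hit (most significant on top), one column per query residue.
Stop codons in the translated homolog are white pixels — in a spurious gene
call they fall throughout the alignment like snow — methionines are red,
whole-codon deletions black, and the base colour of each row encodes match
significance on a rainbow scale over -log10(E-value).

The matrix shows *all* stops in the aligned region, untrimmed: the 10-column
edge trim applies only to feature extraction, so a plot may show a stop that
the features ignore (e.g. one hugging the C-terminus).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib import cm, colors  # noqa: E402

from .searchio import HitSet

SIGNIFICANCE_CLIP = (0.0, 50.0)  # display range of -log10(E-value)

COLOR_STOP = (1.0, 1.0, 1.0)
COLOR_MET = (1.0, 0.0, 0.0)
COLOR_DELETION = (0.0, 0.0, 0.0)
COLOR_UNALIGNED = (0.88, 0.88, 0.88)


class Cell(IntEnum):
    UNALIGNED = 0
    MATCH = 1
    STOP = 2
    MET = 3
    DELETION = 4


@dataclass
class BlizzardMatrix:
    """Pixel codes for rendering: rows are hits, columns query positions."""

    query_id: str
    cells: np.ndarray  # (n_rows, n_cols) of Cell codes
    row_significance: np.ndarray  # -log10(E-value), clipped
    row_labels: list[str]

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    def count(self, code: Cell) -> int:
        return int((self.cells == code).sum())


def build_matrix(hitset: HitSet) -> BlizzardMatrix:
    """Map each hit's alignment onto query coordinates.

    Alignment columns that consume a query residue (no gap in the query
    string) map one-to-one onto matrix columns; subject insertions consume no
    query coordinate and are not drawn.  A subject gap at a query-consuming
    column is a deletion pixel.  Rows keep the hit-set order (ascending
    E-value, deterministic tie-breaks).
    """
    if not hitset.hits:
        raise ValueError(
            f"query {hitset.query.id!r} has no hits; no plot possible")
    n_cols = hitset.query.length
    cells = np.zeros((len(hitset.hits), n_cols), dtype=np.int8)
    sig = np.empty(len(hitset.hits))
    labels = []
    lo, hi = SIGNIFICANCE_CLIP
    for r, hit in enumerate(hitset.hits):
        qpos = hit.q_start - 1  # 0-based query index
        for qc, sc in zip(hit.q_aln, hit.s_aln):
            if qc == "-":
                continue  # subject insertion: no query coordinate
            if sc == "*":
                cells[r, qpos] = Cell.STOP
            elif sc == "-":
                cells[r, qpos] = Cell.DELETION
            elif sc.upper() == "M":
                cells[r, qpos] = Cell.MET
            else:
                cells[r, qpos] = Cell.MATCH
            qpos += 1
        with np.errstate(divide="ignore"):
            sig[r] = np.clip(-np.log10(hit.evalue) if hit.evalue > 0 else hi,
                             lo, hi)
        labels.append(hit.subject_id)
    return BlizzardMatrix(query_id=hitset.query.id, cells=cells,
                          row_significance=sig, row_labels=labels)


def matrix_to_rgb(matrix: BlizzardMatrix) -> np.ndarray:
    """(n_rows, n_cols, 3) float RGB image for the matrix."""
    lo, hi = SIGNIFICANCE_CLIP
    norm = colors.Normalize(vmin=lo, vmax=hi)
    cmap = matplotlib.colormaps["rainbow"]
    base = cmap(norm(matrix.row_significance))[:, :3]  # per-row colour
    rgb = np.empty((matrix.n_rows, matrix.n_cols, 3))
    rgb[:] = np.asarray(COLOR_UNALIGNED)
    match = matrix.cells == Cell.MATCH
    rgb[match] = np.repeat(base, matrix.n_cols, axis=0).reshape(
        matrix.n_rows, matrix.n_cols, 3)[match]
    rgb[matrix.cells == Cell.STOP] = COLOR_STOP
    rgb[matrix.cells == Cell.MET] = COLOR_MET
    rgb[matrix.cells == Cell.DELETION] = COLOR_DELETION
    return rgb


def render(matrix: BlizzardMatrix, out_path, format: str | None = None,
           dpi: int = 150) -> str:
    """Render the matrix to PNG or SVG (inferred from the extension)."""
    if matrix.n_rows == 0:
        raise ValueError("cannot render an empty matrix")
    if format is None:
        ext = str(out_path).rsplit(".", 1)[-1].lower()
        format = ext if ext in ("png", "svg") else "png"
    rgb = matrix_to_rgb(matrix)
    fig, ax = plt.subplots(
        figsize=(8, max(2.0, min(10.0, 0.35 + matrix.n_rows * 0.08))))
    ax.imshow(rgb, interpolation="nearest", aspect="auto",
              extent=(0.5, matrix.n_cols + 0.5, matrix.n_rows + 0.5, 0.5))
    ax.set_xlabel("query position (aa)")
    ax.set_ylabel("hit (by significance)")
    ax.set_title(f"{matrix.query_id}: {matrix.n_rows} homologous sequences")
    lo, hi = SIGNIFICANCE_CLIP
    sm = cm.ScalarMappable(norm=colors.Normalize(lo, hi),
                           cmap=matplotlib.colormaps["rainbow"])
    fig.colorbar(sm, ax=ax, label=r"$-\log_{10}$ E-value")
    fig.savefig(out_path, format=format, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return str(out_path)
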