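"""Per-copy flank coverage matrices with paired full/empty row ordering.

Rows are ordered by total flank coverage in the full-site line
(descending) and the identical permutation is applied to the empty-site
matrix so corresponding rows stay aligned between the two heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coverage import FlankProfile


@dataclass
class FlankMatrix:
    """One row per element copy, one column per bp offset from the edge."""

    copy_ids: list[str]
    values: np.ndarray  # shape (n_copies, flank_len)
    side: str
    line_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 and len(self.copy_ids) > 0:
            raise ValueError("matrix must be 2-dimensional")
        if len(self.copy_ids) != self.values.shape[0]:
            raise ValueError("row count must match number of copy ids")

    @property
    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)


def flank_matrix(
    profiles: Sequence[FlankProfile], side: str | None = None, line_label: str = ""
) -> FlankMatrix:
    """Stack per-copy profiles into a matrix in stable input order."""
    if not profiles:
        return FlankMatrix([], np.zeros((0, 0)), side or "five_prime", line_label)
    side = side or profiles[0].side
    n = len(profiles[0].values)
    for p in profiles:
        if p.side != side:
            raise ValueError("mixed 5'/3' profiles in one matrix")
        if len(p.values) != n:
            raise ValueError("profiles of mixed lengths")
    return FlankMatrix(
        [p.copy_id for p in profiles],
        np.vstack([p.values for p in profiles]),
        side,
        line_label,
    )


def order_rows(
    matrix_full: FlankMatrix, matrix_empty: FlankMatrix
) -> tuple[FlankMatrix, FlankMatrix]:
    """Sort both matrices by the full-site matrix's total row coverage.

    Descending row sums, ties broken by copy_id (lexicographic) for
    determinism; the empty-site matrix is reindexed to the same copy order
    so rows stay paired.
    """
    if set(matrix_full.copy_ids) != set(matrix_empty.copy_ids):
        raise ValueError("matrices must share the same copy ids")
    sums = matrix_full.row_sums
    order = sorted(
        range(len(matrix_full.copy_ids)),
        key=lambda i: (-sums[i], matrix_full.copy_ids[i]),
    )
    ordered_ids = [matrix_full.copy_ids[i] for i in order]
    empty_pos = {cid: i for i, cid in enumerate(matrix_empty.copy_ids)}
    empty_order = [empty_pos[cid] for cid in ordered_ids]
    full_sorted = FlankMatrix(
        ordered_ids,
        matrix_full.values[order],
        matrix_full.side,
        matrix_full.line_label,
    )
    empty_sorted = FlankMatrix(
        ordered_ids,
        matrix_empty.values[empty_order],
        matrix_empty.side,
        matrix_empty.line_label,
    )
    return full_sorted, empty_sorted


def write_flank_matrix(matrix: FlankMatrix, path) -> None:
    """TSV export: header row of bp offsets, one row per copy."""
    with open(path, "w") as fh:
        offsets = "\t".join(str(i) for i in range(matrix.values.shape[1]))
        fh.write(f"copy_id\t{offsets}\n")
        for cid, row in zip(matrix.copy_ids, matrix.values):
            fh.write(cid + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


def plot_flank_matrix(matrix: FlankMatrix, path, cmap: str = "viridis") -> None:
    # thin rendering adapter; the matrix itself is the tested artifact
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.02 * len(matrix.copy_ids))))
    if matrix.values.size:
        ax.imshow(
            np.log1p(matrix.values), aspect="auto", interpolation="nearest", cmap=cmap
        )
    ax.set_xlabel("distance from element edge (bp)")
    ax.set_ylabel("copies")
    ax.set_title(f"{matrix.line_label} {matrix.side}")
    fig.savefig(path, dpi=150)
    plt.close(fig)
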