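"""Functional hierarchy scores from directed-influence asymmetry.

For a nonnegative between-area connection-loading matrix ``e`` with element
``e_ij`` the strength of the connection from area j to area i, the directed
influence asymmetry index is

    DAI_ij = (e_ij − e_ji) / (e_ij + e_ji)  ∈ [−1, 1],

positive when j drives i more than the reverse.  DAIs are scaled by 2.5
(mapping the attainable range onto [−2.5, 2.5], i.e. as many hierarchy levels
as areas for 6 areas), then per target area all source DAIs are shifted so
the smallest equals 1, and the per-area hierarchy score is the mean of the
shifted values in the target's row.  Net drivers of the network obtain the
lowest scores: ranking areas by ascending H orders them from sender to
receiver along the stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HierarchyResult", "dai_matrix", "hierarchy_scores",
           "connection_matrix"]


@dataclass
class HierarchyResult:
    """DAI matrices and per-area hierarchy scores."""

    dai: np.ndarray          # antisymmetric, zero diagonal
    scaled: np.ndarray       # 2.5 * dai
    shifted: np.ndarray      # per-target-row shifted, off-diagonal >= 1
    scores: np.ndarray       # H per area (target-row aggregation)
    areas: list | None = None

    def ranking(self) -> np.ndarray:
        """Area indices ordered by ascending H (drivers first)."""
        return np.argsort(self.scores, kind="stable")


def dai_matrix(e: np.ndarray) -> np.ndarray:
    """Directed influence asymmetry index of a connection-strength matrix.

    ``e[i, j]`` is the loading of the connection from area j to area i
    (source = column).  Pairs with ``e_ij + e_ji = 0`` map to DAI 0; the
    diagonal is zero.  The result is antisymmetric and invariant to any
    positive rescaling of ``e``.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("connection strengths must be nonnegative")
    num = e - e.T
    den = e + e.T
    with np.errstate(divide="ignore", invalid="ignore"):
        dai = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(dai, 0.0)
    return dai


def hierarchy_scores(dai: np.ndarray, areas=None, scale: float = 2.5,
                     aggregate: str = "mean",
                     scale_mode: str = "fixed",
                     shift_mode: str = "fixed") -> HierarchyResult:
    """Scaled/shifted DAI and per-area hierarchy scores.

    Parameters
    ----------
    dai : antisymmetric DAI matrix (checked to 1e-8).
    scale : fixed scaling factor; 2.5 maps DAI ∈ [−1, 1] onto [−2.5, 2.5],
        allowing as many hierarchy levels as areas for a 6-area network.
    aggregate : "mean" (default) or "sum" over a target's shifted row; the
        resulting ranking is identical for complete matrices.
    scale_mode : "fixed" multiplies by ``scale``; "minmax" rescales the
        observed off-diagonal values onto [−scale, scale] instead.
    shift_mode : "fixed" (default) adds ``1 + scale`` so the attainable range
        [−2.5, 2.5] maps onto hierarchy levels [1, 6]; this preserves the net
        directed-influence level of each area, puts the network's driver at
        the bottom of the ranking, and reverses the ranking when all
        connections are reversed.  "per_target" instead shifts each target
        row so its smallest entry is 1; note this removes the between-row
        level information (only within-row spread survives) and is kept as a
        literal-procedure variant.
    """
    dai = np.asarray(dai, dtype=float)
    if not np.allclose(dai, -dai.T, atol=1e-8):
        raise ValueError("DAI matrix is not antisymmetric")
    n = dai.shape[0]
    off = ~np.eye(n, dtype=bool)
    if scale_mode == "minmax":
        m = np.max(np.abs(dai[off])) if np.any(off) else 1.0
        scaled = dai * (scale / m if m > 0 else 1.0)
    else:
        scaled = scale * dai
    shifted = scaled.copy()
    if shift_mode == "per_target":
        for i in range(n):
            row = scaled[i, off[i]]
            shifted[i, off[i]] = row + (1.0 - row.min())
    else:
        shifted[off] = scaled[off] + (1.0 + scale)
    vals = [shifted[i, off[i]] for i in range(n)]
    if aggregate == "sum":
        scores = np.array([v.sum() for v in vals])
    else:
        scores = np.array([v.mean() for v in vals])
    return HierarchyResult(dai=dai, scaled=scaled, shifted=shifted,
                           scores=scores, areas=list(areas) if areas else None)


def connection_matrix(e_loadings: np.ndarray, connections, areas) -> np.ndarray:
    """Arrange a connection-loading vector into the area × area matrix ``e``.

    ``connections`` lists ordered (source_area, target_area) pairs matching
    ``e_loadings``; the output has ``e[i, j]`` = loading of j → i.
    """
    n = len(areas)
    E = np.zeros((n, n))
    index = {a: i for i, a in enumerate(areas)}
    for (src, tgt), v in zip(connections, np.asarray(e_loadings, dtype=float)):
        E[index[tgt], index[src]] = v
    return E
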