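"""Latent-dimension selection by linearly-independent column sampling.

A single pass over the adjacency columns in seeded random order keeps a
column whenever its residual, after projection onto the span of the
columns kept so far (maintained as an orthonormal Gram-Schmidt basis),
exceeds ``tolerance`` times the column norm. The number of kept columns
is the selected latent dimension K. At tight tolerance this equals the
numerical rank of the training adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import derive_rng
from .net_core import Network

__all__ = ["RankSelection", "select_rank_colibri"]


@dataclass(frozen=True)
class RankSelection:
    k: int
    kept_columns: tuple
    tolerance: float


def select_rank_colibri(
    train: Network,
    tolerance: float = 1e-6,
    seed: int = 0,
    k_max: int | None = None,
) -> RankSelection:
    """Select K by residual-thresholded column sampling on the training
    adjacency. Zero columns are skipped; selection stops early at k_max."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if train.n_edges == 0:
        raise ValueError("cannot select rank on an edgeless training network")
    a = train.adjacency.astype(np.float64)
    n = a.shape[0]
    cap = n if k_max is None else int(k_max)
    if cap < 1:
        raise ValueError("k_max must be >= 1")

    rng = derive_rng(seed, "colibri")
    order = rng.permutation(n)
    basis: list[np.ndarray] = []  # orthonormal
    kept: list[int] = []
    for j in order:
        col = a[:, j]
        norm = np.linalg.norm(col)
        if norm == 0.0:
            continue
        residual = col.copy()
        for q in basis:
            residual -= (q @ col) * q
        if np.linalg.norm(residual) > tolerance * norm:
            basis.append(residual / np.linalg.norm(residual))
            kept.append(int(j))
            if len(kept) >= cap:
                break
    return RankSelection(k=len(kept), kept_columns=tuple(kept), tolerance=tolerance)
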