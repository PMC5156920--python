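"""Train/test edge splitting and edge-perturbation ensembles.

A split hides a random fraction of the observed edges for testing. A
perturbation ensemble then derives R replicate adjacencies from the
training network, each with round(eta * (M - L)) edges removed from
(deletion mode) or added to (addition mode) the training edge set,
drawn fresh and independently per replicate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._rng import derive_rng
from .net_core import Network

__all__ = [
    "Split",
    "PerturbationEnsemble",
    "split_train_test",
    "build_perturbation_ensemble",
    "round_half_away",
    "never_perturbed_probability",
]

Mode = Literal["deletion", "addition"]


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def never_perturbed_probability(eta: float, r: int) -> float:
    """Probability that a given training edge appears in none of r
    independent perturbation sets of ratio eta: (1 - eta)**r."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must be in [0, 1]")
    if r < 1:
        raise ValueError("r must be >= 1")
    return (1.0 - eta) ** r


@dataclass(frozen=True)
class Split:
    """Partition of observed edges into a training network and L held-out
    test edges (internal-index pairs, i < j). All N nodes are retained in
    the training network even if isolated."""

    train: Network
    test_edges: frozenset
    fraction: float

    @property
    def n_test(self) -> int:
        return len(self.test_edges)


def split_train_test(net: Network, test_fraction: float, seed: int) -> Split:
    """Hold out a uniformly random round(test_fraction * M) subset of edges."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    edges = net.edges()
    m = len(edges)
    l = round_half_away(test_fraction * m)
    if l < 1:
        raise ValueError(f"test fraction {test_fraction} holds out no edges (M={m})")
    if l >= m:
        raise ValueError(f"test fraction {test_fraction} would hold out all edges")
    rng = derive_rng(seed, "split")
    picked = rng.choice(m, size=l, replace=False)
    test = frozenset(edges[i] for i in picked)
    a = net.adjacency.copy()
    for i, j in test:
        a[i, j] = a[j, i] = 0
    return Split(train=net.with_adjacency(a), test_edges=test, fraction=test_fraction)


@dataclass(frozen=True)
class PerturbationEnsemble:
    """R replicate adjacencies derived from one training network."""

    mode: Mode
    eta: float
    r: int
    perturbed: tuple  # of np.ndarray
    delta_sets: tuple  # of frozenset of (i, j) pairs

    def __iter__(self):
        return iter(self.perturbed)


def _non_edges(train: Network) -> list[tuple[int, int]]:
    ii, jj = np.nonzero(np.triu(train.adjacency == 0, k=1))
    return list(zip(ii.tolist(), jj.tolist()))


def build_perturbation_ensemble(
    split: Split, mode: Mode, eta: float, r: int, seed: int
) -> PerturbationEnsemble:
    """Draw R independent perturbation sets and apply them to the training
    adjacency. Each replicate uses its own RNG stream derived from
    (seed, replicate index), so the ensemble is order-insensitive."""
    if mode not in ("deletion", "addition"):
        raise ValueError(f"unknown mode {mode!r}")
    if eta < 0:
        raise ValueError("eta must be >= 0")
    if r < 1:
        raise ValueError("r must be >= 1")
    train = split.train
    m_train = train.n_edges
    n_delta = round_half_away(eta * m_train)
    pool = train.edges() if mode == "deletion" else _non_edges(train)
    if n_delta > len(pool):
        raise ValueError(
            f"perturbation size {n_delta} exceeds available pool of {len(pool)} pairs"
        )
    if n_delta == 0:
        warnings.warn(
            "perturbation set is empty; replicates equal the training network",
            stacklevel=2,
        )

    sign = -1 if mode == "deletion" else 1
    perturbed = []
    delta_sets = []
    for rep in range(r):
        rng = derive_rng(seed, "perturb", rep)
        picked = rng.choice(len(pool), size=n_delta, replace=False) if n_delta else []
        delta = frozenset(pool[i] for i in picked)
        a = train.adjacency.astype(np.int8).copy()
        for i, j in delta:
            a[i, j] += sign
            a[j, i] += sign
        perturbed.append(a.astype(np.uint8))
        delta_sets.append(delta)
    return PerturbationEnsemble(
        mode=mode, eta=eta, r=r, perturbed=tuple(perturbed), delta_sets=tuple(delta_sets)
    )
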