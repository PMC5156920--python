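"""Precision evaluation harness.

Precision at L (L = test-set size throughout), the analytic random-
predictor baseline, relative precision, a repeated-split experiment
runner, mean precision-ranking across networks, and Pearson correlations
between method precisions and network statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import derive_rng, derive_seed_sequence
from .baselines import GLOBAL_INDICES, LOCAL_INDICES, BaselineParams, baseline_similarity
from .net_core import Network
from .predictor import (
    NMF_VARIANTS,
    MethodSpec,
    SimilarityMatrix,
    perturbed_nmf_similarity,
    rank_candidates,
)
from .sampling import Split, split_train_test

__all__ = [
    "EvaluationResult",
    "precision",
    "random_predictor_precision",
    "monte_carlo_random_precision",
    "relative_precision",
    "get_scorer",
    "available_methods",
    "run_experiment",
    "mean_precision_ranking",
    "stat_correlations",
]


def precision(ranked_pairs: list, test_edges, l: int) -> float:
    """Fraction of the top-l ranked pairs that are test edges."""
    if l < 1:
        raise ValueError("l must be >= 1")
    if l > len(ranked_pairs):
        raise ValueError(f"l={l} exceeds ranking length {len(ranked_pairs)}")
    test = {tuple(sorted(e)) for e in test_edges}
    hits = sum(1 for pair in ranked_pairs[:l] if tuple(sorted(pair)) in test)
    return hits / l


def random_predictor_precision(n: int, m: int, l: int) -> float:
    """Expected precision of a uniformly random ranking: the top-l of the
    n(n-1)/2 - (m-l) candidate pairs contains on average l * l/candidates
    test edges, so the expectation is l / candidates."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 1 <= l <= m:
        raise ValueError("need 1 <= l <= m")
    candidates = n * (n - 1) // 2 - (m - l)
    if candidates <= 0:
        raise ValueError("no candidate pairs for these sizes")
    return l / candidates


def monte_carlo_random_precision(
    n: int, m: int, l: int, reps: int = 10_000, seed: int = 0
) -> float:
    """Empirical estimate of the same expectation: the hit count of a
    random ranking is hypergeometric (l successes among the candidates)."""
    candidates = n * (n - 1) // 2 - (m - l)
    if candidates <= 0 or not 1 <= l <= m:
        raise ValueError("invalid sizes")
    rng = derive_rng(seed, "mc-random")
    hits = rng.hypergeometric(l, candidates - l, l, size=reps)
    return float(hits.mean() / l)


def relative_precision(p: float, p_random: float) -> float:
    """Precision divided by the random-predictor expectation."""
    if p_random <= 0:
        raise ValueError("p_random must be positive")
    return p / p_random


@dataclass(frozen=True)
class EvaluationResult:
    per_run_precision: dict
    mean_precision: dict
    relative_precision: dict
    random_precision: float
    config: dict


def available_methods() -> tuple:
    return LOCAL_INDICES + GLOBAL_INDICES + NMF_VARIANTS


def get_scorer(
    name: str,
    baseline_params: BaselineParams | None = None,
    **nmf_overrides,
):
    """Resolve a method name to a callable (split, seed) -> SimilarityMatrix."""
    if name in NMF_VARIANTS:
        spec = MethodSpec(variant=name, **nmf_overrides)

        def scorer(split: Split, seed: int) -> SimilarityMatrix:
            return perturbed_nmf_similarity(split, spec, seed)

    elif name in LOCAL_INDICES + GLOBAL_INDICES:

        def scorer(split: Split, seed: int) -> SimilarityMatrix:
            return baseline_similarity(split.train, name, baseline_params, seed)

    else:
        raise ValueError(f"unknown method {name!r}; known: {available_methods()}")
    return scorer


def _method_seed(seed: int, run: int, name: str) -> int:
    return int(derive_seed_sequence(seed, "run", run, name).generate_state(1)[0])


def run_experiment(
    net: Network,
    methods,
    test_fraction: float = 0.1,
    runs: int = 100,
    seed: int = 0,
    baseline_params: BaselineParams | None = None,
    tie_break: str = "random",
    **nmf_overrides,
) -> EvaluationResult:
    """Repeated-split evaluation.

    ``methods`` is a list of method names and/or a mapping name -> scorer
    callable. Every method scores the same split in each run; precision is
    evaluated at L = test-set size. A method failure on a run is recorded
    as a warning and that run is excluded for that method only.
    ``tie_break`` is forwarded to the ranking step.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if isinstance(methods, dict):
        scorers = dict(methods)
    else:
        scorers = {name: get_scorer(name, baseline_params, **nmf_overrides) for name in methods}

    per_run: dict = {name: [] for name in scorers}
    l = None
    for run in range(runs):
        split = split_train_test(net, test_fraction, seed=_method_seed(seed, run, "@split"))
        l = split.n_test
        for name, scorer in scorers.items():
            mseed = _method_seed(seed, run, name)
            try:
                sim = scorer(split, mseed)
                ranked = rank_candidates(sim, split.train, mseed, tie_break=tie_break)
                per_run[name].append(precision(ranked, split.test_edges, l))
            except Exception as exc:  # noqa: BLE001 — isolate per-method failures
                warnings.warn(f"method {name} failed on run {run}: {exc}", stacklevel=2)

    p_rand = random_predictor_precision(net.n_nodes, net.n_edges, l)
    means = {
        name: float(np.mean(vals)) if vals else float("nan")
        for name, vals in per_run.items()
    }
    rel = {
        name: relative_precision(m, p_rand) if np.isfinite(m) else float("nan")
        for name, m in means.items()
    }
    return EvaluationResult(
        per_run_precision={k: tuple(v) for k, v in per_run.items()},
        mean_precision=means,
        relative_precision=rel,
        random_precision=p_rand,
        config={
            "test_fraction": test_fraction,
            "runs": runs,
            "seed": seed,
            "methods": tuple(scorers),
        },
    )


def mean_precision_ranking(
    precision_table: pd.DataFrame, tie_order: list | None = None
) -> pd.DataFrame:
    """Rank methods within each network by decreasing precision.

    ``precision_table`` has methods as index and networks as columns.
    Rank 1 is best; ties are broken by ``tie_order`` (default: the table's
    index order). Returns per-network ranks plus a "mean" column.
    """
    if precision_table.isna().any().any():
        raise ValueError("precision table has missing cells")
    methods = list(precision_table.index)
    order = tie_order if tie_order is not None else methods
    tie_pos = {m: order.index(m) for m in methods}

    ranks = pd.DataFrame(index=precision_table.index, columns=precision_table.columns, dtype=float)
    for col in precision_table.columns:
        vals = precision_table[col]
        sorted_methods = sorted(methods, key=lambda m: (-vals[m], tie_pos[m]))
        for rank, m in enumerate(sorted_methods, start=1):
            ranks.loc[m, col] = rank
    ranks["mean"] = ranks.mean(axis=1)
    return ranks


def stat_correlations(
    precision_table: pd.DataFrame, stats_table: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each method's per-network precisions against
    each network statistic. Rows of ``stats_table`` are networks (aligned
    to ``precision_table`` columns by name); zero-variance pairs give NaN.
    """
    networks = [n for n in precision_table.columns if n in stats_table.index]
    if len(networks) < 3:
        raise ValueError("need at least 3 aligned networks")
    out = pd.DataFrame(index=precision_table.index, columns=stats_table.columns, dtype=float)
    for method in precision_table.index:
        x = precision_table.loc[method, networks].to_numpy(dtype=float)
        for stat in stats_table.columns:
            y = stats_table.loc[networks, stat].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                out.loc[method, stat] = np.nan
            else:
                out.loc[method, stat] = float(np.corrcoef(x, y)[0, 1])
    return out
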