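"""Published reference tables bundled as fixtures.

``benchmark_precision_table`` holds the published mean precisions of 23
link-prediction methods on 15 benchmark networks (90/10 splits, averaged
over 100 runs); ``benchmark_network_stats`` holds the corresponding
network statistics. Both are keyed by network name because the two source
tables list the networks in different orders. They feed the ranking and
correlation operations and serve as regression anchors in the tests.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

__all__ = ["benchmark_precision_table", "benchmark_network_stats"]


def _load(name: str, index_col: str) -> pd.DataFrame:
    text = resources.files("nmflink.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), sep="\t", index_col=index_col)


def benchmark_precision_table() -> pd.DataFrame:
    """23 methods x 15 networks of published mean precisions, in the
    published listing order (which is also the ranking tie-break order)."""
    return _load("benchmark_precision.tsv", "method")


def benchmark_network_stats() -> pd.DataFrame:
    """15 networks x 9 statistics (NN, NE, LD, AD, APL, C, CC, P, LCP-corr)."""
    return _load("benchmark_stats.tsv", "network")
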