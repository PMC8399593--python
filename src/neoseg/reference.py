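"""Loader for the shipped reference per-image metrics table.

The table holds published per-image test-set metrics from a fundus
neovascularization segmentation study (50 test patches; "-" where a
metric's denominator was zero).  It anchors two regression suites: the
algebraic identities linking Dice, Jaccard, precision and sensitivity,
and the reconstruction of the printed average row by defined-only
arithmetic means.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metrics import UNDEFINED, MetricsRecord, METRIC_NAMES

__all__ = ["load_reference_metrics", "reference_records"]


def load_reference_metrics() -> pd.DataFrame:
    """Reference table as a DataFrame; undefined entries are NaN."""
    path = resources.files("neoseg.data") / "reference_segmentation_metrics.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", na_values=["-"])
    return df.set_index("image")


def reference_records() -> list[MetricsRecord]:
    """The table as MetricsRecord objects (NaN = undefined)."""
    df = load_reference_metrics()
    return [
        MetricsRecord(**{name: float(row[name]) for name in METRIC_NAMES})
        for _, row in df.iterrows()
    ]
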