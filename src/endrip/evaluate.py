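"""Scoring recovered calls against the planted truth of a synthetic study."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval
from .interval_ops import any_overlap_flags

__all__ = ["dedsb_recovery", "sedsb_contamination", "rloop_recovery", "rnaseh_metrics"]


def _truth_intervals(truth: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in truth.itertuples(index=False)
    ]


def dedsb_recovery(
    truth_dedsb: pd.DataFrame, classes: dict[str, list[GenomicInterval]]
) -> dict:
    """Sensitivity and kinetic-class accuracy of recovered DSB clusters.

    A planted break is recovered when any called cluster overlaps its planted
    span; its class is correct when a cluster of the planted class does.
    """
    spans = _truth_intervals(truth_dedsb)
    all_calls = [iv for cls in ("persistent", "transient", "late") for iv in classes[cls]]
    recovered = any_overlap_flags(spans, all_calls) if all_calls else np.zeros(len(spans), bool)
    correct = np.zeros(len(spans), dtype=bool)
    for cls in ("persistent", "transient", "late"):
        if not classes[cls]:
            continue
        hit = any_overlap_flags(spans, classes[cls])
        correct |= hit & (truth_dedsb["class_label"].to_numpy() == cls)
    n = len(spans)
    return {
        "n_planted": n,
        "sensitivity": float(recovered.mean()) if n else float("nan"),
        "class_accuracy": float(correct[recovered].mean()) if recovered.any() else float("nan"),
    }


def sedsb_contamination(
    truth_sedsb: pd.DataFrame, universe: Sequence[GenomicInterval]
) -> int:
    """Number of called DSB cluster regions that overlap a planted solitary
    (single-ended) break: must be zero for a correct pairing stage."""
    if len(truth_sedsb) == 0 or not universe:
        return 0
    spans = _truth_intervals(truth_sedsb)
    return int(any_overlap_flags(list(universe), spans).sum())


def rloop_recovery(
    truth_rloop: pd.DataFrame,
    kept: Sequence[GenomicInterval],
    categories: Sequence[str],
) -> dict:
    """Fraction of planted hybrid peaks assigned their planted category."""
    spans = _truth_intervals(truth_rloop)
    by_cat: dict[str, list[GenomicInterval]] = {}
    for iv, cat in zip(kept, categories):
        by_cat.setdefault(str(cat), []).append(iv)
    matched = np.zeros(len(spans), dtype=bool)
    correct = np.zeros(len(spans), dtype=bool)
    for cat, ivs in by_cat.items():
        hit = any_overlap_flags(spans, ivs)
        matched |= hit
        correct |= hit & (truth_rloop["class_label"].to_numpy() == cat)
    n = len(spans)
    return {
        "n_planted": n,
        "recovered": float(matched.mean()) if n else float("nan"),
        "category_accuracy": float(correct.mean()) if n else float("nan"),
    }


def rnaseh_metrics(
    truth: pd.DataFrame,
    universe: Sequence[GenomicInterval],
    passed: np.ndarray,
) -> dict:
    """Decoy removal and true-peak retention rates of the RNase H filter."""
    true_spans = _truth_intervals(truth[truth["kind"] == "rloop"])
    decoy_spans = _truth_intervals(truth[truth["kind"] == "decoy"])
    passed_ivs = [iv for iv, ok in zip(universe, passed) if ok]
    retained_true = any_overlap_flags(true_spans, passed_ivs) if passed_ivs else np.zeros(len(true_spans), bool)
    passed_decoys = any_overlap_flags(decoy_spans, passed_ivs) if passed_ivs else np.zeros(len(decoy_spans), bool)
    return {
        "n_true": len(true_spans),
        "n_decoys": len(decoy_spans),
        "true_retention": float(retained_true.mean()) if len(true_spans) else float("nan"),
        "decoy_removal": float(1.0 - passed_decoys.mean()) if len(decoy_spans) else float("nan"),
    }
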