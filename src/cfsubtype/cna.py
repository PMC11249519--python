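"""Thresholding of externally supplied copy-number output.

Consumes per-bin purity-adjusted log2 copy-number ratios and tumor
fractions (ichorCNA-style output) — the copy-number inference itself is an
external input, not reimplemented here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ValidationError

GAIN_THRESHOLD = 0.3
LOSS_THRESHOLD = -0.3
DETECTABLE_LIMIT = 0.03
CHR9P21_GENES = ("CDKN2A", "CDKN2B", "MTAP")


def call_cna(
    bins: pd.DataFrame,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
) -> pd.Series:
    """Per-bin call: gain (> gain_threshold), loss (< loss_threshold),
    else neutral.  Both inequalities are strict."""
    if gain_threshold <= loss_threshold:
        raise ValidationError("gain threshold must exceed loss threshold")
    ratio = bins["log2_ratio"].to_numpy(float)
    if not np.isfinite(ratio).all():
        raise ValidationError("non-finite log2 ratio")
    calls = np.where(
        ratio > gain_threshold, "gain", np.where(ratio < loss_threshold, "loss", "neutral")
    )
    return pd.Series(calls, index=bins.index, name="call")


def detect_9p21_loss(calls: pd.Series, gene_bins: dict[str, int]) -> bool:
    """9p21.3 loss: loss of CDKN2A/B and/or MTAP (any mapped bin lost)."""
    missing = [g for g in CHR9P21_GENES if g not in gene_bins]
    if missing:
        raise ValidationError(f"genes without bin mapping: {missing}")
    return any(calls.loc[gene_bins[g]] == "loss" for g in CHR9P21_GENES)


def stratify_accuracy(
    predictions: pd.Series,
    truth: pd.Series,
    fractions: pd.Series,
    limit: float = DETECTABLE_LIMIT,
) -> dict[str, float | None]:
    """Classification accuracy split by tumor-fraction detectability.

    Samples with fraction >= ``limit`` are detectable (inclusive).  Empty
    groups report None rather than zero.
    """
    ids = predictions.index
    if not (ids.equals(truth.index) and ids.equals(fractions.index)):
        if set(ids) != set(truth.index) or set(ids) != set(fractions.index):
            raise ValidationError("sample ids of predictions/truth/fractions differ")
        truth = truth.loc[ids]
        fractions = fractions.loc[ids]
    frac = fractions.to_numpy(float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValidationError("tumor fractions outside [0, 1]")
    correct = (predictions.to_numpy() == truth.to_numpy())
    detectable = frac >= limit
    out: dict[str, float | None] = {}
    for name, mask in (("detectable", detectable), ("undetectable", ~detectable)):
        out[name] = float(correct[mask].mean()) if mask.any() else None
        out[f"n_{name}"] = int(mask.sum())
    return out
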