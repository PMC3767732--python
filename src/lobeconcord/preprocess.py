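"""Median normalization and present-call filtering.

The normalization is the classic two-step median scaling used for
MAS5-summarized arrays: every chip (sample column) is divided by its own
median, then every gene (probe row) is divided by its median across
samples.  Downstream correlation structure is computed on log2 of these
doubly-normalized values.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np

from .io_formats import DetectionMatrix, ExpressionMatrix, ProbeList, SampleAnnotation

__all__ = [
    "normalize_per_chip",
    "normalize_per_gene",
    "log2_transform",
    "present_filter",
    "fallback_detection",
]

log = logging.getLogger(__name__)


def normalize_per_chip(x: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample column by its median intensity.

    Requires linear scale and a strictly positive median per sample; the
    result has every column median equal to 1 and the operation is
    idempotent.
    """
    if x.scale != "linear":
        raise ValueError("per-chip normalization operates on linear-scale intensities")
    med = x.data.median(axis=0)
    bad = med[med <= 0]
    if len(bad):
        raise ValueError(f"non-positive median for sample(s): {list(bad.index)[:5]}")
    return ExpressionMatrix(x.data.div(med, axis=1), scale="linear")


def normalize_per_gene(x: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each probe row by its median across samples.

    Rows with zero median cannot be scaled; they are excluded from the
    returned matrix and reported through the ``lobeconcord.preprocess``
    logger rather than silently divided.
    """
    if x.scale != "linear":
        raise ValueError("per-gene normalization operates on linear-scale intensities")
    med = x.data.median(axis=1)
    zero = med[med <= 0].index
    if len(zero):
        log.warning(
            "normalize_per_gene: %d probe(s) with zero median excluded (e.g. %s)",
            len(zero), list(zero[:3]),
        )
    keep = med[med > 0].index
    return ExpressionMatrix(x.data.loc[keep].div(med[keep], axis=0), scale="linear")


def log2_transform(x: ExpressionMatrix, floor: float = 0.01) -> ExpressionMatrix:
    """log2 with a positive floor: values below ``floor`` are clamped so
    zeros from background-level probes stay finite."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    if x.scale != "linear":
        raise ValueError("matrix is already on log2 scale")
    return ExpressionMatrix(np.log2(x.data.clip(lower=floor)), scale="log2")


def fallback_detection(x: ExpressionMatrix, percentile: float = 10.0) -> DetectionMatrix:
    """Threshold-based stand-in for platform detection calls: a value is
    'present' when it exceeds its sample's given percentile (default 10th).
    Used only when no detection-call matrix accompanies the data."""
    thr = np.percentile(x.values, percentile, axis=0)
    return DetectionMatrix((x.data > thr).astype(bool))


def present_filter(
    x: ExpressionMatrix,
    det: DetectionMatrix | None,
    groups: Mapping[str, Sequence[str]],
    min_fraction: float = 0.2,
    fallback_percentile: float = 10.0,
) -> ProbeList:
    """Retain probes called present in at least ``min_fraction`` of the
    samples of AT LEAST ONE group (OR semantics across groups).

    The fraction comparison is non-strict (``>=``); equivalently a probe
    needs ``ceil(min_fraction * group_size)`` present calls in some group.
    ``groups`` maps a label (e.g. ``upper``/``lower`` or
    ``smoker``/``nonsmoker``) to its sample ids.
    """
    if not groups:
        raise ValueError("at least one group required")
    for label, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"group {label!r} is empty")
    if det is None:
        det = fallback_detection(x, fallback_percentile)
    if not det.matches(x):
        raise ValueError("detection matrix axes do not match expression matrix")
    keep = np.zeros(len(x.probe_ids), dtype=bool)
    for label, members in groups.items():
        members = list(members)
        need = math.ceil(min_fraction * len(members))
        counts = det.data[members].sum(axis=1).to_numpy()
        keep |= counts >= need
    ids = [p for p, k in zip(x.probe_ids, keep) if k]
    return ProbeList("present", ids)
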