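"""PCA of signature-space samples and the paired vector-length statistic.

The vector length is the Euclidean distance between a subject's upper and
lower sample in the space of a probe list; its median across subjects
summarizes within-subject concordance and is referred to the medians
obtained on random probe lists of the same size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import random_probe_lists
from .io_formats import ExpressionMatrix, ProbeList, SampleAnnotation

__all__ = [
    "VectorLengthNull",
    "pca_scores",
    "paired_vector_lengths",
    "vector_length_null",
]

log = logging.getLogger(__name__)

NULL_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


@dataclass
class VectorLengthNull:
    """Observed per-subject paired vector lengths against B null medians."""

    lengths: pd.Series
    observed_median: float
    null_medians: np.ndarray
    null_quantiles: dict[float, float]
    empirical_p: float

    @property
    def B(self) -> int:
        return len(self.null_medians)

    def to_dict(self) -> dict:
        return {
            "lengths": {str(k): float(v) for k, v in self.lengths.items()},
            "observed_median": float(self.observed_median),
            "null_medians": [float(v) for v in self.null_medians],
            "null_quantiles": {str(q): float(v) for q, v in self.null_quantiles.items()},
            "empirical_p": float(self.empirical_p),
            "B": int(self.B),
        }


def pca_scores(
    x: ExpressionMatrix, probes: ProbeList | None = None, k: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of the samples over a probe list.

    Probes are mean-centered across samples; no variance scaling.  Scores
    come from the SVD of the centered samples-by-probes matrix.  Sign
    convention: within each component the loading of largest magnitude is
    positive.  Returns (scores DataFrame indexed by sample, explained
    variance fractions of the k components).
    """
    sub = x.subset(probes) if probes is not None else x
    X = sub.values.T  # samples x probes
    n = X.shape[0]
    max_k = min(n - 1, X.shape[1])
    if k > max_k:
        raise ValueError(f"k={k} exceeds the rank bound {max_k}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for c in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U[:, :k] * S[:k]
    total = float(np.sum(S**2))
    evr = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    frame = pd.DataFrame(
        scores,
        index=pd.Index(sub.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return frame, evr


def paired_vector_lengths(
    x: ExpressionMatrix, ann: SampleAnnotation, probes: ProbeList | None = None
) -> pd.Series:
    """Per-subject Euclidean norm of (upper - lower) over the probe list.

    Subjects lacking a sample at either site are skipped with a warning.
    """
    sub = x.subset(probes) if probes is not None else x
    have = set(sub.sample_ids)
    out = {}
    for subj, (u, l) in ann.paired_subjects().items():
        if u not in have or l not in have:
            log.warning("paired_vector_lengths: subject %s missing a site", subj)
            continue
        diff = sub.data[u].to_numpy() - sub.data[l].to_numpy()
        out[subj] = float(np.linalg.norm(diff))
    return pd.Series(out, name="vector_length")


def vector_length_null(
    x: ExpressionMatrix,
    ann: SampleAnnotation,
    signature: ProbeList,
    universe: ProbeList,
    B: int = 100,
    seed: int | np.random.Generator = 0,
) -> VectorLengthNull:
    """Median paired vector length on the signature list versus B random
    lists of the same size from ``universe`` minus ``signature``.

    Reports the null medians' 0.05/0.25/0.5/0.75/0.95 quantiles and the
    one-sided add-one proportion (1 + #{null <= observed}) / (B + 1):
    small values mean the signature pairs sit unusually close together.
    """
    lengths = paired_vector_lengths(x, ann, signature)
    if lengths.empty:
        raise ValueError("no complete pairs available")
    observed = float(np.median(lengths.to_numpy()))
    null_medians = np.array(
        [
            float(np.median(paired_vector_lengths(x, ann, pl).to_numpy()))
            for pl in random_probe_lists(universe, signature, len(signature), B, seed)
        ]
    )
    quantiles = {
        q: float(np.quantile(null_medians, q)) for q in NULL_QUANTILES
    }
    p = (1 + int(np.sum(null_medians <= observed))) / (B + 1)
    return VectorLengthNull(
        lengths=lengths,
        observed_median=observed,
        null_medians=null_medians,
        null_quantiles=quantiles,
        empirical_p=p,
    )
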