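"""Dendrogram sibling-pairing concordance with a random gene-list null.

The question: when the samples of a paired cohort (one upper- and one
lower-airway sample per subject) are hierarchically clustered on the
expression of a probe list, how many subjects' two samples merge directly
with each other ("sibling pairing")?  The observed count on a signature
list is referred to an empirical null built by recomputing the count on
``B`` random probe lists of the same size drawn from the present-call
universe with the signature excluded.

Clustering is agglomerative with correlation distance ``1 - r`` (Pearson
or Spearman) and average or complete linkage.  The agglomeration is a
direct O(n^3) implementation with a deterministic lowest-index-first
tie-break so runs are bit-reproducible; at cohort sizes (tens of
samples) this costs nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix, ProbeList, SampleAnnotation

__all__ = [
    "Dendrogram",
    "PairingNullResult",
    "correlation_distance",
    "hierarchical_cluster",
    "pairing_count",
    "random_probe_lists",
    "empirical_p_addone",
    "pairing_permutation_test",
]


def empirical_p_addone(null_values: np.ndarray, observed: float) -> float:
    """Add-one empirical p-value (1 + #{null >= observed}) / (B + 1);
    never zero, so B exceedance-free null draws report 1/(B+1)."""
    null_values = np.asarray(null_values)
    return (1 + int(np.sum(null_values >= observed))) / (len(null_values) + 1)

log = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Binary merge tree over samples in scipy linkage-matrix layout.

    ``merges`` has one row per merge ``[left, right, height, size]``;
    leaves are ids ``0..n-1`` (indexing ``leaf_labels``), internal nodes
    ``n + i`` for merge ``i``.  Heights are non-decreasing for the
    linkages used here.
    """

    merges: np.ndarray
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def sibling_leaf_pairs(self) -> set[frozenset[str]]:
        """Unordered label pairs of leaves whose first merge is with each
        other."""
        n = self.n_leaves
        out = set()
        for left, right, _, _ in self.merges:
            left, right = int(left), int(right)
            if left < n and right < n:
                out.add(frozenset((self.leaf_labels[left], self.leaf_labels[right])))
        return out

    def to_newick(self) -> str:
        n = self.n_leaves
        reps: dict[int, str] = {i: lab for i, lab in enumerate(self.leaf_labels)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for i, (left, right, h, _) in enumerate(self.merges):
            left, right = int(left), int(right)
            bl = h - heights[left]
            br = h - heights[right]
            reps[n + i] = f"({reps[left]}:{bl:.10g},{reps[right]}:{br:.10g})"
            heights[n + i] = h
        return reps[n + len(self.merges) - 1] + ";"


@dataclass
class PairingNullResult:
    """Observed sibling-pairing count against B random-list null counts."""

    observed_k: int
    n_pairs: int
    null_counts: np.ndarray
    empirical_p: float
    method: str = "pearson"

    @property
    def B(self) -> int:
        return len(self.null_counts)

    def to_dict(self) -> dict:
        return {
            "observed_k": int(self.observed_k),
            "n_pairs": int(self.n_pairs),
            "B": int(self.B),
            "null_counts": [int(c) for c in self.null_counts],
            "empirical_p": float(self.empirical_p),
            "method": self.method,
        }


def correlation_distance(
    x: ExpressionMatrix, probes: ProbeList | None = None, method: str = "pearson"
) -> np.ndarray:
    """Sample-by-sample distance 1 - corr over the listed probes.

    Pearson or Spearman (average ranks for ties).  A sample with zero
    variance over the probe list has no defined correlation and raises.
    """
    sub = x.subset(probes) if probes is not None else x
    mat = sub.values  # probes x samples
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 probes for a correlation distance")
    if method == "spearman":
        mat = np.apply_along_axis(stats.rankdata, 0, mat)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = mat.std(axis=0)
    if np.any(sd == 0):
        bad = [s for s, z in zip(sub.sample_ids, sd == 0) if z]
        raise ValueError(f"zero variance over probe list for sample(s): {bad[:5]}")
    corr = np.corrcoef(mat, rowvar=False)
    d = 1.0 - corr
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def _check_distance(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return d


def hierarchical_cluster(
    d: np.ndarray,
    linkage: str = "average",
    labels: list[str] | None = None,
) -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    At each step the pair of active clusters at minimal distance merges;
    ties resolve to the lexicographically smallest (i, j) index pair.
    ``average`` linkage updates d(new, k) as the size-weighted mean of the
    members' distances (UPGMA); ``complete`` takes the maximum.
    """
    d = _check_distance(d).copy()
    n = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")

    # working distance dict over active node ids
    active: list[int] = list(range(n))
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]

    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        best_pair = None
        for a_idx in range(len(active)):
            for b_idx in range(a_idx + 1, len(active)):
                i, j = active[a_idx], active[b_idx]
                key = (i, j) if i < j else (j, i)
                val = dist[key]
                if best is None or val < best:
                    best = val
                    best_pair = key
        i, j = best_pair
        for k in active:
            if k in (i, j):
                continue
            ki = (min(i, k), max(i, k))
            kj = (min(j, k), max(j, k))
            if linkage == "average":
                new = (sizes[i] * dist[ki] + sizes[j] * dist[kj]) / (sizes[i] + sizes[j])
            else:
                new = max(dist[ki], dist[kj])
            dist[(k, next_id) if k < next_id else (next_id, k)] = new
        active = [k for k in active if k not in (i, j)] + [next_id]
        sizes[next_id] = sizes[i] + sizes[j]
        merges[step] = (i, j, best, sizes[next_id])
        next_id += 1
    return Dendrogram(merges=merges, leaf_labels=list(labels))


def pairing_count(tree: Dendrogram, ann: SampleAnnotation) -> int:
    """Number of paired subjects whose upper and lower samples are
    dendrogram siblings (their first merge is with each other).

    Subjects missing either site among the leaves are excluded from the
    count (and the effective denominator) with a warning.
    """
    leaves = set(tree.leaf_labels)
    siblings = tree.sibling_leaf_pairs()
    count = 0
    for subj, (u, l) in ann.paired_subjects().items():
        if u not in leaves or l not in leaves:
            log.warning("pairing_count: subject %s missing a site among leaves", subj)
            continue
        if frozenset((u, l)) in siblings:
            count += 1
    return count


def random_probe_lists(
    universe: ProbeList,
    exclude: ProbeList | None,
    size: int,
    B: int,
    seed: int | np.random.Generator,
) -> list[ProbeList]:
    """B probe lists sampled uniformly without replacement from
    ``universe`` minus ``exclude``; reproducible under ``seed``."""
    excl = set(exclude.probe_ids) if exclude is not None else set()
    eligible = [p for p in universe.probe_ids if p not in excl]
    if len(eligible) < size:
        raise ValueError(
            f"universe minus excluded has {len(eligible)} probes; need {size}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lists = []
    for b in range(B):
        idx = rng.choice(len(eligible), size=size, replace=False)
        lists.append(ProbeList(f"random_{b}", [eligible[i] for i in sorted(idx)]))
    return lists


def pairing_permutation_test(
    x: ExpressionMatrix,
    ann: SampleAnnotation,
    signature: ProbeList,
    universe: ProbeList,
    B: int = 100,
    method: str = "pearson",
    linkage: str = "average",
    seed: int | np.random.Generator = 0,
) -> PairingNullResult:
    """Empirical test of sibling pairing on a signature list.

    The observed pairing count is recomputed on ``B`` random lists of the
    same size drawn from ``universe`` minus ``signature``; the add-one
    empirical p-value is (1 + #{null >= observed}) / (B + 1), so a count
    exceeded by none of the null lists reports 1/(B+1), never zero.
    """

    def count_for(pl: ProbeList) -> int:
        d = correlation_distance(x, pl, method=method)
        tree = hierarchical_cluster(d, linkage=linkage, labels=x.sample_ids)
        return pairing_count(tree, ann)

    observed = count_for(signature)
    nulls = np.array(
        [count_for(pl) for pl in random_probe_lists(universe, signature, len(signature), B, seed)],
        dtype=int,
    )
    p = empirical_p_addone(nulls, observed)
    return PairingNullResult(
        observed_k=observed,
        n_pairs=len(ann.paired_subjects()),
        null_counts=nulls,
        empirical_p=p,
        method=method,
    )
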