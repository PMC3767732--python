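"""Paired and two-group differential expression with multiple-testing
control, and derivation of a smoking-responsive signature list.

Two test statistics are provided:

* a classical paired t-test on per-subject (upper - lower) log2
  differences, and
* a moderated t in which each probe's sample variance ``s^2`` with ``d``
  residual degrees of freedom is shrunk toward a pooled prior ``s0^2``
  with ``d0`` prior degrees of freedom,

      s^2_post = (d0 * s0^2 + d * s^2) / (d0 + d),

  the statistic referred to ``t`` with ``d0 + d`` degrees of freedom.
  The hyperparameters (d0, s0^2) are estimated across probes by matching
  the first two moments of log s^2 to a scaled chi-square model, the
  closed-form empirical-Bayes estimator standard for small-n microarray
  designs.

Multiple-testing control: Benjamini-Hochberg step-up adjustment and the
q-value, here with the single-lambda pi0 estimator at lambda = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    DetectionMatrix,
    ExpressionMatrix,
    ProbeList,
    SampleAnnotation,
)
from .preprocess import log2_transform, present_filter

__all__ = [
    "DifferentialResult",
    "ModeratedFit",
    "paired_t",
    "moderated_t",
    "bh_adjust",
    "storey_q",
    "symmetric_fold_change",
    "derive_signature",
]


@dataclass
class ModeratedFit:
    """Empirical-Bayes variance model: prior df ``d0`` (possibly inf),
    prior variance ``s0_sq`` and per-probe posterior variances."""

    d0: float
    s0_sq: float
    posterior_var: pd.Series


def _differential_frame(
    probes: Sequence[str],
    effect: np.ndarray,
    t_stat: np.ndarray,
    df: np.ndarray,
    p: np.ndarray,
    degenerate: np.ndarray,
) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "effect": effect,
            "t_stat": t_stat,
            "df": df,
            "p": p,
            "p_bh": bh_adjust(p),
            "q": storey_q(p) if len(p) >= 10 else bh_adjust(p),
            "degenerate": degenerate,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return out


def paired_t(
    x: ExpressionMatrix, ann: SampleAnnotation, probes: ProbeList | None = None
) -> pd.DataFrame:
    """Classical paired t-test per probe on (upper - lower) differences.

    Returns a per-probe table with columns effect (mean paired log2
    difference), t_stat, df, p, p_bh, q and a ``degenerate`` flag for
    zero-variance difference vectors (reported with p = 1).
    """
    if x.scale != "log2":
        raise ValueError("paired t expects log2-scale values")
    pairs = ann.paired_subjects()
    if len(pairs) < 2:
        raise ValueError("need at least 2 complete pairs")
    sub = x.subset(probes) if probes is not None else x
    upper = sub.data[[u for u, _ in pairs.values()]].to_numpy()
    lower = sub.data[[l for _, l in pairs.values()]].to_numpy()
    d = upper - lower
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, mean / (sd / np.sqrt(n)))
    df = np.full(len(mean), n - 1, dtype=float)
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), n - 1))
    return _differential_frame(list(sub.probe_ids), mean, t, df, p, degenerate)


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match log sample variances to a scaled chi-square model,
    returning (d0, s0_sq); d0 = inf when the observed spread of log s^2
    is no larger than the chi-square sampling spread."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 3:
        raise ValueError("need at least 3 probes with positive variance")
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar > 0:
        d0 = 2.0 * float(_trigamma_inverse(evar))
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def _posterior_var(s2: np.ndarray, d: float, d0: float, s0_sq: float) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0_sq)
    return (d0 * s0_sq + d * s2) / (d0 + d)


def moderated_t(
    x: ExpressionMatrix,
    ann: SampleAnnotation,
    probes: ProbeList | None = None,
    design: str = "paired",
    d0_override: float | None = None,
) -> tuple[pd.DataFrame, ModeratedFit]:
    """Moderated t-test with empirical-Bayes variance shrinkage.

    ``design="paired"`` tests per-subject (upper - lower) differences;
    ``design="two_group"`` tests smokers against nonsmokers with a pooled
    variance.  ``d0_override`` forces the prior degrees of freedom
    (0 recovers the classical t, inf fully pools the variance).
    """
    if x.scale != "log2":
        raise ValueError("moderated t expects log2-scale values")
    sub = x.subset(probes) if probes is not None else x
    if len(sub.probe_ids) < 3:
        raise ValueError("need at least 3 probes to estimate the variance prior")

    if design == "paired":
        pairs = ann.paired_subjects()
        if len(pairs) < 2:
            raise ValueError("need at least 2 complete pairs")
        diffs = (
            sub.data[[u for u, _ in pairs.values()]].to_numpy()
            - sub.data[[l for _, l in pairs.values()]].to_numpy()
        )
        n = diffs.shape[1]
        effect = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        d = float(n - 1)
        stderr_unit = 1.0 / np.sqrt(n)
    elif design == "two_group":
        ga = ann.samples_in_group("smoker")
        gb = ann.samples_in_group("nonsmoker")
        if not ga or not gb:
            raise ValueError("both smoker and nonsmoker samples required")
        a = sub.data[ga].to_numpy()
        b = sub.data[gb].to_numpy()
        na, nb = a.shape[1], b.shape[1]
        if na < 2 or nb < 2:
            raise ValueError("each group needs at least 2 samples")
        effect = a.mean(axis=1) - b.mean(axis=1)
        s2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
            na + nb - 2
        )
        d = float(na + nb - 2)
        stderr_unit = np.sqrt(1.0 / na + 1.0 / nb)
    else:
        raise ValueError(f"unknown design {design!r}")

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = fit_variance_prior(s2, d) if d0 != 0 else (None, float(np.median(s2)))
        if np.isinf(d0):
            s0_sq = float(np.exp(np.mean(np.log(s2[s2 > 0]))
                                 - special.digamma(d / 2.0) + np.log(d / 2.0)))
    else:
        d0, s0_sq = fit_variance_prior(s2, d)

    if d0 == 0:
        post = s2.copy()
        df_total = d
    else:
        post = _posterior_var(s2, d, d0, s0_sq)
        df_total = d0 + d

    degenerate = post <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, effect / (np.sqrt(post) * stderr_unit))
    if np.isinf(df_total):
        p = np.where(degenerate, 1.0, 2.0 * stats.norm.sf(np.abs(t)))
    else:
        p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df_total))
    df = np.full(len(effect), df_total, dtype=float)
    frame = _differential_frame(list(sub.probe_ids), effect, t, df, p, degenerate)
    fit = ModeratedFit(
        d0=float(d0),
        s0_sq=float(s0_sq),
        posterior_var=pd.Series(post, index=sub.probe_ids),
    )
    return frame, fit


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_pi0(p: Sequence[float] | np.ndarray, lam: float = 0.5) -> float:
    """Single-lambda estimate of the null proportion:
    pi0_hat = #{p > lambda} / ((1 - lambda) m), clipped to (0, 1]."""
    p = np.asarray(p, dtype=float)
    m = p.size
    pi0 = np.sum(p > lam) / ((1.0 - lam) * m)
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_q(p: Sequence[float] | np.ndarray, lam: float = 0.5) -> np.ndarray:
    """q-values with the single-lambda pi0 estimator:
    q_i = pi0_hat * BH_i (monotone by construction, capped at 1).
    Requires at least 10 p-values for a usable pi0 estimate."""
    p = np.asarray(p, dtype=float)
    if p.size < 10:
        raise ValueError("q-value estimation needs at least 10 p-values")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(storey_pi0(p, lam) * bh_adjust(p), 1.0)


def symmetric_fold_change(
    x: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    probes: ProbeList | None = None,
) -> pd.Series:
    """Direction-agnostic linear fold change: max(mean_a/mean_b,
    mean_b/mean_a), always >= 1.  Probes with a zero group mean get NaN."""
    if x.scale != "linear":
        raise ValueError("fold change is computed on linear-scale values")
    if not len(group_a) or not len(group_b):
        raise ValueError("both groups must be non-empty")
    sub = x.subset(probes) if probes is not None else x
    ma = sub.data[list(group_a)].mean(axis=1)
    mb = sub.data[list(group_b)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.maximum(ma / mb, mb / ma)
    fc[(ma <= 0) | (mb <= 0)] = np.nan
    return pd.Series(fc, index=sub.data.index, name="fold_change")


def derive_signature(
    x: ExpressionMatrix,
    det: DetectionMatrix | None,
    ann: SampleAnnotation,
    fc_min: float = 1.5,
    p_bh_max: float = 0.01,
    min_fraction: float = 0.2,
    method: str = "moderated",
    log_floor: float = 0.01,
    name: str = "signature",
) -> tuple[ProbeList, pd.DataFrame]:
    """Smoker-vs-nonsmoker signature: present-call filter (>=20% of the
    smoker or nonsmoker samples), two-group test on log2 values, then keep
    probes with symmetric fold change >= ``fc_min`` AND BH-adjusted
    p < ``p_bh_max``.

    ``x`` is the normalized linear-scale matrix; fold changes use the
    linear values, the test uses log2(floor-clamped) values.  Smokers with
    two paired samples contribute their per-subject mean so each subject
    counts once against the nonsmoker cohort.

    Returns the signature :class:`ProbeList` and the full per-probe table
    for the present probes.
    """
    if x.scale != "linear":
        raise ValueError("derive_signature expects the normalized linear matrix")
    smokers = ann.samples_in_group("smoker")
    nonsmokers = ann.samples_in_group("nonsmoker")
    if not smokers or not nonsmokers:
        raise ValueError("both smoker and nonsmoker samples required")
    present = present_filter(
        x, det, {"smoker": smokers, "nonsmoker": nonsmokers}, min_fraction=min_fraction
    )
    sub = x.subset(present)

    # collapse paired smokers to per-subject means (linear scale)
    pairs = ann.paired_subjects()
    collapsed = {}
    ann_rows = {}
    used = set()
    for subj, (u, l) in pairs.items():
        if ann.table.loc[u, "group"] == "smoker":
            collapsed[subj] = sub.data[[u, l]].mean(axis=1)
            ann_rows[subj] = ("smoker",)
            used.update((u, l))
    for s in smokers:
        if s not in used:
            collapsed[f"{s}"] = sub.data[s]
            ann_rows[f"{s}"] = ("smoker",)
    for s in nonsmokers:
        collapsed[s] = sub.data[s]
        ann_rows[s] = ("nonsmoker",)
    flat = ExpressionMatrix(pd.DataFrame(collapsed), scale="linear")
    flat_ann = SampleAnnotation(
        pd.DataFrame(
            {
                "subject_id": list(ann_rows.keys()),
                "site": ["lower"] * len(ann_rows),
                "group": [g for (g,) in ann_rows.values()],
            },
            index=pd.Index(list(ann_rows.keys()), name="sample_id"),
        )
    )
    logm = log2_transform(flat, floor=log_floor)
    if method == "moderated":
        table, _ = moderated_t(logm, flat_ann, design="two_group")
    elif method == "classical":
        table, _ = moderated_t(logm, flat_ann, design="two_group", d0_override=0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    fc = symmetric_fold_change(
        flat,
        flat_ann.samples_in_group("smoker"),
        flat_ann.samples_in_group("nonsmoker"),
    )
    table = table.assign(fold_change=fc)
    keep = (table["fold_change"] >= fc_min) & (table["p_bh"] < p_bh_max)
    ids = list(table.index[keep.fillna(False)])
    return ProbeList(name, ids), table
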