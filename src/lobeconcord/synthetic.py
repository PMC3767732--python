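"""Synthetic paired airway-epithelium cohorts.

The generator emulates the structure of a paired bronchoscopy study:
``n_subjects`` active smokers each contribute an upper- and a lower-lobe
sample, plus an independent cohort of nonsmokers with one sample each,
on a common probe universe of ``m_total`` probes of which ``m_sig`` are
smoking-responsive.

Per-probe log2 signal for sample s of subject i at site l:

    x[g, s] = mu[g]                          baseline abundance
            + resp[g] * (r[i]*beta[g] + h[i,g])   smoking response (smokers)
            + a[i, g]                        background subject effect
            + c[l, g]                        systematic site (lobe) effect
            + eps[g, s]                      residual noise

* ``beta[g]`` is the canonical response of a responsive probe,
  sign * Uniform(0.7, 2.0) log2.  The realized group-level effect is the
  canonical response scaled by the mean subject response (~0.9), so the
  weakest planted probe still has an expected fold change of about
  2**(0.9 * 0.7) ~ 1.55, clearing a fold-change >= 1.5 screen.
* ``r[i] ~ Uniform(0.3, 1.5)`` scales each smoker's overall response:
  some smokers respond weakly, others strongly.
* ``h[i, g] ~ N(0, sigma_resp_het)`` is the subject-specific response
  pattern, shared between a subject's two sites: smokers differ not only
  in how much but in exactly which responsive genes move and by how much.
  This shared component is what makes a subject's two samples cluster
  together on the responsive list.
* ``a[i, g] ~ N(0, sigma_subj_bg)`` is a weak genome-wide subject effect,
  giving random probe lists a small (but far from perfect) tendency to
  pair a subject's samples.
* ``c[l, g] ~ N(0, sigma_site)`` is a small systematic upper-vs-lower
  effect shared by all subjects.

The matrix is returned on the linear scale (2**x) with Bernoulli
detection calls plus a guaranteed-absent probe block so present-call
filtering always has something to remove.  Nonsmokers have r = 0 and
h = 0 and are labelled site "lower" (they are unpaired, so the label is
inert).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import DetectionMatrix, ExpressionMatrix, ProbeList, SampleAnnotation

__all__ = ["SyntheticConfig", "generate_cohort", "generate_null_cohort"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the paired-cohort generator (log2 scale unless noted)."""

    n_subjects: int = 11
    n_nonsmokers: int = 60
    m_total: int = 5000
    m_sig: int = 529
    mu_mean: float = 6.0
    mu_sd: float = 1.5
    beta_min: float = 0.7
    beta_max: float = 2.0
    r_min: float = 0.3
    r_max: float = 1.5
    sigma_site: float = 0.05
    sigma_subj_bg: float = 0.07
    sigma_resp_het: float = 0.5
    sigma_e: float = 0.25
    present_prob: float = 0.85
    n_absent: int = 50
    site_effect_on_signature: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_nonsmokers < 0:
            raise ValueError("cohort sizes must be positive")
        if not (0 < self.m_sig <= self.m_total - self.n_absent):
            raise ValueError("m_sig must fit inside the non-absent probe universe")
        for name in ("sigma_site", "sigma_subj_bg", "sigma_resp_het", "sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.present_prob <= 1):
            raise ValueError("present_prob must be a probability")
        if self.beta_min <= 0 or self.beta_max < self.beta_min:
            raise ValueError("need 0 < beta_min <= beta_max")
        if self.r_min < 0 or self.r_max < self.r_min:
            raise ValueError("need 0 <= r_min <= r_max")


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, DetectionMatrix, SampleAnnotation, ProbeList]:
    """Generate (expression, detection calls, annotation, planted
    signature) for a paired smoker cohort plus nonsmokers.

    Bit-reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    m, n = cfg.m_total, cfg.n_subjects
    width = len(str(m))
    probe_ids = [f"P{i:0{width}d}" for i in range(m)]

    mu = rng.normal(cfg.mu_mean, cfg.mu_sd, m)
    eligible = m - cfg.n_absent  # absent block occupies the tail
    sig_idx = np.sort(rng.choice(eligible, cfg.m_sig, replace=False))
    responsive = np.zeros(m, dtype=bool)
    responsive[sig_idx] = True
    beta = np.zeros(m)
    beta[sig_idx] = rng.uniform(cfg.beta_min, cfg.beta_max, cfg.m_sig) * rng.choice(
        [-1.0, 1.0], cfg.m_sig
    )
    r = rng.uniform(cfg.r_min, cfg.r_max, n)

    site_mask = np.ones(m, dtype=bool)
    if not cfg.site_effect_on_signature:
        site_mask = ~responsive
    c = rng.normal(0.0, cfg.sigma_site, (m, 2)) * site_mask[:, None]

    cols: dict[str, np.ndarray] = {}
    ann_rows = []
    for i in range(n):
        subj = f"S{i + 1:02d}"
        a = rng.normal(0.0, cfg.sigma_subj_bg, m)
        h = np.zeros(m)
        if cfg.sigma_resp_het > 0:
            h[sig_idx] = rng.normal(0.0, cfg.sigma_resp_het, cfg.m_sig)
        for li, site in enumerate(("upper", "lower")):
            eps = rng.normal(0.0, cfg.sigma_e, m)
            sample = f"{subj}_{site}"
            cols[sample] = mu + responsive * (r[i] * beta + h) + a + c[:, li] + eps
            ann_rows.append((sample, subj, site, "smoker"))
    for j in range(cfg.n_nonsmokers):
        subj = f"N{j + 1:02d}"
        a = rng.normal(0.0, cfg.sigma_subj_bg, m)
        eps = rng.normal(0.0, cfg.sigma_e, m)
        sample = f"{subj}_lower"
        cols[sample] = mu + a + c[:, 1] + eps
        ann_rows.append((sample, subj, "lower", "nonsmoker"))

    log2_mat = pd.DataFrame(cols, index=probe_ids)
    expr = ExpressionMatrix(np.exp2(log2_mat), scale="linear")

    present = rng.random(log2_mat.shape) < cfg.present_prob
    present[eligible:, :] = False  # guaranteed-absent block
    det = DetectionMatrix(
        pd.DataFrame(present, index=probe_ids, columns=log2_mat.columns)
    )
    ann = SampleAnnotation(
        pd.DataFrame(
            [(s, t, g) for _, s, t, g in ann_rows],
            columns=["subject_id", "site", "group"],
            index=pd.Index([r0 for r0, *_ in ann_rows], name="sample_id"),
        )
    )
    planted = ProbeList("planted_signature", [probe_ids[i] for i in sig_idx])
    return expr, det, ann, planted


def generate_null_cohort(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, DetectionMatrix, SampleAnnotation, ProbeList]:
    """Cohort with no subject-level structure: response magnitudes,
    response heterogeneity and the background subject effect are all
    zeroed, so nothing beyond chance links a subject's two samples."""
    null_cfg = replace(
        cfg, r_min=0.0, r_max=0.0, sigma_resp_het=0.0, sigma_subj_bg=0.0
    )
    return generate_cohort(null_cfg)
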