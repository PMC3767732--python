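"""End-to-end orchestration: (simulate | load) -> preprocess -> signature
-> concordance -> multivariate -> machine-readable report.

The report JSON is deterministic under a fixed seed: keys are sorted and
floats serialize via Python's shortest-repr, so re-running the same
config yields byte-identical output.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import concordance as cc
from . import differential as de
from . import io_formats as io
from . import multivariate as mv
from . import preprocess as pp
from . import synthetic as syn

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG"]

log = logging.getLogger("lobeconcord.pipeline")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "B": 100,
    "methods": ["pearson", "spearman"],
    "linkage": "average",
    "min_fraction": 0.2,
    "log_floor": 0.01,
    "fallback_present_percentile": 10.0,
    "fc_min": 1.5,
    "p_bh_max": 0.01,
    "pca_components": 3,
    # which probe list drives the concordance/multivariate analyses:
    # "planted" (synthetic runs), "derived", or a file path
    "signature_source": "planted",
    "synthetic": {},  # SyntheticConfig overrides; omit `input` to simulate
    "input": None,  # {"expression":..., "annotation":..., "detection":..., "scale":...}
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for k, v in user.items():
            if k not in cfg:
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(cfg.get(k), dict) and isinstance(v, Mapping):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _log_kv(stage: str, **kv: Any) -> None:
    items = " ".join(f"{k}={v}" for k, v in kv.items())
    log.info("%s %s %s", time.strftime("%Y-%m-%dT%H:%M:%S"), stage, items)


def run_pipeline(config: Mapping[str, Any] | str | Path, outdir: str | Path) -> dict:
    """Run every stage and write per-stage outputs plus ``report.json``
    under ``outdir``.  Returns the report dict."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else {
        **{k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()},
        **{k: v for k, v in config.items()},
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # ---- stage: input ----
    planted: io.ProbeList | None = None
    if cfg.get("input"):
        paths = cfg["input"]
        expr = io.read_expression(paths["expression"], scale=paths.get("scale", "linear"))
        ann = io.read_annotation(paths["annotation"])
        det = io.read_detection(paths["detection"]) if paths.get("detection") else None
        _log_kv("input", expression=paths["expression"], samples=len(expr.sample_ids))
    else:
        scfg = syn.SyntheticConfig(**{**cfg.get("synthetic", {}), "seed": seed})
        expr, det, ann, planted = syn.generate_cohort(scfg)
        _log_kv(
            "simulate",
            n_subjects=scfg.n_subjects,
            n_nonsmokers=scfg.n_nonsmokers,
            m_total=scfg.m_total,
            m_sig=scfg.m_sig,
            seed=seed,
        )
        io.write_annotation(ann, outdir / "annotation.tsv")
        io.write_probe_list(planted, outdir / "planted_signature.txt")

    # ---- stage: preprocess ----
    norm = pp.normalize_per_gene(pp.normalize_per_chip(expr))
    if det is not None and not det.matches(norm):
        det = io.DetectionMatrix(det.data.loc[norm.probe_ids, norm.sample_ids])
    logm = pp.log2_transform(norm, floor=float(cfg["log_floor"]))
    upper = ann.samples_at_site("upper")
    lower = ann.samples_at_site("lower")
    universe = pp.present_filter(
        norm,
        det,
        {"upper": upper, "lower": lower},
        min_fraction=float(cfg["min_fraction"]),
        fallback_percentile=float(cfg["fallback_present_percentile"]),
    )
    universe = io.ProbeList("universe", universe.probe_ids)
    io.write_probe_list(universe, outdir / "universe.txt")
    _log_kv("preprocess", universe=len(universe), probes=len(norm.probe_ids))

    # ---- stage: signature ----
    derived: io.ProbeList | None = None
    diff_table = None
    if ann.samples_in_group("smoker") and ann.samples_in_group("nonsmoker"):
        derived, diff_table = de.derive_signature(
            norm,
            det,
            ann,
            fc_min=float(cfg["fc_min"]),
            p_bh_max=float(cfg["p_bh_max"]),
            min_fraction=float(cfg["min_fraction"]),
            log_floor=float(cfg["log_floor"]),
            name="derived_signature",
        )
        io.write_probe_list(derived, outdir / "derived_signature.txt")
        io.write_results(diff_table, outdir / "differential.tsv")
    source = cfg["signature_source"]
    if source == "planted":
        if planted is None:
            raise ValueError("signature_source=planted requires a synthetic run")
        signature = planted
    elif source == "derived":
        if derived is None or len(derived) == 0:
            raise ValueError("no derived signature available")
        signature = derived
    else:
        signature = io.read_probe_list(source)
    signature = io.ProbeList(
        signature.name, [p for p in signature.probe_ids if p in set(norm.probe_ids)]
    )
    _log_kv(
        "signature",
        source=source,
        size=len(signature),
        derived_size=(len(derived) if derived is not None else None),
    )

    # ---- stage: paired genome-wide test ----
    paired_table = de.paired_t(logm.subset(universe), ann)
    io.write_results(paired_table, outdir / "paired_t.tsv")
    n_sig_bh = int((paired_table["p_bh"] < 0.05).sum())

    # ---- stage: concordance ----
    pairs = ann.paired_subjects()
    paired_samples = [s for u_l in pairs.values() for s in u_l]
    logm_paired = logm.subset_samples(paired_samples)
    pairing: dict[str, dict] = {}
    for mi, method in enumerate(cfg["methods"]):
        res = cc.pairing_permutation_test(
            logm_paired,
            ann,
            signature,
            universe,
            B=int(cfg["B"]),
            method=method,
            linkage=cfg["linkage"],
            seed=seed + mi,  # distinct null draws per correlation method
        )
        pairing[method] = res.to_dict()
        d = cc.correlation_distance(logm_paired, signature, method=method)
        tree = cc.hierarchical_cluster(d, linkage=cfg["linkage"], labels=logm_paired.sample_ids)
        (outdir / f"dendrogram_{method}.nwk").write_text(tree.to_newick() + "\n")
        io.write_results(pairing[method], outdir / f"pairing_{method}.json")
        _log_kv("concordance", method=method, observed=res.observed_k, p=res.empirical_p)
    per_method_p = [pairing[m]["empirical_p"] for m in cfg["methods"]]
    combined_bound = min(1.0, len(per_method_p) * min(per_method_p))

    # ---- stage: multivariate ----
    scores, evr = mv.pca_scores(
        logm_paired, signature, k=int(cfg["pca_components"])
    )
    io.write_results(scores, outdir / "pca_scores.tsv")
    vl = mv.vector_length_null(
        logm_paired,
        ann,
        signature,
        universe,
        B=int(cfg["B"]),
        seed=seed,
    )
    io.write_results(vl.to_dict(), outdir / "vector_length.json")
    _log_kv("multivariate", observed_median=vl.observed_median, p=vl.empirical_p)

    report = {
        "seed": seed,
        "n_probes_total": len(norm.probe_ids),
        "universe_size": len(universe),
        "signature_source": str(source),
        "signature_size": len(signature),
        "derived_signature_size": (len(derived) if derived is not None else None),
        "n_pairs": len(pairs),
        "paired_test_significant_bh_05": n_sig_bh,
        "pairing": pairing,
        "pairing_combined_bound": combined_bound,
        "vector_length": {
            "observed_median": vl.observed_median,
            "null_quantiles": {str(q): v for q, v in vl.null_quantiles.items()},
            "empirical_p": vl.empirical_p,
        },
        "pca_explained_variance": [float(v) for v in evr],
        "B": int(cfg["B"]),
        "linkage": cfg["linkage"],
    }
    io.write_results(report, outdir / "report.json")
    return report
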