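"""Tabular I/O for the pipeline: expression matrices, detection calls,
sample annotations, probe lists and result tables.

All files are UTF-8, tab-separated, decimal point ``.``, no quoting.
Probe and sample identifiers are opaque strings; nothing here assumes a
particular array platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DetectionMatrix",
    "SampleAnnotation",
    "ProbeList",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_detection",
    "write_detection",
    "read_annotation",
    "write_annotation",
    "read_probe_list",
    "write_probe_list",
    "write_results",
]

SITES = ("upper", "lower")
GROUPS = ("smoker", "nonsmoker")

#: float format used for every TSV we write; 17 significant digits
#: round-trips IEEE doubles exactly.
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicated {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Probe-by-sample intensity table.

    Parameters
    ----------
    data : DataFrame
        Rows indexed by probe id, columns by sample id.
    scale : {"linear", "log2"}
        Linear-scale intensities must be finite and non-negative;
        log2 values merely finite.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise FormatError(f"unknown scale {self.scale!r}")
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise FormatError("expression matrix contains non-finite values")
        if self.scale == "linear" and (vals < 0).any():
            raise FormatError("linear-scale intensities must be non-negative")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, probes: "ProbeList | Iterable[str]") -> "ExpressionMatrix":
        ids = probes.probe_ids if isinstance(probes, ProbeList) else list(probes)
        missing = [p for p in ids if p not in self.data.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[ids], scale=self.scale)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        ids = list(samples)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[ids], scale=self.scale)


@dataclass
class DetectionMatrix:
    """Boolean present/absent call matrix sharing axes with an
    :class:`ExpressionMatrix`."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        self.data = self.data.astype(bool)

    def matches(self, x: ExpressionMatrix) -> bool:
        return list(self.data.index) == x.probe_ids and list(self.data.columns) == x.sample_ids


@dataclass
class SampleAnnotation:
    """Sample-to-subject map defining the paired design.

    Columns: ``subject_id``, ``site`` in {upper, lower}, ``group`` in
    {smoker, nonsmoker}; indexed by sample id.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "site", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "sample")
        bad_site = set(self.table["site"]) - set(SITES)
        if bad_site:
            raise FormatError(f"unknown site token(s): {sorted(bad_site)}")
        bad_group = set(self.table["group"]) - set(GROUPS)
        if bad_group:
            raise FormatError(f"unknown group token(s): {sorted(bad_group)}")
        dup = self.table.duplicated(subset=["subject_id", "site"])
        if dup.any():
            pairs = self.table.loc[dup, ["subject_id", "site"]].to_records(index=False)
            raise FormatError(f"duplicate (subject, site) combination(s): {list(pairs)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def samples_at_site(self, site: str) -> list[str]:
        return list(self.table.index[self.table["site"] == site])

    def paired_subjects(self) -> dict[str, tuple[str, str]]:
        """Subjects with exactly one upper and one lower sample, mapped to
        their (upper_sample, lower_sample) ids, in subject order of first
        appearance."""
        out: dict[str, tuple[str, str]] = {}
        for subj in self.table["subject_id"].unique():
            sub = self.table[self.table["subject_id"] == subj]
            upper = sub.index[sub["site"] == "upper"]
            lower = sub.index[sub["site"] == "lower"]
            if len(upper) == 1 and len(lower) == 1:
                out[str(subj)] = (str(upper[0]), str(lower[0]))
        return out


@dataclass
class ProbeList:
    """Named, ordered, duplicate-free list of probe ids."""

    name: str
    probe_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.probe_ids, "probe")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def __iter__(self):
        return iter(self.probe_ids)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path, scale: str = "linear") -> ExpressionMatrix:
    """Read a tab-delimited expression table: first column probe ids,
    header row sample ids.  Raises :class:`FormatError` on duplicate ids
    and a parse error naming the offending cell on non-numeric input."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        num = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric cell at probe {df.index[i]!r}, sample {col!r}: {v!r}"
                    ) from None
        raise
    return ExpressionMatrix(num, scale=scale)


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    x.data.to_csv(path, sep="\t", index_label="probe_id", float_format=_FLOAT_FMT)


def read_detection(path: str | Path) -> DetectionMatrix:
    """Detection calls encoded as 0/1 (or P/A) in the expression layout."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    mapping = {"0": False, "1": True, "P": True, "A": False,
               "True": True, "False": False}
    try:
        boolean = df.map(lambda v: mapping[v])
    except KeyError as e:
        raise FormatError(f"unknown detection-call token {e.args[0]!r}") from None
    return DetectionMatrix(boolean)


def write_detection(det: DetectionMatrix, path: str | Path) -> None:
    det.data.astype(int).to_csv(path, sep="\t", index_label="probe_id")


def read_annotation(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError("annotation must have a sample_id column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicated sample id(s): {dups[:5]}")
    df = df.set_index("sample_id")
    return SampleAnnotation(df)


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="sample_id")


def read_probe_list(path: str | Path, name: str | None = None) -> ProbeList:
    """One probe id per line; blank lines are skipped; an empty file is an
    error."""
    text = Path(path).read_text(encoding="utf-8")
    ids = [line.strip() for line in text.splitlines() if line.strip()]
    if not ids:
        raise FormatError(f"probe list {path} is empty")
    return ProbeList(name or Path(path).stem, ids)


def write_probe_list(pl: ProbeList, path: str | Path) -> None:
    Path(path).write_text("\n".join(pl.probe_ids) + "\n", encoding="utf-8")


def write_results(results: pd.DataFrame | Mapping, path: str | Path) -> None:
    """Per-probe tables go to TSV; scalar statistics / null distributions
    (mappings) go to JSON with sorted keys for reproducible bytes."""
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    else:
        def default(o):
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serializable: {type(o)}")

        path.write_text(
            json.dumps(results, indent=2, sort_keys=True, default=default) + "\n",
            encoding="utf-8",
        )
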