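"""Core in-memory containers: probe definitions, count matrices, sample sheets.

A cohort is represented by three objects that travel together through the
pipeline: a :class:`CountMatrix` (genes x samples), a list of
:class:`ProbeDef` assigning every probe to a code class, and a
:class:`SampleSheet` with per-sample group labels and clinical annotations.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROBE_CLASSES = ("endogenous", "housekeeping", "positive", "negative")
STAGES = ("raw", "background_corrected", "normalized")
GROUPS = ("normal_PB", "pure_B", "CLL", "MCL", "MZL", "FL", "HCL", "other")
IGVH_STATUSES = ("mutated", "unmutated", "borderline", "unknown")
ZAP70_STATUSES = ("pos", "neg", "unknown")

#: B-CLPD entities other than CLL, used for pooled classifier validation.
BCLPD_GROUPS = ("MCL", "MZL", "FL", "HCL")


class ValidationError(ValueError):
    """Input data violates an invariant (negative count, duplicate id, ...)."""


class FormatError(ValidationError):
    """A file does not conform to its declared container format."""


class ProbeMismatchError(ValidationError):
    """Lane files disagree on the probe set; carries the offending probes."""

    def __init__(self, message: str, probes: Sequence[str] = ()):
        super().__init__(message)
        self.probes = sorted(probes)


class ConfigurationError(ValueError):
    """A pipeline configuration is invalid or incomplete for the operation."""


@dataclasses.dataclass(frozen=True)
class ProbeDef:
    """One probe of the code set.

    Parameters
    ----------
    gene_id:
        Gene symbol / probe name, unique within a code set.
    probe_class:
        One of ``endogenous``, ``housekeeping``, ``positive``, ``negative``.
    note:
        Free-text annotation.
    nominal_conc:
        Spike-in concentration for positive-control probes (arbitrary
        units); ``None`` for all other classes.
    """

    gene_id: str
    probe_class: str
    note: str = ""
    nominal_conc: float | None = None

    def __post_init__(self):
        if self.probe_class not in PROBE_CLASSES:
            raise ValidationError(
                f"unknown probe class {self.probe_class!r} for {self.gene_id!r}"
            )


def validate_codeset(probes: Iterable[ProbeDef]) -> dict[str, ProbeDef]:
    """Check uniqueness and minimal control content; return a gene_id map."""
    by_id: dict[str, ProbeDef] = {}
    for p in probes:
        if p.gene_id in by_id:
            raise ValidationError(f"duplicate gene_id in code set: {p.gene_id!r}")
        by_id[p.gene_id] = p
    return by_id


class CountMatrix:
    """Nonnegative genes x samples count table with probe-class annotation.

    Wraps a :class:`pandas.DataFrame` (index = gene ids, columns = sample
    ids) plus a parallel probe-class Series and a processing ``stage`` flag
    (``raw`` -> ``background_corrected`` -> ``normalized``).
    """

    def __init__(self, data: pd.DataFrame, probe_classes: pd.Series, stage: str = "raw"):
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("count matrix contains non-finite values")
        if (values < 0).any():
            bad = data.index[(values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative counts for genes: {bad}")
        missing = data.index.difference(probe_classes.index)
        if len(missing):
            raise ValidationError(
                f"genes absent from the code set: {missing.tolist()}"
            )
        if stage == "raw" and not np.allclose(values, np.round(values)):
            raise ValidationError("raw-stage counts must be integers")
        self.data = data.astype(float)
        self.probe_classes = probe_classes.reindex(data.index)
        self.stage = stage

    # -- basic introspection -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def genes_of_class(self, probe_class: str) -> list[str]:
        if probe_class not in PROBE_CLASSES:
            raise ValidationError(f"unknown probe class {probe_class!r}")
        mask = self.probe_classes == probe_class
        return self.data.index[mask].tolist()

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown samples: {missing}")
        return CountMatrix(self.data.loc[:, list(samples)], self.probe_classes, self.stage)

    def with_data(self, data: pd.DataFrame, stage: str | None = None) -> "CountMatrix":
        """Return a copy with new values (and optionally an advanced stage)."""
        return CountMatrix(data, self.probe_classes, stage or self.stage)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"CountMatrix({g} genes x {s} samples, stage={self.stage!r})"


def _norm_enum(value, allowed: Sequence[str], default: str, column: str):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return default
    text = str(value).strip()
    folded = {a.lower(): a for a in allowed}
    if text.lower() not in folded:
        raise ValidationError(f"invalid {column} value {text!r}; allowed: {allowed}")
    return folded[text.lower()]


def _norm_pct(value, column: str):
    if value is None or value == "":
        return np.nan
    x = float(value)
    if np.isnan(x):
        return np.nan
    if not 0.0 <= x <= 100.0:
        raise ValidationError(f"{column} must be in [0, 100], got {x}")
    return x


class SampleSheet:
    """Per-sample annotations: group, IgVH status, flow-cytometry percentages.

    Percentages of CD38-positive and of malignant B cells may be missing
    (NaN); IgVH status other than ``unknown`` is meaningful for CLL samples
    only.
    """

    COLUMNS = ("group", "igvh_status", "pct_CD38_pos", "pct_malignant", "zap70_status")

    def __init__(self, table: pd.DataFrame):
        if table.index.has_duplicates:
            raise ValidationError("duplicate sample ids in sample sheet")
        rows = {}
        for sid, row in table.iterrows():
            rows[sid] = {
                "group": _norm_enum(row.get("group"), GROUPS, "other", "group"),
                "igvh_status": _norm_enum(
                    row.get("igvh_status"), IGVH_STATUSES, "unknown", "igvh_status"
                ),
                "pct_CD38_pos": _norm_pct(row.get("pct_CD38_pos"), "pct_CD38_pos"),
                "pct_malignant": _norm_pct(row.get("pct_malignant"), "pct_malignant"),
                "zap70_status": _norm_enum(
                    row.get("zap70_status"), ZAP70_STATUSES, "unknown", "zap70_status"
                ),
            }
        self.table = pd.DataFrame.from_dict(rows, orient="index").reindex(
            columns=list(self.COLUMNS)
        )
        self.table.index.name = "sample_id"

    @property
    def samples(self) -> list[str]:
        return self.table.index.tolist()

    def group_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "group"])

    def samples_in_group(self, group: str) -> list[str]:
        return self.table.index[self.table["group"] == group].tolist()

    def cll_by_igvh(self, status: str) -> list[str]:
        mask = (self.table["group"] == "CLL") & (self.table["igvh_status"] == status)
        return self.table.index[mask].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        counts = self.table["group"].value_counts().to_dict()
        return f"SampleSheet({len(self)} samples, {counts})"


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)
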