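"""Differential expression: group comparisons, the filter cascade, set
algebra, the CV homogeneity filter and signature assembly.

A gene survives the cascade when (i) its mean in the higher-expressing
group reaches the count floor (default 50), (ii) the group-mean ratio
reaches the fold-change threshold (default 2, or <= 1/2 for
down-regulation) and (iii) a two-sided Student t-test on the linear
normalized counts gives p <= alpha (default 0.05). Signatures are built by
set algebra over cascade survivor lists; the homogeneous core keeps genes
whose coefficient of variation across the disease group stays below 0.5.
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, SampleSheet, ValidationError


@dataclasses.dataclass
class ComparisonTable:
    """Per-gene two-group comparison with cascade pass flags.

    ``ratio`` is ``mean_b / mean_a`` (orientation explicit in the field
    names); flags are populated by :func:`apply_cascade`.
    """

    table: pd.DataFrame  # mean_a, sd_a, mean_b, sd_b, ratio, p, zero_variance
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test: str = "student"
    scale: str = "linear"

    def __post_init__(self):
        required = {"mean_a", "sd_a", "mean_b", "sd_b", "ratio", "p", "zero_variance"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"comparison table missing columns: {sorted(missing)}")


def compare_samples(
    m: CountMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    label_a: str = "A",
    label_b: str = "B",
    test: str = "student",
    scale: str = "linear",
) -> ComparisonTable:
    """Two-group comparison over explicit sample lists.

    Means, SDs (n-1) and the ratio ``mean_b / mean_a`` are always computed
    on linear counts (these are what report tables print); the t-test runs
    on linear counts by default or on ``log2(x + 1)`` with ``scale="log"``.
    ``test`` is ``"student"`` (pooled variance) or ``"welch"``. Genes with
    zero variance in both groups get p = 1 and a flag.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError(
            f"need >=2 samples per group, got {len(samples_a)} vs {len(samples_b)}"
        )
    if set(samples_a) & set(samples_b):
        raise ValidationError("comparison groups must be disjoint")
    a = m.data.loc[:, samples_a].to_numpy(dtype=float)
    b = m.data.loc[:, samples_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    sd_a, sd_b = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_a > 0, mean_b / mean_a, np.inf)
        ratio = np.where((mean_a == 0) & (mean_b == 0), np.nan, ratio)
    ta, tb = (np.log2(a + 1.0), np.log2(b + 1.0)) if scale == "log" else (a, b)
    zero_var = (ta.std(axis=1) == 0) & (tb.std(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = stats.ttest_ind(ta, tb, axis=1, equal_var=(test == "student"))
    p = np.where(zero_var, 1.0, result.pvalue)
    # identical nonconstant groups: t = 0 exactly, p = 1
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "sd_a": sd_a,
            "mean_b": mean_b,
            "sd_b": sd_b,
            "ratio": ratio,
            "p": p,
            "zero_variance": zero_var,
        },
        index=m.data.index,
    )
    return ComparisonTable(
        table, label_a, label_b, len(samples_a), len(samples_b), test, scale
    )


def compare_groups(
    m: CountMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    test: str = "student",
    scale: str = "linear",
) -> ComparisonTable:
    """Two-group comparison by sample-sheet group label (B over A ratio)."""
    samples_a = [s for s in sheet.samples_in_group(group_a) if s in m.data.columns]
    samples_b = [s for s in sheet.samples_in_group(group_b) if s in m.data.columns]
    return compare_samples(m, samples_a, samples_b, group_a, group_b, test, scale)


def apply_cascade(
    comparison: ComparisonTable,
    floor: float = 50.0,
    fc: float = 2.0,
    alpha: float = 0.05,
    direction: str = "up_in_b",
    endogenous_only: bool = True,
    bh_correct: bool = False,
) -> list[str]:
    """Apply the count-floor / fold-change / p-value filter cascade.

    ``up_in_b`` keeps genes with ``mean_b >= floor``, ``ratio >= fc`` and
    ``p <= alpha``; ``down_in_b`` keeps ``mean_a >= floor``,
    ``ratio <= 1/fc`` and ``p <= alpha`` — the floor always applies to the
    higher-expressing group. Survivors are returned sorted
    lexicographically; pass flags are annotated onto the comparison table.

    ``bh_correct`` optionally replaces raw p-values by Benjamini-Hochberg
    adjusted ones before thresholding (off by default: the original
    procedure applies no multiplicity correction).
    """
    if floor <= 0 or fc <= 0 or not 0 < alpha <= 1:
        raise ValidationError("cascade thresholds must be positive (alpha in (0, 1])")
    if direction not in ("up_in_b", "down_in_b"):
        raise ValidationError(f"unknown direction {direction!r}")
    t = comparison.table
    p = t["p"].to_numpy(dtype=float)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    if direction == "up_in_b":
        pass_floor = t["mean_b"] >= floor
        pass_fc = t["ratio"] >= fc
    else:
        pass_floor = t["mean_a"] >= floor
        pass_fc = t["ratio"] <= 1.0 / fc
    pass_p = pd.Series(p <= alpha, index=t.index)
    t["pass_floor"], t["pass_fc"], t["pass_p"] = pass_floor, pass_fc, pass_p
    keep = t.index[pass_floor & pass_fc & pass_p]
    return sorted(keep)


def set_ops(lists: Sequence[Sequence[str]], op: str) -> list[str]:
    """Exact set algebra over gene lists, result sorted lexicographically.

    ``difference`` is the first list minus the union of the rest.
    """
    if not lists:
        return []
    sets = [set(lst) for lst in lists]
    if op == "intersect":
        result = set.intersection(*sets)
    elif op == "union":
        result = set.union(*sets)
    elif op == "difference":
        result = sets[0].difference(*sets[1:]) if len(sets) > 1 else sets[0]
    else:
        raise ValidationError(f"unknown set operation {op!r}")
    return sorted(result)


def cv_filter_values(cv: Mapping[str, float] | pd.Series, cv_max: float = 0.5) -> list[str]:
    """Keep genes whose coefficient of variation is strictly below ``cv_max``."""
    series = pd.Series(cv, dtype=float)
    return sorted(series.index[series < cv_max])


def cv_filter(
    m: CountMatrix,
    sheet: SampleSheet,
    genes: Sequence[str],
    group: str = "CLL",
    cv_max: float = 0.5,
) -> tuple[list[str], pd.Series]:
    """CV homogeneity filter: keep genes with SD/mean < ``cv_max`` in ``group``.

    Genes with zero group mean are excluded (CV undefined; reported as NaN).
    """
    samples = [s for s in sheet.samples_in_group(group) if s in m.data.columns]
    if len(samples) < 2:
        raise ValidationError(f"group {group!r} needs >=2 samples for a CV")
    sub = m.data.loc[list(genes), samples]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = pd.Series(np.where(mean > 0, sd / mean, np.nan), index=sub.index, name="cv")
    kept = cv_filter_values(cv.dropna(), cv_max)
    return kept, cv


@dataclasses.dataclass
class Signature:
    """A named gene list with enough provenance to re-derive it."""

    name: str
    genes: list[str]
    provenance: dict

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name}: duplicate genes")

    def to_dict(self) -> dict:
        return {"name": self.name, "genes": self.genes, "provenance": self.provenance}


def derive_signatures(
    m: CountMatrix,
    sheet: SampleSheet,
    floor: float = 50.0,
    fc: float = 2.0,
    alpha: float = 0.05,
    cv_max: float = 0.5,
    test: str = "student",
    scale: str = "linear",
) -> dict[str, Signature]:
    """Derive the full signature collection from a normalized cohort.

    Produces, as cohort composition allows:

    * ``B_cell`` — genes up in pure B cells vs normal PB,
    * ``CLL_vs_PB`` / ``CLL_vs_pureB`` — genes up in CLL vs each control,
    * ``LymphCLL_Diag`` — their intersection (the diagnostic signature),
    * ``Core`` — diagnostic genes with CV < ``cv_max`` across CLL samples,
    * ``CLL_under`` — genes down in CLL vs pure B cells,
    * ``LymphCLL_Mut`` — genes separating IgVH mutated from unmutated CLL
      (borderline cases excluded), the union of both directions.

    Missing groups cause the dependent signatures to be skipped with a
    warning rather than an error.
    """
    thresholds = {"floor": floor, "fc": fc, "alpha": alpha, "test": test, "scale": scale}
    stamp = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
    present = {
        g: [s for s in sheet.samples_in_group(g) if s in m.data.columns]
        for g in ("normal_PB", "pure_B", "CLL")
    }
    signatures: dict[str, Signature] = {}

    def make(name, genes, **extra):
        signatures[name] = Signature(
            name, list(genes), {**thresholds, **extra, "derived_at": stamp}
        )

    have = {g: len(s) >= 2 for g, s in present.items()}
    if have["normal_PB"] and have["pure_B"]:
        t = compare_groups(m, sheet, "normal_PB", "pure_B", test, scale)
        make(
            "B_cell",
            apply_cascade(t, floor, fc, alpha, "up_in_b"),
            comparison="pure_B vs normal_PB, up in pure_B",
        )
    else:
        warnings.warn("B_cell signature skipped: needs normal_PB and pure_B groups")

    up_pb = up_pureb = None
    if have["CLL"] and have["normal_PB"]:
        t = compare_groups(m, sheet, "normal_PB", "CLL", test, scale)
        up_pb = apply_cascade(t, floor, fc, alpha, "up_in_b")
        make("CLL_vs_PB", up_pb, comparison="CLL vs normal_PB, up in CLL")
    if have["CLL"] and have["pure_B"]:
        t = compare_groups(m, sheet, "pure_B", "CLL", test, scale)
        up_pureb = apply_cascade(t, floor, fc, alpha, "up_in_b")
        make("CLL_vs_pureB", up_pureb, comparison="CLL vs pure_B, up in CLL")
        down = apply_cascade(t, floor, fc, alpha, "down_in_b")
        make("CLL_under", down, comparison="CLL vs pure_B, down in CLL")
    if up_pb is not None and up_pureb is not None:
        diag = set_ops([up_pb, up_pureb], "intersect")
        make("LymphCLL_Diag", diag, derivation="intersection(CLL_vs_PB, CLL_vs_pureB)")
        core, cv = cv_filter(m, sheet, diag, "CLL", cv_max)
        make(
            "Core",
            core,
            derivation=f"LymphCLL_Diag genes with CV < {cv_max} across CLL samples",
            cv={g: float(cv[g]) for g in diag},
        )
    else:
        warnings.warn("LymphCLL_Diag/Core skipped: need CLL plus both control groups")

    mutated = [s for s in sheet.cll_by_igvh("mutated") if s in m.data.columns]
    unmutated = [s for s in sheet.cll_by_igvh("unmutated") if s in m.data.columns]
    if len(mutated) >= 2 and len(unmutated) >= 2:
        t = compare_samples(m, mutated, unmutated, "CLL_mutated", "CLL_unmutated", test, scale)
        up_unmut = apply_cascade(t, floor, fc, alpha, "up_in_b")
        up_mut = apply_cascade(t, floor, fc, alpha, "down_in_b")
        make(
            "LymphCLL_Mut",
            set_ops([up_unmut, up_mut], "union"),
            comparison="IgVH mutated vs unmutated CLL (borderline excluded)",
            up_in_unmutated=up_unmut,
            up_in_mutated=up_mut,
        )
    else:
        warnings.warn("LymphCLL_Mut skipped: need >=2 mutated and >=2 unmutated CLL samples")
    return signatures
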