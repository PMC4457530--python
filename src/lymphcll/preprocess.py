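"""Control-based preprocessing of nCounter count matrices.

Three stages, matching platform practice for targeted count panels:

1. **Background correction** — per sample, the mean of the negative-control
   (alien-probe) counts plus two sample standard deviations is subtracted
   from every non-negative-control count; results are clamped at zero.
2. **Reference-gene selection** — candidate normalization genes are ranked
   by the geNorm stability measure M (the mean, over all other candidates,
   of the across-sample standard deviation of pairwise log2 expression
   ratios); the least stable gene is eliminated iteratively until the
   requested number remain.
3. **Normalization** — each sample is scaled by ``G / g_s`` where ``g_s``
   is the geometric mean of the selected reference genes in sample ``s``
   and ``G`` the geometric mean of the ``g_s`` across samples, so that the
   normalization factors themselves have geometric mean one.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, CountMatrix, ProbeDef, ValidationError


@dataclasses.dataclass
class StabilityRanking:
    """geNorm result: stability values per elimination step and selection."""

    candidates: list[str]
    #: one mapping gene -> M per elimination round (first = all candidates)
    m_values: list[dict[str, float]]
    elimination_order: list[str]
    selected: list[str]


@dataclasses.dataclass
class NormalizationFactors:
    factors: pd.Series  # per-sample multiplicative factor, geomean == 1
    reference_geomean: float
    hk_genes: list[str]


def background_correct(m: CountMatrix) -> tuple[CountMatrix, pd.DataFrame]:
    """Subtract the per-sample negative-control mean + 2 SD, clamping at 0.

    Negative-control rows are retained unchanged for audit. Returns the
    corrected matrix and a per-sample background model (columns
    ``neg_mean``, ``neg_sd``, ``threshold``).

    The SD is the sample standard deviation (n - 1 denominator), hence at
    least two negative-control probes are required.
    """
    if m.stage != "raw":
        raise ValidationError(f"background correction expects raw counts, got {m.stage!r}")
    neg = m.genes_of_class("negative")
    if len(neg) < 2:
        raise ConfigurationError(
            f"need >=2 negative-control probes for background SD, found {len(neg)}"
        )
    neg_counts = m.data.loc[neg]
    neg_mean = neg_counts.mean(axis=0)
    neg_sd = neg_counts.std(axis=0, ddof=1)
    threshold = neg_mean + 2.0 * neg_sd
    model = pd.DataFrame(
        {"neg_mean": neg_mean, "neg_sd": neg_sd, "threshold": threshold}
    )
    model.index.name = "sample_id"
    corrected = (m.data - threshold).clip(lower=0.0)
    corrected.loc[neg] = m.data.loc[neg]
    return m.with_data(corrected, stage="background_corrected"), model


def _pairwise_logratio_sd(x_j: np.ndarray, x_k: np.ndarray) -> float:
    return float(np.std(np.log2(x_j / x_k), ddof=1))


def genorm_rank(
    m: CountMatrix,
    candidates: Sequence[str],
    n_select: int = 3,
    pseudo_count: float = 0.5,
) -> StabilityRanking:
    """Rank candidate reference genes by geNorm stability and select the best.

    ``M_j`` is the mean over all other remaining candidates ``k`` of the
    across-sample standard deviation of ``log2(x_j / x_k)``; the gene with
    the highest M is removed each round until ``n_select`` remain. Ties are
    broken by removing the lexicographically greatest gene id, and the final
    pair is never split (selection stops at ``n_select >= 2``).

    Candidate counts <= 0 are replaced by ``pseudo_count`` with a warning so
    the log-ratios stay defined.
    """
    candidates = list(candidates)
    if n_select < 2:
        raise ConfigurationError("n_select must be >= 2 (the final pair is never split)")
    if len(candidates) <= n_select:
        raise ConfigurationError(
            f"need more candidates ({len(candidates)}) than n_select ({n_select})"
        )
    missing = [g for g in candidates if g not in m.data.index]
    if missing:
        raise ValidationError(f"candidate genes absent from matrix: {missing}")
    values = m.data.loc[candidates].to_numpy(dtype=float).copy()
    if (values <= 0).any():
        n_bad = int((values <= 0).sum())
        warnings.warn(
            f"{n_bad} non-positive candidate counts replaced by pseudo-count {pseudo_count}"
        )
        values[values <= 0] = pseudo_count
    counts = {g: values[i] for i, g in enumerate(candidates)}

    remaining = sorted(candidates)
    m_steps: list[dict[str, float]] = []
    elimination: list[str] = []
    while True:
        m_now = {
            j: float(
                np.mean([_pairwise_logratio_sd(counts[j], counts[k]) for k in remaining if k != j])
            )
            for j in remaining
        }
        m_steps.append(m_now)
        if len(remaining) <= n_select:
            break
        worst_m = max(m_now.values())
        # lexicographically greatest among the tied-worst genes
        worst = max(g for g, v in m_now.items() if v == worst_m)
        elimination.append(worst)
        remaining = [g for g in remaining if g != worst]
    return StabilityRanking(
        candidates=sorted(candidates),
        m_values=m_steps,
        elimination_order=elimination,
        selected=sorted(remaining),
    )


def geometric_mean(x: np.ndarray | pd.Series) -> float:
    arr = np.asarray(x, dtype=float)
    return float(np.exp(np.mean(np.log(arr))))


def normalize(
    m: CountMatrix, hk_genes: Sequence[str]
) -> tuple[CountMatrix, NormalizationFactors]:
    """Scale each sample by the geometric mean of its reference-gene counts.

    Factor for sample ``s`` is ``G / g_s`` with ``g_s`` the geometric mean
    of the reference genes in ``s`` and ``G`` the geometric mean of all
    ``g_s`` — so the factors themselves have geometric mean 1 and
    re-normalization is idempotent.
    """
    hk_genes = list(hk_genes)
    missing = [g for g in hk_genes if g not in m.data.index]
    if missing:
        raise ValidationError(f"reference genes absent from matrix: {missing}")
    hk = m.data.loc[hk_genes]
    if (hk.to_numpy() <= 0).any():
        bad = hk.columns[(hk <= 0).any(axis=0)].tolist()
        raise ValidationError(
            f"reference gene count <= 0 in samples {bad}; reselect reference genes "
            "or apply a pseudo-count before normalization"
        )
    g_s = hk.apply(geometric_mean, axis=0)
    big_g = geometric_mean(g_s)
    factors = big_g / g_s
    normalized = m.data.mul(factors, axis=1)
    return (
        m.with_data(normalized, stage="normalized"),
        NormalizationFactors(factors=factors, reference_geomean=big_g, hk_genes=hk_genes),
    )


def qc_positive_controls(
    m: CountMatrix,
    probes: Sequence[ProbeDef],
    r2_floor: float = 0.95,
) -> pd.DataFrame:
    """Per-sample linearity QC of the spiked positive controls.

    Fits log2(count) against log2(nominal concentration) for each sample and
    flags samples whose R^2 falls below ``r2_floor``. Advisory only: flagged
    samples are never dropped by the pipeline.
    """
    conc = {
        p.gene_id: p.nominal_conc
        for p in probes
        if p.probe_class == "positive" and p.nominal_conc is not None
    }
    if len(conc) < 3:
        warnings.warn(
            "positive-control QC skipped: need >=3 positive probes with nominal concentrations"
        )
        return pd.DataFrame(columns=["slope", "r_squared", "flagged"])
    genes = sorted(conc)
    missing = [g for g in genes if g not in m.data.index]
    if missing:
        raise ValidationError(f"positive-control probes absent from matrix: {missing}")
    log_conc = np.log2([conc[g] for g in genes])
    rows = {}
    for sample in m.samples:
        log_counts = np.log2(m.data.loc[genes, sample].to_numpy(dtype=float) + 1.0)
        if np.allclose(log_counts, log_counts[0]):
            rows[sample] = {"slope": 0.0, "r_squared": 0.0, "flagged": True}
            continue
        fit = stats.linregress(log_conc, log_counts)
        r2 = float(fit.rvalue**2)
        rows[sample] = {
            "slope": float(fit.slope),
            "r_squared": r2,
            "flagged": bool(r2 < r2_floor),
        }
    qc = pd.DataFrame.from_dict(rows, orient="index")
    qc.index.name = "sample_id"
    return qc


def preprocess_pipeline(
    m: CountMatrix,
    probes: Sequence[ProbeDef],
    hk_candidates: Sequence[str] | None = None,
    n_hk: int = 3,
    pseudo_count: float = 0.5,
) -> dict:
    """Run background correction, geNorm selection and normalization.

    ``hk_candidates`` defaults to all housekeeping-class probes. Returns a
    dict with the normalized matrix, the background model, the stability
    ranking, the normalization factors and the positive-control QC table.
    """
    corrected, background = background_correct(m)
    if hk_candidates is None:
        hk_candidates = corrected.genes_of_class("housekeeping")
    if len(hk_candidates) < 2:
        raise ConfigurationError("need >=2 housekeeping candidates")
    if len(hk_candidates) > n_hk:
        ranking = genorm_rank(corrected, hk_candidates, n_select=n_hk, pseudo_count=pseudo_count)
        selected = ranking.selected
    else:
        ranking = StabilityRanking(sorted(hk_candidates), [], [], sorted(hk_candidates))
        selected = ranking.selected
    normalized, factors = normalize(corrected, selected)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qc = qc_positive_controls(m, probes)
    return {
        "normalized": normalized,
        "background": background,
        "ranking": ranking,
        "factors": factors,
        "qc": qc,
    }
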