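"""Signature-based classification and the three ratio markers.

Classification operates on a ``log2(count + 1)``, per-gene z-scored view of
the normalized matrix restricted to a signature's genes: PCA for
visualization/embedding, average-linkage hierarchical clustering for the
unsupervised two-class split, nearest centroid for supervised prediction.

Ratio markers:

* **kappa/lambda clonality** — the light-chain transcript ratio is compared
  to a polyclonal reference interval (mean +/- 2 SD of polyclonal
  samples' ratios; with the published reference, 0.89 +/- 0.44);
* **LDOC1/ADAM29** — a present/absent trichotomy (LDOC1-high,
  ADAM29-high, double-negative) that mirrors IgVH mutation status except
  for the double-negative subclass;
* **LPL/ADAM29** — the surrogate marker for IgVH status (ratio > 1 reads
  unmutated-like).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import CountMatrix, SampleSheet, ValidationError

#: polyclonal kappa/lambda reference published for normal PB and pure B cells
POLYCLONAL_KL_MEAN = 0.89
POLYCLONAL_KL_SD = 0.22


def transform_matrix(m: CountMatrix, genes: Sequence[str]) -> pd.DataFrame:
    """log2(x+1) then per-gene z-score; returns samples x genes.

    Genes constant after the log transform carry no information and are
    dropped with a warning.
    """
    missing = [g for g in genes if g not in m.data.index]
    if missing:
        raise ValidationError(f"signature genes absent from matrix: {missing}")
    x = np.log2(m.data.loc[list(genes)].to_numpy(dtype=float) + 1.0)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValidationError("all signature genes are constant after transform")
    if not keep.all():
        import warnings

        dropped = [g for g, k in zip(genes, keep) if not k]
        warnings.warn(f"constant genes dropped from transform: {dropped}")
    x = x[keep]
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
    return pd.DataFrame(z.T, index=m.samples, columns=[g for g, k in zip(genes, keep) if k])


@dataclasses.dataclass
class PCAEmbedding:
    coordinates: pd.DataFrame  # samples x PC1..PCk
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x PCs


def embed_pca(m: CountMatrix, genes: Sequence[str], n_components: int = 3) -> PCAEmbedding:
    """PCA of the transformed signature matrix.

    Components are ordered by decreasing variance; each component's sign is
    fixed so its largest-magnitude gene loading is positive.
    """
    z = transform_matrix(m, genes)
    if len(z) < 3:
        raise ValidationError("PCA needs >=3 samples")
    n_components = min(n_components, min(z.shape))
    centered = z.to_numpy() - z.to_numpy().mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    explained = s**2 / (len(z) - 1)
    total = centered.var(axis=0, ddof=1).sum()
    for i in range(n_components):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    coords = u[:, :n_components] * s[:n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAEmbedding(
        coordinates=pd.DataFrame(coords, index=z.index, columns=cols),
        explained_variance=explained[:n_components],
        explained_variance_ratio=explained[:n_components] / total,
        loadings=pd.DataFrame(vt[:n_components].T, index=z.columns, columns=cols),
    )


@dataclasses.dataclass
class ClassificationReport:
    predicted: pd.Series  # per-sample predicted truth-class label
    truth: pd.Series
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: dict  # {(truth, predicted): count}
    positive_label: str
    coordinates: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "positive_label": self.positive_label,
            "confusion": {f"{t}->{p}": c for (t, p), c in self.confusion.items()},
            "predicted": self.predicted.to_dict(),
        }


def _score_mapping(truth: pd.Series, predicted: pd.Series, positive: str) -> tuple:
    acc = float((truth == predicted).mean())
    pos = truth == positive
    sens = float((predicted[pos] == positive).mean()) if pos.any() else math.nan
    spec = float((predicted[~pos] != positive).mean()) if (~pos).any() else math.nan
    confusion = {
        (t, p): int(((truth == t) & (predicted == p)).sum())
        for t in truth.unique()
        for p in truth.unique()
    }
    return acc, sens, spec, confusion


def cluster_classify(
    m: CountMatrix,
    genes: Sequence[str],
    sheet: SampleSheet,
    truth_field: str = "group",
    positive_label: str | None = None,
    linkage: str = "average",
) -> ClassificationReport:
    """Unsupervised two-cluster split scored against a binary truth label.

    Hierarchical clustering (Euclidean distance, average linkage by
    default) on the transformed signature matrix is cut into two clusters;
    each cluster is mapped to the truth label it agrees with most
    (maximum-agreement assignment over both mappings). The positive class
    for sensitivity/specificity defaults to the rarer label.
    """
    truth_all = sheet.table[truth_field]
    labeled = [s for s in m.samples if s in truth_all.index]
    truth = truth_all.loc[labeled].astype(str)
    classes = sorted(truth.unique())
    if len(classes) != 2:
        raise ValidationError(
            f"cluster_classify expects exactly 2 truth classes, got {classes}; "
            "pool or one-vs-rest the labels first"
        )
    if min((truth == c).sum() for c in classes) < 2:
        raise ValidationError("each truth class needs >=2 samples")
    z = transform_matrix(m.subset_samples(labeled), genes)
    link = hierarchy.linkage(pdist(z.to_numpy()), method=linkage)
    cut = hierarchy.fcluster(link, t=2, criterion="maxclust")
    best = None
    for mapping in ({1: classes[0], 2: classes[1]}, {1: classes[1], 2: classes[0]}):
        predicted = pd.Series([mapping[c] for c in cut], index=z.index)
        agreement = (predicted == truth).sum()
        if best is None or agreement > best[0]:
            best = (agreement, predicted)
    predicted = best[1]
    positive = positive_label or min(classes, key=lambda c: ((truth == c).sum(), c))
    acc, sens, spec, confusion = _score_mapping(truth, predicted, positive)
    return ClassificationReport(predicted, truth, acc, sens, spec, confusion, positive)


def nearest_centroid(
    m: CountMatrix,
    genes: Sequence[str],
    sheet: SampleSheet,
    truth_field: str = "group",
    positive_label: str | None = None,
) -> ClassificationReport:
    """Nearest-centroid prediction on the transformed signature matrix.

    Centroids are the per-class means of the transformed matrix; every
    labeled sample is assigned to its nearest centroid by Euclidean
    distance (self-inclusive resubstitution — the deterministic supervised
    rule for labeling new samples; use holdout sample sets for unbiased
    error estimates).
    """
    truth_all = sheet.table[truth_field]
    labeled = [s for s in m.samples if s in truth_all.index]
    truth = truth_all.loc[labeled].astype(str)
    classes = sorted(truth.unique())
    if len(classes) < 2:
        raise ValidationError("nearest_centroid needs >=2 truth classes")
    z = transform_matrix(m.subset_samples(labeled), genes)
    centroids = np.stack([z.to_numpy()[(truth == c).to_numpy()].mean(axis=0) for c in classes])
    d = ((z.to_numpy()[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    predicted = pd.Series([classes[i] for i in d.argmin(axis=1)], index=z.index)
    positive = positive_label or min(classes, key=lambda c: ((truth == c).sum(), c))
    acc, sens, spec, confusion = _score_mapping(truth, predicted, positive)
    return ClassificationReport(predicted, truth, acc, sens, spec, confusion, positive)


@dataclasses.dataclass
class ClonalityCall:
    ratio: float  # kappa / lambda (inf when lambda == 0)
    interval_low: float
    interval_high: float
    call: str  # polyclonal | monoclonal_kappa | monoclonal_lambda


def clonality_call(
    kappa: float,
    lam: float,
    reference: tuple[float, float] | Sequence[float] | None = None,
) -> ClonalityCall:
    """Call light-chain clonality from kappa and lambda transcript counts.

    ``reference`` is either ``(mean, sd)`` of the polyclonal kappa/lambda
    ratio or an iterable of polyclonal samples' ratios (mean and n-1 SD are
    then computed); default is the published polyclonal reference
    (0.89 +/- 0.22). The call is polyclonal inside mean +/- 2 SD,
    monoclonal_kappa above, monoclonal_lambda below.
    """
    if kappa < 0 or lam < 0:
        raise ValidationError("light-chain counts must be nonnegative")
    if kappa == 0 and lam == 0:
        raise ValidationError("both light chains zero: clonality indeterminate")
    if reference is None:
        mean, sd = POLYCLONAL_KL_MEAN, POLYCLONAL_KL_SD
    elif len(tuple(reference)) == 2 and np.isscalar(tuple(reference)[0]):
        mean, sd = float(tuple(reference)[0]), float(tuple(reference)[1])
    else:
        ratios = np.asarray(list(reference), dtype=float)
        mean, sd = float(ratios.mean()), float(ratios.std(ddof=1))
    low, high = mean - 2.0 * sd, mean + 2.0 * sd
    ratio = math.inf if lam == 0 else kappa / lam
    if ratio > high:
        call = "monoclonal_kappa"
    elif ratio < low:
        call = "monoclonal_lambda"
    else:
        call = "polyclonal"
    return ClonalityCall(ratio, low, high, call)


@dataclasses.dataclass
class MutMarkerCall:
    ldoc1: float
    adam29: float
    trichotomy: str  # ldoc1_high | adam29_high | double_negative
    lpl_adam29_ratio: float
    lpl_call: str  # unmutated_like | mutated_like | indeterminate
    adam29_pseudo: bool = False  # denominator pseudo-count applied


def mut_marker_call(
    ldoc1: float,
    adam29: float,
    lpl: float,
    absence_threshold: float = 50.0,
    ratio_cut: float = 1.0,
) -> MutMarkerCall:
    """Call the LDOC1/ADAM29 trichotomy and the LPL/ADAM29 surrogate status.

    Both markers below ``absence_threshold`` give the double-negative
    subclass (LPL call indeterminate there); otherwise the higher marker
    wins. The LPL/ADAM29 ratio uses a pseudo-count of 1 in the denominator
    when ADAM29 is zero (flagged); ratio > ``ratio_cut`` reads
    unmutated-like.
    """
    if min(ldoc1, adam29, lpl) < 0:
        raise ValidationError("marker counts must be nonnegative")
    if ldoc1 < absence_threshold and adam29 < absence_threshold:
        trichotomy = "double_negative"
    elif ldoc1 >= adam29:
        trichotomy = "ldoc1_high"
    else:
        trichotomy = "adam29_high"
    pseudo = adam29 == 0
    ratio = lpl / (adam29 if adam29 > 0 else 1.0)
    if trichotomy == "double_negative":
        lpl_call = "indeterminate"
    else:
        lpl_call = "unmutated_like" if ratio > ratio_cut else "mutated_like"
    return MutMarkerCall(ldoc1, adam29, trichotomy, ratio, lpl_call, pseudo)


def protein_mrna_correlation(
    sheet: SampleSheet,
    m: CountMatrix,
    gene: str,
    field: str = "pct_CD38_pos",
    method: str = "pearson",
) -> tuple[float, int]:
    """Correlate a flow-cytometry percentage with a gene's normalized counts.

    Pairs with a missing percentage are dropped; returns (r, n). Pearson by
    default, Spearman on request.
    """
    if gene not in m.data.index:
        raise ValidationError(f"gene {gene!r} absent from matrix")
    pct = sheet.table[field]
    shared = [s for s in m.samples if s in pct.index and not pd.isna(pct[s])]
    if len(shared) < 3:
        raise ValidationError(f"need >=3 samples with {field}, got {len(shared)}")
    x = pct.loc[shared].to_numpy(dtype=float)
    y = m.data.loc[gene, shared].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined: zero variance")
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValidationError(f"unknown method {method!r}")
    return float(r), len(shared)


def marker_table(
    m: CountMatrix,
    sheet: SampleSheet,
    kappa_gene: str = "kappa",
    lambda_gene: str = "lambda",
    reference: tuple[float, float] | None = None,
    absence_threshold: float = 50.0,
    ratio_cut: float = 1.0,
) -> pd.DataFrame:
    """Per-sample ratio-marker calls as one tidy table.

    When ``reference`` is None the polyclonal interval is estimated from
    the cohort's own normal_PB and pure_B samples if there are at least
    three, else the published reference is used.
    """
    if reference is None:
        poly = [
            s
            for s in sheet.samples_in_group("normal_PB") + sheet.samples_in_group("pure_B")
            if s in m.data.columns
        ]
        if len(poly) >= 3 and kappa_gene in m.data.index and lambda_gene in m.data.index:
            ratios = (
                m.data.loc[kappa_gene, poly].to_numpy(dtype=float)
                / m.data.loc[lambda_gene, poly].to_numpy(dtype=float)
            )
            reference = (float(ratios.mean()), float(ratios.std(ddof=1)))
        else:
            reference = (POLYCLONAL_KL_MEAN, POLYCLONAL_KL_SD)
    rows = {}
    have_kl = kappa_gene in m.data.index and lambda_gene in m.data.index
    have_mut = all(g in m.data.index for g in ("LDOC1", "ADAM29", "LPL"))
    for s in m.samples:
        row: dict = {"group": sheet.group_of(s) if s in sheet.table.index else "other"}
        if have_kl:
            try:
                call = clonality_call(
                    float(m.data.loc[kappa_gene, s]), float(m.data.loc[lambda_gene, s]), reference
                )
                row.update(kl_ratio=call.ratio, clonality=call.call)
            except ValidationError:
                row.update(kl_ratio=np.nan, clonality="indeterminate")
        if have_mut:
            mc = mut_marker_call(
                float(m.data.loc["LDOC1", s]),
                float(m.data.loc["ADAM29", s]),
                float(m.data.loc["LPL", s]),
                absence_threshold,
                ratio_cut,
            )
            row.update(
                ldoc1=mc.ldoc1,
                adam29=mc.adam29,
                ldoc1_adam29_class=mc.trichotomy,
                lpl_adam29_ratio=mc.lpl_adam29_ratio,
                lpl_call=mc.lpl_call,
            )
        rows[s] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
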