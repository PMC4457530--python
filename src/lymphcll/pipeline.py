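"""End-to-end orchestration and report-table rendering.

``run_pipeline`` composes loading, preprocessing, signature derivation,
classification and marker calling into a run directory with a
machine-readable provenance record; ``render_tables`` formats the stored
comparison tables the way the printed report tables lay them out (ratio at
one decimal, half away from zero; p-values at fixed precision).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import diffexp
from .classify import cluster_classify, embed_pca, marker_table, nearest_centroid
from .containers import ConfigurationError, CountMatrix, SampleSheet, ValidationError, round_half_away
from .io import read_codeset, read_counts_csv, read_rcc, read_sample_sheet, write_counts_csv
from .preprocess import preprocess_pipeline

logger = logging.getLogger("lymphcll")

_THRESHOLD_RANGES = {
    "floor": (0.0, np.inf),
    "fc": (1.0, np.inf),
    "alpha": (0.0, 1.0),
    "cv_max": (0.0, np.inf),
    "n_hk": (2, 100),
    "pseudo_count": (0.0, np.inf),
    "absence_threshold": (0.0, np.inf),
    "ratio_cut": (0.0, np.inf),
}


@dataclasses.dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run; unknown keys rejected."""

    counts: str | list[str]  # counts CSV or list of RCC files
    codeset: str | None = None  # required with a CSV counts path
    samples: str | None = None
    out_dir: str = "run"
    stage: str = "raw"
    hk_candidates: list[str] | None = None
    n_hk: int = 3
    pseudo_count: float = 0.5
    floor: float = 50.0
    fc: float = 2.0
    alpha: float = 0.05
    cv_max: float = 0.5
    test: str = "student"
    scale: str = "linear"
    classify_signature: str = "LymphCLL_Diag"
    classify_mode: str = "cluster"  # cluster | centroid
    absence_threshold: float = 50.0
    ratio_cut: float = 1.0

    def __post_init__(self):
        for key, (lo, hi) in _THRESHOLD_RANGES.items():
            v = getattr(self, key)
            if not lo <= v <= hi:
                raise ConfigurationError(f"{key}={v} outside valid range [{lo}, {hi}]")
        if self.test not in ("student", "welch") or self.scale not in ("linear", "log"):
            raise ConfigurationError("test must be student|welch, scale linear|log")
        if self.classify_mode not in ("cluster", "centroid"):
            raise ConfigurationError("classify_mode must be cluster|centroid")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_inputs(config: PipelineConfig):
    counts = config.counts
    if isinstance(counts, (list, tuple)):
        m, probes = read_rcc(list(counts))
    else:
        if config.codeset is None:
            raise ConfigurationError("a CSV counts path requires a codeset path")
        probes = read_codeset(config.codeset)
        m = read_counts_csv(counts, probes, stage=config.stage)
    if config.samples is None:
        raise ConfigurationError("a sample sheet path is required")
    sheet = read_sample_sheet(config.samples)
    return m, probes, sheet


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write outputs + provenance into the run directory.

    Deterministic given config + inputs. Raises on stage errors after
    logging the failing stage; no partial provenance record is written.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "load"
    try:
        m, probes, sheet = load_inputs(config)
        logger.info("loaded %d genes x %d samples (stage=%s)", *m.shape, m.stage)

        if m.stage == "raw":
            stage = "preprocess"
            pp = preprocess_pipeline(
                m, probes, config.hk_candidates, config.n_hk, config.pseudo_count
            )
            norm = pp["normalized"]
            pp["background"].to_csv(out / "background.csv")
            pd.DataFrame(
                {"factor": pp["factors"].factors}
            ).to_csv(out / "normalization_factors.csv", index_label="sample_id")
            m_csv = pd.DataFrame(pp["ranking"].m_values)
            m_csv.to_csv(out / "genorm_m_values.csv", index_label="elimination_round")
            pp["qc"].to_csv(out / "qc_positive_controls.csv")
            (out / "qc.json").write_text(
                json.dumps(
                    {
                        "hk_selected": pp["ranking"].selected,
                        "hk_elimination_order": pp["ranking"].elimination_order,
                        "flagged_samples": pp["qc"].index[pp["qc"].get("flagged", pd.Series(dtype=bool)) == True].tolist(),  # noqa: E712
                    },
                    indent=1,
                )
            )
            logger.info("normalizers: %s", pp["ranking"].selected)
        else:
            norm = m
        write_counts_csv(norm, out / "normalized.csv")

        stage = "derive"
        signatures = diffexp.derive_signatures(
            norm, sheet, config.floor, config.fc, config.alpha, config.cv_max,
            config.test, config.scale,
        )
        (out / "signatures.json").write_text(
            json.dumps({k: v.to_dict() for k, v in signatures.items()}, indent=1, sort_keys=True)
        )
        tables_dir = out / "tables"
        tables_dir.mkdir(exist_ok=True)
        _write_comparisons(norm, sheet, config, tables_dir)

        stage = "classify"
        report = None
        sig = signatures.get(config.classify_signature)
        groups = set(sheet.table["group"])
        if sig and sig.genes and {"CLL"} < groups:
            pool = sheet.table["group"].map(
                lambda g: "CLL" if g == "CLL" else "non_CLL"
            )
            sheet2 = SampleSheet(sheet.table.assign(group=sheet.table["group"]))
            sheet2.table["pooled"] = pool
            fn = cluster_classify if config.classify_mode == "cluster" else nearest_centroid
            report = fn(norm, sig.genes, sheet2, truth_field="pooled", positive_label="CLL")
            emb = embed_pca(norm, sig.genes, n_components=3)
            report.coordinates = emb.coordinates
            emb.coordinates.to_csv(out / "pca_coordinates.csv", index_label="sample_id")
            (out / "classification.json").write_text(json.dumps(report.to_dict(), indent=1))
            logger.info("classification accuracy %.3f", report.accuracy)

        stage = "markers"
        markers = marker_table(
            norm, sheet, absence_threshold=config.absence_threshold, ratio_cut=config.ratio_cut
        )
        markers.to_csv(out / "markers.csv")

        stage = "provenance"
        prov = {
            "config": dataclasses.asdict(config),
            "inputs": {
                str(p): _sha256(Path(p))
                for p in (
                    ([config.counts] if isinstance(config.counts, str) else list(config.counts))
                    + [x for x in (config.codeset, config.samples) if x]
                )
            },
            "elapsed_s": round(time.time() - t0, 3),
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True))
        return out
    except Exception:
        logger.exception("stage %r failed", stage)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_comparisons(norm, sheet, config, tables_dir: Path):
    pairs = [
        ("normal_PB", "pure_B", "b_cell_vs_pb.csv"),
        ("normal_PB", "CLL", "cll_vs_pb.csv"),
        ("pure_B", "CLL", "cll_vs_pureb.csv"),
    ]
    for a, b, name in pairs:
        if len(sheet.samples_in_group(a)) >= 2 and len(sheet.samples_in_group(b)) >= 2:
            t = diffexp.compare_groups(norm, sheet, a, b, config.test, config.scale)
            diffexp.apply_cascade(t, config.floor, config.fc, config.alpha)
            t.table.to_csv(tables_dir / name, index_label="gene_id")
    mut = sheet.cll_by_igvh("mutated")
    unmut = sheet.cll_by_igvh("unmutated")
    if len(mut) >= 2 and len(unmut) >= 2:
        t = diffexp.compare_samples(norm, mut, unmut, "CLL_mutated", "CLL_unmutated",
                                    config.test, config.scale)
        diffexp.apply_cascade(t, config.floor, config.fc, config.alpha)
        t.table.to_csv(tables_dir / "mut_vs_unmut.csv", index_label="gene_id")


def format_comparison(
    table: pd.DataFrame,
    mean_cols: Sequence[str] = ("mean_a", "mean_b"),
    ratio_col: str = "ratio",
    p_col: str = "p",
    p_decimals: int = 3,
    descending_ratio: bool = True,
) -> pd.DataFrame:
    """Render a comparison table the way printed report tables are laid out.

    Means at two decimals, the ratio at one decimal rounded half away from
    zero, p at ``p_decimals``; rows sorted by descending ratio.
    """
    out = pd.DataFrame(index=table.index)
    for c in mean_cols:
        out[c] = table[c].map(lambda x: f"{x:.2f}")
    out[ratio_col] = table[ratio_col].map(
        lambda x: f"{round_half_away(x, 1):.1f}" if np.isfinite(x) else ""
    )
    out[p_col] = table[p_col].map(lambda x: f"{x:.{p_decimals}f}")
    if descending_ratio:
        order = table[ratio_col].sort_values(ascending=False).index
        out = out.loc[order]
    return out


def render_tables(run_dir: str | Path, p_decimals: int = 3) -> list[Path]:
    """Format every stored comparison table in a completed run directory."""
    run_dir = Path(run_dir)
    tables_dir = run_dir / "tables"
    if not tables_dir.is_dir():
        raise ValidationError(f"no tables directory under {run_dir}")
    written = []
    for path in sorted(tables_dir.glob("*.csv")):
        if path.stem.endswith("_formatted"):
            continue
        t = pd.read_csv(path, index_col=0)
        out_path = tables_dir / f"{path.stem}_formatted.csv"
        if {"pass_floor", "pass_fc", "pass_p"} <= set(t.columns):
            t = t.loc[t["pass_floor"] & t["pass_fc"] & t["pass_p"]]
        rendered = format_comparison(t, p_decimals=p_decimals)
        rendered.to_csv(out_path, index_label="gene_id")
        written.append(out_path)
    return written
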