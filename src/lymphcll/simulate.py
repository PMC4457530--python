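"""Seeded generator of nCounter-like CLL cohorts with ground truth.

The generator emulates the data-generating structure the analysis assumes:

* per-sample multiplicative size factors (log-normal),
* negative-control probes (Poisson background, unaffected by biology),
* positive-control probes proportional to their nominal concentration,
* stable housekeeping genes (the nine normalization candidates, three of
  them most stable),
* group-specific fold changes for a B-cell panel, a CLL panel (a
  homogeneous core plus heterogeneous genes), an IgVH mutation-status
  panel seeded from the published group means/dispersions, genes lost in
  CLL relative to normal B cells, and neutral filler genes,
* immunoglobulin light-chain skew in clonal samples (dominant chain with
  the minor chain suppressed ~50-fold; polyclonal samples draw their
  kappa/lambda ratio from the published 0.89 +/- 0.22 reference),
* the LDOC1/ADAM29 present/absent dichotomy, including a both-absent
  subgroup (default five of thirty CLL samples: two mutated, three
  unmutated).

Counts are ``round(f_s * mu_g * FC_{g,group(s)} * exp(eps))`` with
``eps ~ N(0, sigma_g^2)``. Randomness flows through per-gene and
per-sample substreams derived from one global seed, so adding a gene does
not reshuffle every other count. The same config + seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    BCLPD_GROUPS,
    ConfigurationError,
    CountMatrix,
    ProbeDef,
    SampleSheet,
)
from .io import write_codeset, write_counts_csv, write_sample_sheet

_BCLPD = "BCLPD"  # fold-change key shared by MCL/MZL/FL/HCL


@dataclasses.dataclass(frozen=True)
class GeneSpec:
    """Simulation parameters for one probe.

    ``fc`` maps group keys (``pure_B``, ``CLL``, ``CLL_mutated``,
    ``CLL_unmutated``, ``CLL_borderline``, ``BCLPD``) to multiplicative
    fold changes over the normal-PB baseline ``base``; absent keys mean 1.
    """

    gene: str
    probe_class: str = "endogenous"
    base: float = 100.0
    sigma: float = 0.4
    fc: Mapping[str, float] = dataclasses.field(default_factory=dict)
    panel: str = "filler"
    nominal_conc: float | None = None

    def fold_change(self, group: str, igvh: str) -> float:
        if group == "CLL":
            key = f"CLL_{igvh}"
            if key in self.fc:
                return float(self.fc[key])
            return float(self.fc.get("CLL", 1.0))
        if group in BCLPD_GROUPS:
            return float(self.fc.get(group, self.fc.get(_BCLPD, 1.0)))
        return float(self.fc.get(group, 1.0))


def _default_genes(n_fillers: int, filler_sigma: float, neg_lambda: float) -> list[GeneSpec]:
    g: list[GeneSpec] = []

    # nine normalization candidates; RPL19/RPLP0/TPT1 are the most stable
    hk = [
        ("RPL19", 8000, 0.02),
        ("RPLP0", 6000, 0.02),
        ("TPT1", 9000, 0.02),
        ("ACTB", 20000, 0.06),
        ("TBP", 500, 0.06),
        ("G6PD", 800, 0.06),
        ("ABCF1", 600, 0.06),
        ("B2M", 30000, 0.06),
        ("RPS23", 4000, 0.06),
    ]
    g += [GeneSpec(n, "housekeeping", b, s, {}, "housekeeping") for n, b, s in hk]

    g += [
        GeneSpec(f"NEG_{c}", "negative", neg_lambda, 0.0, {}, "negative")
        for c in "ABCDEFGH"
    ]
    for letter, conc in zip("ABCDEF", (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)):
        g.append(
            GeneSpec(f"POS_{letter}", "positive", 80.0 * conc, 0.05, {}, "positive", conc)
        )

    # B-cell panel: high in pure B cells and B-cell malignancies; fold
    # changes follow the published pure-B/normal-PB and CLL ratios
    bcell = [
        ("CD19", 608, {"pure_B": 28.3, "CLL": 31.5, _BCLPD: 25.0}),
        ("CD20", 2112, {"pure_B": 31.7, "CLL": 9.3, _BCLPD: 28.0}),
        ("CD22", 825, {"pure_B": 29.0, "CLL": 10.4, _BCLPD: 22.0}),
        ("CD79A", 3448, {"pure_B": 34.7, "CLL": 18.6, _BCLPD: 30.0}),
        ("CD79B", 182, {"pure_B": 20.2, "CLL": 25.6, _BCLPD: 18.0}),
        ("PAX5", 268, {"pure_B": 40.8, "CLL": 30.0, _BCLPD: 32.0}),
        ("FCER2", 226, {"pure_B": 32.5, "CLL": 70.6, _BCLPD: 20.0}),
        ("CD83", 3283, {"pure_B": 41.6, "CLL": 3.6, _BCLPD: 30.0}),
        ("CD40", 542, {"pure_B": 22.2, "CLL": 8.0, _BCLPD: 18.0}),
    ]
    g += [GeneSpec(n, "endogenous", b, 0.35, fc, "b_cell") for n, b, fc in bcell]

    # genes lost in CLL relative to normal B cells
    under = [
        ("IL6", 50, {"pure_B": 35.0, "CLL": 0.02, _BCLPD: 10.0}),
        ("TIMP4", 5, {"pure_B": 19.0, "CLL": 0.2, _BCLPD: 5.0}),
        ("MMP12", 5, {"pure_B": 18.0, "CLL": 0.2, _BCLPD: 4.0}),
    ]
    g += [GeneSpec(n, "endogenous", b, 0.35, fc, "under") for n, b, fc in under]

    # CLL panel, homogeneous core: sigma 0.3 -> CV ~ 0.31, below the 0.5 cut
    core = [
        ("BMI1", 75, 8.0),
        ("CD200", 500, 20.0),
        ("CD27", 850, 10.0),
        ("CD5", 250, 16.0),
        ("COL9A2", 200, 25.0),
        ("DNMBP", 380, 12.0),
        ("FAIM3", 1470, 30.0),
        ("GNRH1", 58, 9.0),
        ("LEF1", 480, 15.0),
        ("RASGRF1", 150, 20.0),
        ("ROR1", 170, 14.0),
        ("SFMBT1", 920, 12.0),
        ("TTN", 400, 18.0),
    ]
    g += [GeneSpec(n, "endogenous", b, 0.3, {"CLL": f}, "cll_core") for n, b, f in core]

    # CLL panel, heterogeneous genes: sigma 0.8 -> CV ~ 0.95, above the cut
    hetero = [("CLLU1", 560), ("LILRA4", 180), ("WNT3", 520), ("FGF2", 70), ("IGFBP4", 490)]
    g += [GeneSpec(n, "endogenous", b, 0.8, {"CLL": 10.0}, "cll_hetero") for n, b in hetero]

    # IgVH mutation-status panel; fold changes and dispersions follow the
    # published mutated/unmutated group means and SDs
    mut_up_unmut = [
        ("ZAP70", 1400, {"pure_B": 0.2, "CLL_mutated": 0.96, "CLL_unmutated": 2.49,
                         "CLL_borderline": 1.5}, 0.40),
        ("CD38", 496, {"pure_B": 2.2, "CLL_mutated": 0.28, "CLL_unmutated": 2.88,
                       "CLL_borderline": 1.0}, 0.90),
        ("SEPT10", 10, {"CLL_mutated": 1.0, "CLL_unmutated": 117.0, "CLL_borderline": 10.0}, 1.0),
        ("AICDA", 5, {"CLL_mutated": 0.5, "CLL_unmutated": 24.0, "CLL_borderline": 3.0}, 1.0),
        ("FARP1", 4, {"CLL_mutated": 1.0, "CLL_unmutated": 14.0, "CLL_borderline": 4.0}, 1.0),
        ("CNR1", 50, {"CLL_mutated": 1.0, "CLL_unmutated": 11.6, "CLL_borderline": 4.0}, 0.9),
        ("DMD", 1400, {"CLL_mutated": 1.0, "CLL_unmutated": 3.79, "CLL_borderline": 2.0}, 0.7),
        ("CEACAM1", 194, {"CLL_mutated": 1.0, "CLL_unmutated": 3.0, "CLL_borderline": 1.7}, 0.8),
        ("CRY1", 500, {"CLL_mutated": 1.0, "CLL_unmutated": 2.76, "CLL_borderline": 1.6}, 0.5),
        ("ITGA4", 600, {"CLL_mutated": 1.0, "CLL_unmutated": 2.55, "CLL_borderline": 1.5}, 0.6),
        ("TCL1A", 15285, {"CLL_mutated": 1.0, "CLL_unmutated": 2.53, "CLL_borderline": 1.5}, 0.6),
        ("CD26", 60, {"CLL_mutated": 1.0, "CLL_unmutated": 2.5, "CLL_borderline": 1.5}, 0.8),
        ("VPREB3", 2530, {"CLL_mutated": 1.0, "CLL_unmutated": 2.18, "CLL_borderline": 1.4}, 0.5),
    ]
    mut_up_mut = [
        ("CTLA4", 8500, {"CLL_mutated": 2.16, "CLL_unmutated": 1.0, "CLL_borderline": 1.4}, 0.7),
        ("RARA", 1185, {"CLL_mutated": 2.87, "CLL_unmutated": 1.0, "CLL_borderline": 1.5}, 0.6),
        ("LGMN", 38, {"CLL_mutated": 3.0, "CLL_unmutated": 1.0, "CLL_borderline": 1.5}, 0.7),
        ("CD150", 490, {"CLL_mutated": 3.4, "CLL_unmutated": 1.0, "CLL_borderline": 1.6}, 0.6),
    ]
    g += [GeneSpec(n, "endogenous", b, s, fc, "mut_up_unmut") for n, b, fc, s in mut_up_unmut]
    g += [GeneSpec(n, "endogenous", b, s, fc, "mut_up_mut") for n, b, fc, s in mut_up_mut]

    # present/absent markers and light chains are filled per sample by the
    # generator (marker class, clonality); base/sigma here are the
    # "present" level and its noise, LPL follows IgVH status
    g.append(GeneSpec("LDOC1", "endogenous", 483, 0.6, {}, "marker"))
    g.append(GeneSpec("ADAM29", "endogenous", 1061, 0.9, {}, "marker"))
    # LPL follows IgVH status like the mut panel but lives with the markers
    # so the LPL/ADAM29 ratio call can find it
    g.append(
        GeneSpec("LPL", "endogenous", 91, 0.6,
                 {"CLL_mutated": 1.0, "CLL_unmutated": 11.78, "CLL_borderline": 3.0},
                 "marker")
    )
    g.append(GeneSpec("kappa", "endogenous", 11354, 0.25, {"pure_B": 6.2}, "light_chain"))
    g.append(GeneSpec("lambda", "endogenous", 12757, 0.25, {"pure_B": 5.0}, "light_chain"))

    # neutral fillers: deterministic spread of baselines
    bases = (20.0, 80.0, 300.0, 1200.0, 5000.0)
    for i in range(n_fillers):
        g.append(
            GeneSpec(f"GENE{i + 1:03d}", "endogenous", bases[i % 5] * (1.0 + i / 50.0),
                     filler_sigma, {}, "filler")
        )
    return g


@dataclasses.dataclass
class SimConfig:
    """Cohort composition and noise model; defaults mirror the study design.

    30 CLL patients (11 IgVH mutated, 17 unmutated, 2 borderline), 5 normal
    peripheral-blood and 4 purified B-cell samples, plus the 51-sample
    B-CLPD validation series (20 MCL, 22 MZL, 4 FL, 5 HCL).
    """

    n_normal_PB: int = 5
    n_pure_B: int = 4
    n_cll_mutated: int = 11
    n_cll_unmutated: int = 17
    n_cll_borderline: int = 2
    n_mcl: int = 20
    n_mzl: int = 22
    n_fl: int = 4
    n_hcl: int = 5
    include_bclpd: bool = True

    n_fillers: int = 150
    filler_sigma: float = 0.4
    size_factor_log_sd: float = 0.15
    neg_lambda: float = 5.0

    #: CLL samples with neither LDOC1 nor ADAM29 expressed: (mutated, unmutated)
    n_double_negative: tuple[int, int] = (2, 3)
    marker_absent_level: float = 2.0
    kappa_prob: float = 0.6
    clonal_suppression: float = 50.0
    clonal_light_chain_total: float = 135000.0
    kl_mean: float = 0.89
    kl_sd: float = 0.22

    #: replace the Poisson negative-control draw by its mean (noiseless mode)
    deterministic_negatives: bool = False
    #: plant the LDOC1/ADAM29 present/absent structure in CLL samples
    plant_marker_dichotomy: bool = True

    seed: int = 0
    genes: list[GeneSpec] | None = None

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("n_") and isinstance(v, int) and v < 0:
                raise ConfigurationError(f"{f.name} must be >= 0")
        if self.size_factor_log_sd < 0 or self.filler_sigma < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        if self.genes is None:
            self.genes = _default_genes(self.n_fillers, self.filler_sigma, self.neg_lambda)
        if not any(g.probe_class == "negative" for g in self.genes):
            raise ConfigurationError("config must define at least one negative-control probe")
        dn_m, dn_u = self.n_double_negative
        if dn_m > self.n_cll_mutated or dn_u > self.n_cll_unmutated:
            raise ConfigurationError("double-negative counts exceed group sizes")

    def noiseless(self) -> "SimConfig":
        """Copy with every noise source set to zero (expected-mean output)."""
        genes = [dataclasses.replace(g, sigma=0.0) for g in self.genes]
        return dataclasses.replace(
            self, genes=genes, size_factor_log_sd=0.0, filler_sigma=0.0, kl_sd=0.0,
            deterministic_negatives=True,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_double_negative"] = list(self.n_double_negative)
        d["genes"] = [
            {**dataclasses.asdict(g), "fc": dict(g.fc)} for g in self.genes
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        genes = d.pop("genes", None)
        if "n_double_negative" in d:
            d["n_double_negative"] = tuple(d["n_double_negative"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if genes is not None:
            cfg.genes = [GeneSpec(**g) for g in genes]
        return cfg


@dataclasses.dataclass
class TruthRecord:
    """Ground truth: everything needed to reconstruct count expectations."""

    config: SimConfig
    seed: int
    size_factors: pd.Series
    planted: dict[str, list[str]]  # panel name -> gene list
    clonality: dict[str, str]  # sample -> polyclonal | monoclonal_kappa | monoclonal_lambda
    marker_class: dict[str, str]  # CLL sample -> ldoc1_high | adam29_high | double_negative

    def expected_mean(self, gene: str, sample: str, group: str, igvh: str) -> float:
        spec = next(g for g in self.config.genes if g.gene == gene)
        return spec.base * spec.fold_change(group, igvh) * float(self.size_factors[sample])

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "size_factors": {k: float(v) for k, v in self.size_factors.items()},
            "planted": self.planted,
            "clonality": self.clonality,
            "marker_class": self.marker_class,
        }


@dataclasses.dataclass
class Cohort:
    counts: CountMatrix
    sheet: SampleSheet
    probes: list[ProbeDef]
    truth: TruthRecord


def _rng(seed: int, stream: int, name: str = "") -> np.random.Generator:
    return np.random.default_rng([seed, stream, zlib.crc32(name.encode())])


def _sample_plan(config: SimConfig) -> list[tuple[str, str, str]]:
    """(sample_id, group, igvh) in deterministic order."""
    plan = []
    plan += [(f"PB{i + 1:02d}", "normal_PB", "unknown") for i in range(config.n_normal_PB)]
    plan += [(f"B{i + 1:02d}", "pure_B", "unknown") for i in range(config.n_pure_B)]
    k = 0
    for status, n in (
        ("mutated", config.n_cll_mutated),
        ("unmutated", config.n_cll_unmutated),
        ("borderline", config.n_cll_borderline),
    ):
        for _ in range(n):
            k += 1
            plan.append((f"CLL{k:02d}", "CLL", status))
    if config.include_bclpd:
        for group, n in (
            ("MCL", config.n_mcl),
            ("MZL", config.n_mzl),
            ("FL", config.n_fl),
            ("HCL", config.n_hcl),
        ):
            plan += [(f"{group}{i + 1:02d}", group, "unknown") for i in range(n)]
    return plan


def generate_cohort(config: SimConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a raw count matrix, sample sheet, code set and truth record.

    ``seed`` overrides ``config.seed``; the same (config, seed) pair is
    bit-identical across runs.
    """
    config = config or SimConfig()
    seed = config.seed if seed is None else int(seed)
    plan = _sample_plan(config)
    samples = [s for s, _, _ in plan]
    group = {s: g for s, g, _ in plan}
    igvh = {s: v for s, _, v in plan}

    sf_rng = _rng(seed, 1, "size_factors")
    size_factors = pd.Series(
        np.exp(sf_rng.normal(0.0, config.size_factor_log_sd, len(samples))), index=samples
    )

    # marker classes for CLL samples: mutated -> ADAM29-high, unmutated ->
    # LDOC1-high, except the configured double-negative subgroup; the
    # borderline cases alternate between the two expressed classes
    dn_m, dn_u = config.n_double_negative
    marker_class: dict[str, str] = {}
    if not config.plant_marker_dichotomy:
        dn_m = dn_u = 0
    mut_s = [s for s in samples if group[s] == "CLL" and igvh[s] == "mutated"]
    unmut_s = [s for s in samples if group[s] == "CLL" and igvh[s] == "unmutated"]
    border_s = [s for s in samples if group[s] == "CLL" and igvh[s] == "borderline"]
    if config.plant_marker_dichotomy:
        dn_rng = _rng(seed, 2, "double_negative")
        dn_pick = set(dn_rng.choice(mut_s, size=dn_m, replace=False)) | set(
            dn_rng.choice(unmut_s, size=dn_u, replace=False)
        ) if (mut_s and unmut_s) else set()
        for s in mut_s:
            marker_class[s] = "double_negative" if s in dn_pick else "adam29_high"
        for s in unmut_s:
            marker_class[s] = "double_negative" if s in dn_pick else "ldoc1_high"
        for i, s in enumerate(border_s):
            marker_class[s] = "adam29_high" if i % 2 == 0 else "ldoc1_high"

    # clonality: CLL and other B-CLPD carry one dominant light chain
    clon_rng = _rng(seed, 3, "clonality")
    clonality: dict[str, str] = {}
    for s in samples:
        if group[s] in ("CLL",) + BCLPD_GROUPS:
            kappa_clone = clon_rng.random() < config.kappa_prob
            clonality[s] = "monoclonal_kappa" if kappa_clone else "monoclonal_lambda"
        else:
            clonality[s] = "polyclonal"

    n = len(samples)
    data: dict[str, np.ndarray] = {}
    f = size_factors.to_numpy()
    for spec in config.genes:
        rng = _rng(seed, 4, spec.gene)
        if spec.probe_class == "negative":
            if config.deterministic_negatives:
                data[spec.gene] = np.full(n, np.round(spec.base))
            else:
                data[spec.gene] = rng.poisson(spec.base, n).astype(float)
            continue
        if spec.panel == "light_chain":
            continue  # handled jointly below
        if spec.gene in ("LDOC1", "ADAM29"):
            level = np.array(
                [
                    spec.base
                    if (
                        (spec.gene == "LDOC1" and marker_class.get(s) == "ldoc1_high")
                        or (spec.gene == "ADAM29" and marker_class.get(s) == "adam29_high")
                    )
                    else config.marker_absent_level
                    for s in samples
                ]
            )
        else:
            level = np.array(
                [spec.base * spec.fold_change(group[s], igvh[s]) for s in samples]
            )
        noise = np.exp(rng.normal(0.0, 1.0, n) * spec.sigma) if spec.sigma > 0 else 1.0
        data[spec.gene] = np.round(level * f * noise)

    # light chains
    kappa_spec = next(g for g in config.genes if g.gene == "kappa")
    kl_rng = _rng(seed, 5, "light_chains")
    kappa = np.zeros(n)
    lam = np.zeros(n)
    for i, s in enumerate(samples):
        if clonality[s] == "polyclonal":
            ratio = max(0.3, kl_rng.normal(config.kl_mean, config.kl_sd))
            base_k = kappa_spec.base * kappa_spec.fold_change(group[s], igvh[s])
            noise = (
                np.exp(kl_rng.normal(0.0, kappa_spec.sigma)) if kappa_spec.sigma > 0 else 1.0
            )
            kappa[i] = base_k * f[i] * noise
            lam[i] = kappa[i] / ratio
        else:
            total_sigma = 0.8 if kappa_spec.sigma > 0 else 0.0
            total = config.clonal_light_chain_total * (
                np.exp(kl_rng.normal(0.0, total_sigma)) if total_sigma else 1.0
            )
            minor_noise = (
                np.exp(kl_rng.normal(0.0, 0.3)) if kappa_spec.sigma > 0 else 1.0
            )
            minor = total / config.clonal_suppression * minor_noise
            if clonality[s] == "monoclonal_kappa":
                kappa[i], lam[i] = total * f[i], minor * f[i]
            else:
                kappa[i], lam[i] = minor * f[i], total * f[i]
    data["kappa"] = np.round(kappa)
    data["lambda"] = np.round(lam)

    order = [g.gene for g in config.genes]
    matrix = pd.DataFrame({s: [data[g][i] for g in order] for i, s in enumerate(samples)},
                          index=order)
    probes = [
        ProbeDef(g.gene, g.probe_class, f"panel={g.panel}", g.nominal_conc)
        for g in config.genes
    ]
    classes = pd.Series({p.gene_id: p.probe_class for p in probes})
    counts = CountMatrix(matrix, classes, stage="raw")

    # sample sheet with flow-cytometry style annotations for CLL samples
    sheet_rng = _rng(seed, 6, "sheet")
    rows = {}
    for i, s in enumerate(samples):
        row = {
            "group": group[s],
            "igvh_status": igvh[s],
            "pct_CD38_pos": np.nan,
            "pct_malignant": np.nan,
            "zap70_status": "unknown",
        }
        if group[s] == "CLL":
            cd38 = float(data["CD38"][i]) / f[i]
            pct = 100.0 * cd38 / (cd38 + 800.0)
            pct *= np.exp(sheet_rng.normal(0.0, 0.3))
            row["pct_CD38_pos"] = float(np.clip(pct, 0.0, 100.0))
            row["pct_malignant"] = float(np.round(sheet_rng.uniform(58.0, 100.0), 1))
            row["zap70_status"] = "pos" if data["ZAP70"][i] / f[i] > 2000.0 else "neg"
        rows[s] = row
    sheet = SampleSheet(pd.DataFrame.from_dict(rows, orient="index"))

    by_panel: dict[str, list[str]] = {}
    for g in config.genes:
        by_panel.setdefault(g.panel, []).append(g.gene)
    planted = {
        # every endogenous gene the generator makes B-cell-preferential:
        # expected pure-B fold change >= 2 at an expected mean >= 50
        "b_cell": sorted(
            g.gene
            for g in config.genes
            if g.probe_class == "endogenous"
            and g.panel not in ("marker",)
            and g.fold_change("pure_B", "unknown") >= 2.0
            and g.base * g.fold_change("pure_B", "unknown") >= 50.0
        ),
        "core": sorted(by_panel.get("cll_core", [])),
        "cll": sorted(by_panel.get("cll_core", []) + by_panel.get("cll_hetero", [])),
        "under": sorted(
            by_panel.get("under", [])
            + [
                g.gene
                for g in config.genes
                if g.panel == "b_cell"
                and g.fold_change("CLL", "unknown") / g.fold_change("pure_B", "unknown") < 0.5
            ]
        ),
        "mut_up_unmutated": sorted(by_panel.get("mut_up_unmut", []) + ["LDOC1", "LPL"]),
        "mut_up_mutated": sorted(by_panel.get("mut_up_mut", []) + ["ADAM29"]),
    }
    planted["mut"] = sorted(planted["mut_up_unmutated"] + planted["mut_up_mutated"])

    truth = TruthRecord(config, seed, size_factors, planted, clonality, marker_class)
    return Cohort(counts, sheet, probes, truth)


def recovery_config(seed: int = 0) -> SimConfig:
    """Parameter-recovery study design.

    Control groups of ten samples each, the planted signature panels
    carrying fold changes of at least four, and every other endogenous
    gene neutral (fold change 1, no IgVH effects, no marker dichotomy) —
    the design under which signature derivation is expected to recover the
    planted panels essentially exactly.
    """
    cfg = SimConfig(
        n_normal_PB=10, n_pure_B=10, plant_marker_dichotomy=False, seed=seed
    )
    genes = []
    for g in cfg.genes:
        if g.panel in ("mut_up_unmut", "mut_up_mut", "marker"):
            genes.append(dataclasses.replace(g, fc={}))
        elif g.panel == "b_cell":
            genes.append(
                dataclasses.replace(g, fc={k: v for k, v in g.fc.items() if k == "pure_B"})
            )
        else:
            genes.append(g)
    cfg.genes = genes
    return cfg


def write_fixture(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write counts.csv, codeset.csv, samples.csv and truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.csv",
        "codeset": directory / "codeset.csv",
        "samples": directory / "samples.csv",
        "truth": directory / "truth.json",
    }
    write_counts_csv(cohort.counts, paths["counts"])
    write_codeset(cohort.probes, paths["codeset"])
    write_sample_sheet(cohort.sheet, paths["samples"])
    paths["truth"].write_text(json.dumps(cohort.truth.to_dict(), indent=1, sort_keys=True))
    return paths
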