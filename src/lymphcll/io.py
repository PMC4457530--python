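"""Readers and writers for RCC lane files, count CSVs, code sets and sample
sheets.

The RCC reader accepts the common comma-separated section layout
(``<Header>``, ``<Sample_Attributes>``, ``<Lane_Attributes>``,
``<Code_Summary>``); unknown sections are skipped so that files from
different instrument software versions remain readable.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .containers import (
    CountMatrix,
    FormatError,
    ProbeDef,
    ProbeMismatchError,
    SampleSheet,
    ValidationError,
    validate_codeset,
)

_CODECLASS_MAP = {
    "endogenous": "endogenous",
    "housekeeping": "housekeeping",
    "positive": "positive",
    "negative": "negative",
}


def _map_code_class(code_class: str, gene: str) -> str:
    key = code_class.strip().lower()
    # vendor panels carry extra classes (SpikeIn, Binding, ...): fail open
    if key not in _CODECLASS_MAP:
        warnings.warn(
            f"probe {gene!r}: unknown CodeClass {code_class!r} mapped to endogenous"
        )
        return "endogenous"
    return _CODECLASS_MAP[key]


def _parse_rcc_sections(path: Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw_line in path.read_text().splitlines():
        line = raw_line.strip()
        if not line:
            continue
        if line.startswith("</") and line.endswith(">"):
            current = None
        elif line.startswith("<") and line.endswith(">"):
            current = line[1:-1]
            sections.setdefault(current, [])
        elif current is not None:
            sections[current].append(line)
    return sections


def read_rcc(paths: Sequence[str | os.PathLike]) -> tuple[CountMatrix, list[ProbeDef]]:
    """Read one or more RCC lane files into a raw count matrix.

    One sample per file; the sample id is the ``ID`` entry of the
    ``Sample_Attributes`` section when present, else the file stem. All
    files must carry identical probe sets.
    """
    if not paths:
        raise ValidationError("no RCC files given")
    per_sample: dict[str, pd.Series] = {}
    probes: list[ProbeDef] | None = None
    reference_genes: list[str] | None = None
    for p in paths:
        path = Path(p)
        sections = _parse_rcc_sections(path)
        for required in ("Header", "Lane_Attributes", "Code_Summary"):
            if required not in sections:
                raise FormatError(f"{path}: missing <{required}> section")
        sample_id = path.stem
        for line in sections.get("Sample_Attributes", []):
            key, _, value = line.partition(",")
            if key.strip() == "ID" and value.strip():
                sample_id = value.strip()
        rows = sections["Code_Summary"]
        if not rows:
            raise FormatError(f"{path}: empty Code_Summary")
        header = [h.strip() for h in rows[0].split(",")]
        try:
            i_class = header.index("CodeClass")
            i_name = header.index("Name")
            i_count = header.index("Count")
        except ValueError as exc:
            raise FormatError(
                f"{path}: Code_Summary must have CodeClass, Name, Count columns"
            ) from exc
        file_probes: list[ProbeDef] = []
        counts: dict[str, int] = {}
        for row in rows[1:]:
            fields = [f.strip() for f in row.split(",")]
            gene = fields[i_name]
            if gene in counts:
                raise ValidationError(f"{path}: duplicate probe {gene!r}")
            counts[gene] = int(float(fields[i_count]))
            file_probes.append(ProbeDef(gene, _map_code_class(fields[i_class], gene)))
        genes = list(counts)
        if reference_genes is None:
            reference_genes, probes = genes, file_probes
        elif set(genes) != set(reference_genes):
            diff = set(genes) ^ set(reference_genes)
            raise ProbeMismatchError(
                f"{path}: probe set differs from first file: {sorted(diff)}", diff
            )
        per_sample[sample_id] = pd.Series(counts)
    assert probes is not None and reference_genes is not None
    data = pd.DataFrame(
        {sid: s.reindex(reference_genes) for sid, s in per_sample.items()},
        index=reference_genes,
    )
    classes = pd.Series({p.gene_id: p.probe_class for p in probes})
    validate_codeset(probes)
    return CountMatrix(data, classes, stage="raw"), probes


def read_counts_csv(
    path: str | os.PathLike,
    codeset: Iterable[ProbeDef],
    stage: str = "raw",
) -> CountMatrix:
    """Read a genes x samples CSV count matrix against a code set.

    The first column holds gene ids, remaining columns one sample each.
    ``stage`` declares whether the body is raw integer counts or an
    already-normalized matrix. Gene ids absent from the code set raise a
    :class:`ValidationError` naming them.
    """
    table = pd.read_csv(path, index_col=0)
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene rows in {path}: {dupes}")
    by_id = validate_codeset(codeset)
    classes = pd.Series({g: p.probe_class for g, p in by_id.items()})
    return CountMatrix(table, classes, stage=stage)


def write_counts_csv(m: CountMatrix, path: str | os.PathLike) -> None:
    data = m.data
    if m.stage == "raw":
        data = data.astype(int)
    data.to_csv(path, index_label="gene_id")


def read_codeset(path: str | os.PathLike) -> list[ProbeDef]:
    """Read a code-set CSV (gene_id, probe_class[, note, nominal_conc])."""
    table = pd.read_csv(path)
    probes = []
    for _, row in table.iterrows():
        conc = row.get("nominal_conc")
        conc = None if conc is None or pd.isna(conc) else float(conc)
        note = row.get("note", "")
        probes.append(
            ProbeDef(
                str(row["gene_id"]),
                _map_code_class(str(row["probe_class"]), str(row["gene_id"])),
                "" if pd.isna(note) else str(note),
                conc,
            )
        )
    validate_codeset(probes)
    return probes


def write_codeset(probes: Iterable[ProbeDef], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": p.gene_id,
                "probe_class": p.probe_class,
                "note": p.note,
                "nominal_conc": p.nominal_conc,
            }
            for p in probes
        ]
    ).to_csv(path, index=False)


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Read a sample-sheet CSV (sample_id + annotation columns).

    Enum columns are case-insensitive; missing optional columns are filled
    with unknown/missing values.
    """
    table = pd.read_csv(path, index_col=0)
    return SampleSheet(table)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.table.to_csv(path, index_label="sample_id")
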