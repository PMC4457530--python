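"""Shared fixtures: small hand-written lane files and cached synthetic runs."""

from __future__ import annotations

import warnings

import pytest

import lymphcll as L
from lymphcll.preprocess import preprocess_pipeline

RCC_TEMPLATE = """\
<Header>
FileVersion,1.7
SoftwareVersion,4.0
</Header>
<Sample_Attributes>
ID,{sample_id}
Owner,lab
</Sample_Attributes>
<Lane_Attributes>
ID,1
FovCount,555
</Lane_Attributes>
<Code_Summary>
CodeClass,Name,Accession,Count
{rows}
</Code_Summary>
"""


def make_rcc(path, sample_id, rows):
    """rows: list of (code_class, name, count)."""
    body = "\n".join(f"{c},{n},ACC_{n},{v}" for c, n, v in rows)
    path.write_text(RCC_TEMPLATE.format(sample_id=sample_id, rows=body))
    return path


DEFAULT_ROWS = [
    ("Endogenous", "CD19", 10),
    ("Endogenous", "CD5", 0),
    ("Negative", "NEG_A", 3),
    ("Housekeeping", "RPL19", 500),
]


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized synthetic cohort, preprocessed, seed 0."""
    cohort = L.generate_cohort(L.SimConfig(), seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pp = preprocess_pipeline(cohort.counts, cohort.probes)
    return cohort, pp


@pytest.fixture(scope="session")
def default_signatures(default_cohort):
    cohort, pp = default_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return L.derive_signatures(pp["normalized"], cohort.sheet)
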