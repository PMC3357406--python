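"""Shared fixtures: tiny hand-built matrices and clinical tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lungdiverge.datamodel import ClinicalTable, ProbeStateMatrix


def make_annotation(positions, chromosome="chr1", probe_len=999, prefix="p"):
    """Annotation frame from 1-based start positions."""
    if isinstance(positions, dict):
        items = [(c, p) for c, pos in positions.items() for p in pos]
    else:
        items = [(chromosome, p) for p in positions]
    rows = [
        {
            "probe_id": f"{prefix}{i}",
            "chromosome": c,
            "start": int(p),
            "end": int(p) + probe_len,
        }
        for i, (c, p) in enumerate(items)
    ]
    return pd.DataFrame(rows).set_index("probe_id")


def make_state_matrix(states, positions, samples=None, chromosome="chr1"):
    """ProbeStateMatrix from a probes x samples array (NaN = missing)."""
    arr = np.asarray(states, dtype=float)
    ann = make_annotation(positions, chromosome)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ProbeStateMatrix(ann, pd.DataFrame(arr, index=ann.index, columns=samples))


def make_clinical(groups: dict[str, list[str]], **extra_cols) -> ClinicalTable:
    rows = []
    for group, samples in groups.items():
        for s in samples:
            rows.append({"sample_id": s, "subtype": group})
    table = pd.DataFrame(rows).set_index("sample_id")
    for col, values in extra_cols.items():
        table[col] = values
    return ClinicalTable(table)


@pytest.fixture
def two_group_clinical():
    """5 AC + 5 SqCC samples named a0..a4, b0..b4."""
    return make_clinical(
        {"AC": [f"a{i}" for i in range(5)], "SqCC": [f"b{i}" for i in range(5)]}
    )
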