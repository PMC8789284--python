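"""Packaged reference connectivity tables from the seed-column
reconstruction study.

Four tables are shipped as CSV fixtures: synaptic outputs of, and inputs
to, the central-column and dorsal-rim seed photoreceptors. Each file holds
the per-type, per-subtype synapse counts (the inputs to the summary
pipeline) together with the published derived percent columns (the expected
values the pipeline must reproduce to one decimal). Pooled-row labels are
normalized to ASCII ("Identified_<3", "Unidentified_>=3",
"Unidentified_<3").
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "REFERENCE_TABLES",
    "load_reference_table",
    "reference_counts",
    "PERCENT_COLUMNS",
]

REFERENCE_TABLES = {
    "central_outputs": "seed_central_outputs.csv",
    "central_inputs": "seed_central_inputs.csv",
    "dra_outputs": "seed_dra_outputs.csv",
    "dra_inputs": "seed_dra_inputs.csv",
}

PERCENT_COLUMNS = ("%R7", "%R8", "%p", "%y", "%Total", "%Total_R7", "%Total_R8")


def table_region(name: str) -> str:
    """"central" or "dra" for a reference table name."""
    if name not in REFERENCE_TABLES:
        raise KeyError(f"unknown reference table {name!r}")
    return "dra" if name.startswith("dra") else "central"


def load_reference_table(name: str) -> pd.DataFrame:
    """Full reference table (counts plus published percent columns)."""
    fname = REFERENCE_TABLES[name]
    with resources.files("medconn.data").joinpath(fname).open("r") as fh:
        return pd.read_csv(fh)


def reference_counts(name: str) -> pd.DataFrame:
    """Count columns only (Type, No., per-subtype counts), without the
    published Total row — the raw inputs to :func:`medconn.tables.summarize_counts`."""
    df = load_reference_table(name)
    sub = ["pR7", "yR7", "pR8", "yR8"] if table_region(name) == "central" else ["DRAR7", "DRAR8"]
    return df.loc[df["Type"] != "Total", ["Type", "No.", *sub]].reset_index(drop=True)
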