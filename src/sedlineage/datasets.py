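"""Bundled reference tables.

The package ships the published characteristics of the 21 surveyed
treeline lakes (three transects — Tiksi, Saskylakh, Khatanga — crossing
four vegetation types) as a plain TSV, used by the lake-summary operation
and as a realistic metadata example.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

LAKE_NUMERIC_COLUMNS = (
    "size_ha",
    "depth_m",
    "secchi_m",
    "ph",
    "conductivity",
    "hco3",
    "lai",
    "larix_pct",
)


def load_treeline_lakes() -> pd.DataFrame:
    """The 21 treeline lakes with physico-chemistry, LAI, Larix pollen % and vegetation."""
    with resources.files("sedlineage.data").joinpath("treeline_lakes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
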