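"""Packaged data: transcribed survey tables, reference panel, example catalog."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import ReferencePanel
from .regulome import CisElementCatalog


def _data_path(name: str):
    return resources.files("wrkykit").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    """The 63-row family-survey fixture (motifs, signatures, counts, groups)."""
    with resources.as_file(_data_path("table1.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_table2() -> pd.DataFrame:
    """The target-gene fixture (W-box counts and ATG-relative positions)."""
    with resources.as_file(_data_path("table2.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    df["positions"] = df["positions"].map(
        lambda s: tuple(int(x) for x in str(s).split(","))
    )
    return df


def default_panel() -> ReferencePanel:
    """The packaged subgroup-labelled reference panel (replaceable FASTA)."""
    from .io import read_panel_fasta

    with resources.as_file(_data_path("reference_panel.fasta")) as p:
        return read_panel_fasta(p)


def example_catalog() -> CisElementCatalog:
    """A small PLACE-style cis-element catalog shipped for demonstrations."""
    from .io import read_catalog_tsv

    with resources.as_file(_data_path("cis_elements.tsv")) as p:
        return CisElementCatalog(read_catalog_tsv(p))
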