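"""Packaged reference tables from the published ant-genome EVE census.

Small TSV tables shipped with the package: the survey of the 19
published ant genome assemblies screened for endogenous viral elements
(per-genome assembly size and element count), the per-clade/protein
summary of the viral phylogenies, the 16 intact elements whose lengths
are comparable to their closest exogenous viral proteins, and the
overall stop-codon (intact-ORF) counts.  They drive the desk-scale
reproduction of the census statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("evescan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_genome_survey() -> pd.DataFrame:
    """Per-genome survey: species, subfamily, accession, assembly size
    (Mb), nesting habitat, diet, and number of EVEs recovered."""
    return _load("ant_genome_survey.tsv")


def load_viral_clade_summary() -> pd.DataFrame:
    """Per viral clade and protein class: number of EVEs and of
    exogenous proteins used in the corresponding phylogeny."""
    return _load("viral_clade_summary.tsv")


def load_intact_full_length_eves() -> pd.DataFrame:
    """The 16 intact (stop-free) elements with lengths comparable to
    their most similar exogenous viral proteins."""
    return _load("intact_full_length_eves.tsv")


def load_stop_codon_summary() -> dict[str, int]:
    """Census-wide intact-ORF counts: elements without internal stops
    out of all elements recovered."""
    df = _load("stop_codon_summary.tsv")
    return {"n_intact": int(df.loc[0, "n_intact"]), "n_total": int(df.loc[0, "n_total"])}
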