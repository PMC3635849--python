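"""Bundled reference tables.

``table4_alleles.tsv`` is the published allele matrix of the 36-strain
*Persephonella hydrogeniphila* collection (six typing loci; the row for
the two strains with identical sequences at every locus is expanded to
one row per strain).  ``table6_env.tsv`` holds the end-member vent-fluid
compositions of the six sampling sites (missing / below-detection values
are blank).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mlsa_typing import AlleleTable

LOCI = ("atpA", "dnaK", "gyrB", "metG", "napA", "tkt")


def _path(name: str):
    return resources.files("ventpop") / "data" / name


def load_table4_alleles() -> pd.DataFrame:
    """Published allele numbers per strain and locus (36 strains x 6 loci)."""
    return pd.read_csv(_path("table4_alleles.tsv"), sep="\t")


def table4_allele_tables() -> dict:
    """The published allele matrix as per-locus :class:`AlleleTable` objects.

    Representative sequences are unavailable (numbers only), so the
    tables carry assignments alone.
    """
    df = load_table4_alleles()
    return {
        locus: AlleleTable(locus, dict(zip(df["strain"], df[locus].astype(int))), {})
        for locus in LOCI
    }


def load_table6_env() -> pd.DataFrame:
    """End-member vent-fluid chemistry per site (Tmax, pH, major species)."""
    return pd.read_csv(_path("table6_env.tsv"), sep="\t")
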