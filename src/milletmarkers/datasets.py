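"""Bundled per-locus validation tables.

Published marker-validation statistics for finger millet: 49 polymorphic
SSR markers scored across 10 genotypes, and 80 polymorphic SNP (KASPar)
markers scored across 89 wild and cultivated accessions.  Columns are
major allele frequency, allele number, gene diversity, observed
heterozygosity and PIC (overall and per group); group PIC is NA where a
marker is monomorphic within that group.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["ssr_validation", "snp_validation"]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("milletmarkers").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def ssr_validation() -> pd.DataFrame:
    """49 polymorphic SSR markers: MAF, allele number, gene diversity, PIC."""
    return _load("ssr_validation.tsv")


def snp_validation() -> pd.DataFrame:
    """80 polymorphic SNP markers with overall and per-group (wild /
    cultivated) PIC; NA marks group-monomorphic loci."""
    return _load("snp_validation.tsv")
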