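"""The published cyanopodovirus genome catalog and genome-size statistics.

The catalog lists the 39 marine cyanopodovirus isolates — 18 MPP-C phages
from the South China Sea plus the 21 previously sequenced MPP-A, MPP-B and
P-RSP2 phages — with clade, host, genome length, GC content, ORF count and
GenBank accession.  Genome lengths support the clade genome-size contrast
(MPP-C genomes are the smallest sequenced cyanophage genomes).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ecostats import TestResult, two_sample_ttest


def genome_catalog() -> pd.DataFrame:
    """The 39-genome cyanopodovirus catalog as a DataFrame."""
    with resources.files("podovirome.data").joinpath("cyanopodovirus_genomes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def clade_genome_sizes(catalog: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-clade genome-size summary in kb (mean, sd, n)."""
    cat = catalog if catalog is not None else genome_catalog()
    kb = cat.assign(genome_kb=cat["genome_bp"] / 1000.0)
    out = (
        kb.groupby("clade")["genome_kb"]
        .agg(mean_kb="mean", sd_kb="std", n="count")
        .reset_index()
    )
    return out.sort_values("clade", ignore_index=True)


def genome_size_contrast(
    catalog: pd.DataFrame | None = None, clade: str = "MPP-C", welch: bool = True
) -> TestResult:
    """t-test of one clade's genome lengths against all other clades."""
    cat = catalog if catalog is not None else genome_catalog()
    a = cat.loc[cat["clade"] == clade, "genome_bp"].to_numpy(dtype=float)
    b = cat.loc[cat["clade"] != clade, "genome_bp"].to_numpy(dtype=float)
    return two_sample_ttest(a, b, welch=welch)
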