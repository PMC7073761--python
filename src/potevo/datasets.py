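"""Small bundled reference tables for the human POTE gene family.

These are published annotation facts (HGNC/Ensembl gene metadata and the
marmoset BAC-screen probe coordinates), shipped so the pipeline's
examples and sanity checks run without any download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .seqio import GenomicInterval

__all__ = ["pote_gene_table", "BAC_SCREEN_PROBES", "DEFAULT_CALIBRATIONS_MYR"]


def pote_gene_table() -> pd.DataFrame:
    """The 14 human POTE paralogs: Ensembl id, symbol, group, genomic
    localization, gene size, exon count, LIR status and beta-actin
    retrogene status."""
    ref = resources.files("potevo") / "resources" / "pote_genes.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


# Hybridization probes used to screen the marmoset CHORI-259 BAC library
# for POTE loci, on the calJac3 assembly (1-based inclusive coordinates).
# STS1 spans the first exon-intron junction, STS2 the eighth
# intron-exon junction.
BAC_SCREEN_PROBES: dict[str, GenomicInterval] = {
    "STS1": GenomicInterval(chrom="chr16", start=10145382, end=10145806),
    "STS2": GenomicInterval(chrom="chr16", start=10127122, end=10127552),
}

# Great-ape calibration split times (Myr) used for clock dating.
DEFAULT_CALIBRATIONS_MYR: dict[tuple[str, str], float] = {
    ("human", "chimpanzee"): 6.0,
    ("human", "orangutan"): 16.0,
}
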