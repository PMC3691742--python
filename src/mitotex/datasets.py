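"""Packaged reference tables for the MED whitefly mitogenome.

``med_annotation.tsv`` is the published 37-gene annotation (plus the two
putative control regions CR1/CR2) of the 15,632 bp Mediterranean *Bemisia
tabaci* mitogenome; ``med_snps.tsv`` is the published 8-SNP table.  The
deposited genome sequence itself is not redistributed here;
:func:`med_like_genome` builds a synthetic genome on the same geometry whose
annotated codons and published SNP codon contexts are honored, so coordinate
and codon arithmetic can be exercised without a download.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .genome_model import AnnotationTable, MitoGenome, parse_annotation_text
from .simulate import SimulationConfig, SyntheticTruth, generate_genome

__all__ = ["MED_GENOME_LENGTH", "load_med_annotation", "load_med_snps", "med_like_genome"]

MED_GENOME_LENGTH = 15632

# codon contexts printed for the five coding SNPs: (gene, codon index, codon)
_TABLE_CODON_PLANTS = [
    ("cox1", 328, "ATG"),
    ("cox2", 91, "GAA"),
    ("nd5", 42, "GGA"),
    ("cytb", 41, "GTC"),
    ("nd2", 66, "ACG"),
]
# reference bases at the three control-region SNP positions
_CR_REF_BASES = {14011: "A", 14090: "G", 14180: "A"}


def _data_text(name: str) -> str:
    return files("mitotex").joinpath("data", name).read_text()


def load_med_annotation() -> AnnotationTable:
    """The published MED mitogenome annotation as an AnnotationTable."""
    return parse_annotation_text(_data_text("med_annotation.tsv"), MED_GENOME_LENGTH)


def load_med_snps() -> pd.DataFrame:
    """The published 8-SNP table (coding rows carry codon/aa columns)."""
    import io

    return pd.read_csv(io.StringIO(_data_text("med_snps.tsv")), sep="\t", dtype=str)


def med_like_genome(seed: int = 0) -> tuple[MitoGenome, AnnotationTable, SyntheticTruth]:
    """A synthetic genome on the MED layout honoring the published SNP codons.

    Synthetic stand-in for the deposited genome: sequence is random apart
    from annotated start/stop codons, the codon contexts of the five coding
    SNPs, and the reference bases at the three control-region SNP positions.
    """
    config = SimulationConfig(
        seed=seed,
        codon_plants=list(_TABLE_CODON_PLANTS),
        base_plants=dict(_CR_REF_BASES),
        genome_id="med_like_synthetic",
    )
    return generate_genome(config)
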