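"""Packaged fixtures: the study-shaped phyletic pattern and the 18-nt
homing-endonuclease recognition site."""

from __future__ import annotations

from importlib import resources

from .phylo_io import PhyleticPattern, read_fasta_sequence, read_pattern


def _data_path(name: str):
    return resources.files("intron_turnover") / "data" / name


def load_study_pattern(character: str = "intron") -> PhyleticPattern:
    """Phyletic pattern of the 29-strain yeast complex.

    ``character="intron"`` gives all 29 taxa; ``character="heg"`` gives the
    22 intron-containing taxa (HEG is undefined — NA — where the intron is
    absent).
    """
    with resources.as_file(_data_path("saccharomyces_complex.tsv")) as p:
        return read_pattern(p, character)


def load_recognition_site() -> str:
    """The 18-nt exon sequence the intron-encoded endonuclease cleaves."""
    with resources.as_file(_data_path("heg_recognition_site.fasta")) as p:
        _, seq = read_fasta_sequence(p)
    return seq
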