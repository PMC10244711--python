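"""In-silico genotyping of the G51D knock-in allele.

The G51D edit changes the rat alpha-synuclein Gly-51 codon GGA to GAT
(2 bp), creating a BspHI recognition site (TCATGA, palindromic) in exon 3,
so a PCR product spanning the codon is cut if and only if the mutant allele
is present.  This module provides restriction-site scanning, linear digest
arithmetic, Hamming distance, genotype calling from cut/uncut patterns, and
a Mendelian-ratio chi-square test; the guide RNA and the 80-nt single-strand
donor oligonucleotide ship as a FASTA fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio import SeqIO
from scipy import stats as sps

from .tac import ValidationError

__all__ = [
    "BSPHI_SITE",
    "BSPHI_CUT_OFFSET",
    "SequenceRecord",
    "DigestResult",
    "find_sites",
    "digest",
    "hamming",
    "mendelian_chisq",
    "call_genotype",
    "load_reference_sequences",
    "read_fasta",
    "write_fasta",
]

#: BspHI recognition sequence (T^CATGA); its own reverse complement, so
#: single-strand scanning suffices.
BSPHI_SITE = "TCATGA"
#: Cut position within the site (after the leading T), standard enzyme datum.
BSPHI_CUT_OFFSET = 1

_DNA = set("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """Named DNA sequence over A/C/G/T; case is preserved but ignored."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError("sequence must be non-empty")
        bad = set(self.sequence.upper()) - _DNA
        if bad:
            raise ValidationError(f"invalid DNA characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestResult:
    cut_positions: tuple
    fragment_lengths: tuple


def find_sites(seq: SequenceRecord | str, recognition: str) -> list[int]:
    """0-based start positions of all (possibly overlapping) matches of the
    recognition sequence on the given strand, case-insensitive."""
    s = (seq.sequence if isinstance(seq, SequenceRecord) else seq).upper()
    if isinstance(seq, str):
        SequenceRecord("query", seq)  # validate alphabet
    if not recognition:
        raise ValidationError("recognition sequence must be non-empty")
    SequenceRecord("recognition", recognition)
    rec = recognition.upper()
    return [i for i in range(len(s) - len(rec) + 1) if s[i : i + len(rec)] == rec]


def digest(
    seq: SequenceRecord | str, recognition: str, cut_offset: int = BSPHI_CUT_OFFSET
) -> DigestResult:
    """Fragment lengths of a linear sequence cut at site start + offset."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if not 0 <= cut_offset <= len(recognition):
        raise ValidationError("cut_offset must lie within the recognition sequence")
    sites = find_sites(seq, recognition)
    cuts = sorted({p + cut_offset for p in sites if 0 < p + cut_offset < len(s)})
    bounds = [0, *cuts, len(s)]
    fragments = tuple(b - a for a, b in zip(bounds[:-1], bounds[1:]))
    return DigestResult(cut_positions=tuple(cuts), fragment_lengths=fragments)


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings
    (case-insensitive)."""
    if len(a) != len(b):
        raise ValidationError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a.upper(), b.upper()))


def mendelian_chisq(counts, ratio=(1, 2, 1)) -> dict:
    """Pearson chi-square of observed (n_WT, n_het, n_hom) litter counts
    against an expected Mendelian ratio (default 1:2:1)."""
    obs = np.asarray(counts, dtype=float)
    if obs.size != len(ratio):
        raise ValidationError("counts and ratio must have the same length")
    if np.any(obs < 0):
        raise ValidationError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValidationError("total count must be > 0")
    expected = total * np.asarray(ratio, dtype=float) / sum(ratio)
    chi2, p = sps.chisquare(obs, expected)
    return {"chi2": float(chi2), "df": obs.size - 1, "p": float(p)}


def call_genotype(amplicon: SequenceRecord | str, other_allele=None) -> str:
    """Cut/uncut genotype call for one amplicon (or an allele pair).

    The mutant allele carries the BspHI site and is cut; the WT allele is
    not.  With two alleles, presence of both cut and uncut products reads as
    heterozygous (band-intensity modelling is out of scope).
    """
    alleles = [amplicon] if other_allele is None else [amplicon, other_allele]
    cut = [len(find_sites(a, BSPHI_SITE)) > 0 for a in alleles]
    if all(cut):
        return "G51D/G51D"
    if not any(cut):
        return "WT"
    return "G51D/+"


def read_fasta(path) -> list[SequenceRecord]:
    return [SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.sequence}\n")


def load_reference_sequences() -> dict:
    """The guide RNA and 80-nt ssDNA donor shipped with the package,
    keyed by record name (``gRNA``, ``ssDNA_donor``)."""
    with resources.files("fdopakin.data").joinpath("g51d_sequences.fasta").open() as fh:
        return {r.id: SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta")}
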