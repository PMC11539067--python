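"""Sequence utilities for frameshift-allele characterisation.

The mutant alleles of interest are (i) a splice-site allele producing a
protein shortened by a known number of residues, and (ii) a
CRISPR-generated four-nucleotide deletion causing a frameshift and a
premature stop codon. These helpers apply deletions to a coding
sequence, translate to the first in-frame stop, and do the truncation
arithmetic. Coordinates are 0-based, end-exclusive; standard genetic
code only.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = [
    "apply_deletion",
    "translate_to_stop",
    "truncation_length",
    "TranslationResult",
]

_VALID = set("ACGT")


@dataclass(frozen=True)
class TranslationResult:
    n_residues: int
    stop_found: bool

    def __int__(self) -> int:
        return self.n_residues


def apply_deletion(cds: str, pos: int, n: int) -> str:
    """Remove ``n`` bases at 0-based position ``pos``."""
    if n < 0 or pos < 0 or pos + n > len(cds):
        raise ValueError(f"deletion [{pos}, {pos + n}) out of range for "
                         f"sequence of length {len(cds)}")
    return cds[:pos] + cds[pos + n:]


def translate_to_stop(cds: str) -> TranslationResult:
    """Number of residues translated before the first in-frame stop.

    The count includes the initiator methionine. If no stop codon occurs
    in frame, the full-length residue count is returned with
    ``stop_found=False``. Trailing bases short of a codon are ignored.
    """
    cds = cds.upper()
    if not set(cds) <= _VALID:
        raise ValueError("CDS must contain only A, C, G, T")
    if not cds.startswith("ATG"):
        raise ValueError("CDS must start with ATG")
    trimmed = cds[: len(cds) - len(cds) % 3]
    full = str(Seq(trimmed).translate())
    stop = full.find("*")
    if stop < 0:
        return TranslationResult(n_residues=len(full), stop_found=False)
    return TranslationResult(n_residues=stop, stop_found=True)


def truncation_length(full_length_aa: int, aa_lost: int) -> int:
    """Residues remaining after losing ``aa_lost`` from the C-terminus."""
    if aa_lost < 0 or aa_lost > full_length_aa:
        raise ValueError("aa_lost must lie in [0, full_length_aa]")
    return full_length_aa - aa_lost
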