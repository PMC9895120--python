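"""Small shared helpers: rounding and nucleotide alphabet conversions.

Site keys follow the field convention ``{precursor}_{position}_{REF}_{alt}``
with the reference nucleotide in upper-case RNA letters and the alternative
in lower-case RNA letters (``u`` rather than ``t``), e.g.
``hsa-mir-376a-1_9_A_g`` for an A-to-I site at hairpin position 9.
"""

from __future__ import annotations

import math

_TO_RNA = str.maketrans("Tt", "Uu")
_TO_DNA = str.maketrans("Uu", "Tt")
_COMPLEMENT_DNA = str.maketrans("ACGTacgt", "TGCAtgca")

DNA_ALPHABET = "ACGT"
RNA_ALPHABET = "ACGU"


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up.

    Used wherever a fractional weighted count must become an integer count
    (binomial test sizes, the cohort retention threshold).
    """
    return int(math.floor(x + 0.5))


def rna_upper(nt: str) -> str:
    """Upper-case RNA spelling of a nucleotide (T becomes U)."""
    return nt.upper().translate(_TO_RNA)


def rna_lower(nt: str) -> str:
    """Lower-case RNA spelling of a nucleotide (t becomes u)."""
    return nt.lower().translate(_TO_RNA)


def dna_upper(nt: str) -> str:
    """Upper-case DNA spelling of a nucleotide (U becomes T)."""
    return nt.upper().translate(_TO_DNA)


def complement_dna(seq: str) -> str:
    return seq.translate(_COMPLEMENT_DNA)


def make_site_key(locus_id: str, position: int, ref_nt: str, alt_nt: str) -> str:
    return f"{locus_id}_{position}_{rna_upper(ref_nt)}_{rna_lower(alt_nt)}"


def parse_site_key(key: str) -> tuple[str, int, str, str]:
    """Split a site key into (locus id, position, REF, alt).

    The locus id may itself contain underscores, so the key is split from
    the right.
    """
    try:
        locus, pos, ref, alt = key.rsplit("_", 3)
        position = int(pos)
    except ValueError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unparseable site key: {key!r}") from exc
    if position < 1 or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"unparseable site key: {key!r}")
    return locus, position, rna_upper(ref), rna_lower(alt)
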