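"""Nine-way categorisation of retained M/E sites and their annotations.

Every retained site is assigned exactly one of nine categories:

``SNP``       a known genomic variant (position + alleles match a variant
              record and the site is fully edited in at least one sample),
``Pseudo``    a site whose alternative reads are majority-attributed to
              another locus by cross-mapping correction (> 0.5 of the
              alt read mass elsewhere),
``3'-A`` / ``3'-U`` / ``3'-Other``
              untemplated additions past the mature 3' end,
``5'``        a site at or before the mature 5' start,
``A-to-I``    a central A->g substitution (ADAR deamination; inosine is
              read as guanosine),
``C-to-U``    a central C->u substitution (APOBEC deamination),
``Other``     any other central substitution (e.g. U->g).

The decision order is SNP, Pseudo, 3', 5', central — so a fully edited
variant never masquerades as editing, and a cross-mapping artifact never
reaches the nucleotide-change rules. Auxiliary annotations record seed
membership (mature positions 2-8), cross-species conservation and the
immediate 5'/3' neighbour nucleotides (A-to-I sites favour a 5' U and a
3' G; C-to-U sites sit in C_C context).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import Mature, PreMiRNA
from .errors import ClassificationError, ParameterError
from .sitecall import CombinedSite
from .util import complement_dna, dna_upper, parse_site_key, rna_upper

CATEGORIES = (
    "3'-A",
    "3'-U",
    "3'-Other",
    "5'",
    "A-to-I",
    "C-to-U",
    "Other",
    "Pseudo",
    "SNP",
)

TAIL_WINDOW = 5  # 3' sites classify up to mature_end + TAIL_WINDOW
SEED_RANGE = (2, 8)  # mature-relative positions of the seed region


@dataclass(frozen=True)
class VariantRecord:
    """A known genomic variant (dbSNP-style subset)."""

    chrom: str
    position: int  # 1-based genomic
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self) -> None:
        for allele in (self.ref, self.alt):
            if allele.upper() not in "ACGT" or len(allele) != 1:
                raise ParameterError(f"alleles must be single A/C/G/T, got {allele!r}")


@dataclass(frozen=True)
class CrossSpeciesSite:
    """An editing site reported in another species, in mature coordinates."""

    species: str
    mature_name: str
    position: int  # 1-based within the mature miRNA
    editing_type: str  # "A-to-I" | "C-to-U"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ParameterError("mature-relative position must be >= 1")
        if self.editing_type not in ("A-to-I", "C-to-U"):
            raise ParameterError(f"unknown editing type {self.editing_type!r}")


@dataclass
class SiteAnnotation:
    key: str
    category: str
    is_snp: bool = False
    is_conserved: bool = False
    in_seed: bool = False
    context5: str | None = None  # immediate 5' neighbour, upper-case RNA
    context3: str | None = None
    mature_name: str | None = None
    mature_relative_position: int | None = None


def resolve_mature(hairpin: PreMiRNA, position: int) -> Mature:
    """Pick the mature annotation a hairpin position belongs to.

    Preference order: a mature containing the position, then one whose 3'
    tail window (end + 5) covers it, then the nearest mature downstream of
    the position (a 5' site). Positions beyond every window raise a
    classification error.
    """
    if not hairpin.matures:
        raise ClassificationError(f"hairpin {hairpin.id} has no mature annotation")
    for m in hairpin.matures:
        if m.start <= position <= m.end:
            return m
    tail_hits = [m for m in hairpin.matures if m.end < position <= m.end + TAIL_WINDOW]
    if tail_hits:
        return max(tail_hits, key=lambda m: m.end)
    upstream = [m for m in hairpin.matures if position <= m.start]
    if upstream:
        return min(upstream, key=lambda m: m.start)
    raise ClassificationError(
        f"position {position} of {hairpin.id} is outside every mature window"
    )


def in_seed(position: int, mature: Mature) -> bool:
    """True when the hairpin position maps to mature positions 2-8."""
    rel = position - mature.start + 1
    return SEED_RANGE[0] <= rel <= SEED_RANGE[1]


def classify_site(
    site: CombinedSite | str,
    hairpin: PreMiRNA,
    *,
    mature: Mature | None = None,
    cross_map_fraction: float | None = None,
    is_snp: bool = False,
) -> SiteAnnotation:
    """Assign one of the nine categories to a retained site.

    ``site`` may be a CombinedSite (its pooled cross-mapping fraction is
    used unless overridden) or a bare site key.
    """
    if isinstance(site, str):
        key = site
        cmf = cross_map_fraction or 0.0
    else:
        key = site.key
        cmf = site.cross_map_fraction if cross_map_fraction is None else cross_map_fraction
    locus, position, ref, alt = parse_site_key(key)
    if locus != hairpin.id:
        raise ClassificationError(f"site {key} does not belong to hairpin {hairpin.id}")
    ext = hairpin.extended
    if position > len(ext):
        raise ClassificationError(f"position {position} beyond hairpin+flank of {locus}")
    m = mature if mature is not None else resolve_mature(hairpin, position)
    if position > m.end + TAIL_WINDOW:
        raise ClassificationError(
            f"position {position} beyond the 3' window of mature {m.name}"
        )

    if is_snp:
        category = "SNP"
    elif cmf > 0.5:
        category = "Pseudo"
    elif position > m.end:
        category = {"a": "3'-A", "u": "3'-U"}.get(alt, "3'-Other")
    elif position <= m.start:
        category = "5'"
    elif ref == "A" and alt == "g":
        category = "A-to-I"
    elif ref == "C" and alt == "u":
        category = "C-to-U"
    else:
        category = "Other"

    context5 = rna_upper(ext[position - 2]) if position >= 2 else (
        rna_upper(hairpin.flank5[-1]) if hairpin.flank5 else None
    )
    context3 = rna_upper(ext[position]) if position < len(ext) else None
    inside = m.start <= position <= m.end
    return SiteAnnotation(
        key=key,
        category=category,
        is_snp=is_snp,
        in_seed=inside and in_seed(position, m),
        context5=context5,
        context3=context3,
        mature_name=m.name,
        mature_relative_position=(position - m.start + 1) if inside else None,
    )


def match_snp(
    site: CombinedSite,
    variants: Sequence[VariantRecord],
    hairpin_genomic_location: tuple[str, int, str],
) -> bool:
    """Does the site coincide with a known variant and reach full editing?

    All three conditions must hold: same genomic position as a variant,
    same ref/alt alleles (strand-aware: alleles are complemented for
    minus-strand hairpins), and an editing level of 100% in at least one
    sample. ``hairpin_genomic_location`` is (chrom, genomic coordinate of
    hairpin position 1, strand).
    """
    chrom, origin, strand = hairpin_genomic_location
    if strand not in ("+", "-"):
        raise ParameterError(f"strand must be '+' or '-', got {strand!r}")
    if site.max_level < 1.0 - 1e-9:
        return False
    if strand == "+":
        gpos = origin + site.position - 1
        ref_dna = dna_upper(site.ref)
        alt_dna = dna_upper(site.alt)
    else:
        gpos = origin - (site.position - 1)
        ref_dna = complement_dna(dna_upper(site.ref))
        alt_dna = complement_dna(dna_upper(site.alt))
    return any(
        v.chrom == chrom
        and v.position == gpos
        and v.ref.upper() == ref_dna
        and v.alt.upper() == alt_dna
        for v in variants
    )


def flag_conserved(
    annotation: SiteAnnotation,
    mature: Mature,
    cross_sites: Iterable[CrossSpeciesSite],
) -> bool:
    """True when another species reports the same editing type at the same
    mature-relative position (so at least two species share the site).

    Sites outside a mature miRNA, or of a non-deamination category, are
    never conserved by this definition.
    """
    if annotation.category not in ("A-to-I", "C-to-U"):
        return False
    _, position, _, _ = parse_site_key(annotation.key)
    if not mature.start <= position <= mature.end:
        return False
    rel = position - mature.start + 1
    return any(
        cs.position == rel and cs.editing_type == annotation.category
        for cs in cross_sites
    )


def context_preference(
    annotations: Sequence[SiteAnnotation],
    hairpins: Sequence[PreMiRNA] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Neighbour-nucleotide counts and frequencies for a set of sites.

    Returns (counts, frequencies, n_excluded): 4x2 tables with rows
    A/C/G/U and columns "5'"/"3'"; frequency columns sum to 1. Sites
    missing a neighbour (hairpin terminus without flank) are excluded and
    counted. ``hairpins`` is accepted for API symmetry; contexts are read
    from the annotations, which already resolved them.
    """
    del hairpins
    nts = list("ACGU")
    counts = pd.DataFrame(0, index=pd.Index(nts, name="nucleotide"), columns=["5'", "3'"])
    excluded = 0
    for ann in annotations:
        if ann.context5 in nts and ann.context3 in nts:
            counts.loc[ann.context5, "5'"] += 1
            counts.loc[ann.context3, "3'"] += 1
        else:
            excluded += 1
    totals = counts.sum(axis=0)
    freq = counts / totals.replace(0, pd.NA) if (totals > 0).any() else counts.astype(float)
    freq = freq.fillna(0.0).astype(float)
    return counts, freq, excluded
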