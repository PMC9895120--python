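"""Hand-built worked examples shared by the test suite and the
acceptance script.

``nine_category_sites`` enumerates one site per classification category
on a single synthetic hairpin, together with the variant table and
genomic location needed for the SNP branch, and the expected category of
every site. It is the classification oracle: a correct classifier must
agree 9/9 with the hand-written truth.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import Mature, PreMiRNA
from .classify import VariantRecord
from .sitecall import CombinedSite, SampleSiteStat
from .util import make_site_key


@dataclass
class NineCategoryFixture:
    hairpin: PreMiRNA
    sites: list[CombinedSite]
    expected: dict[str, str]  # site key -> category
    variants: list[VariantRecord]
    genomic_location: tuple[str, int, str]  # of hairpin position 1


def _site(
    hairpin: PreMiRNA,
    position: int,
    alt: str,
    *,
    level: float = 0.3,
    cross_map_fraction: float = 0.0,
) -> CombinedSite:
    ref = hairpin.extended[position - 1]
    key = make_site_key(hairpin.id, position, ref, alt)
    stat = SampleSiteStat(level=level, support_rptm=50.0, significant=True)
    return CombinedSite(
        key=key,
        locus_id=hairpin.id,
        position=position,
        ref=ref.replace("T", "U"),
        alt=alt,
        per_sample={"s1": stat},
        n_significant=1,
        retained=True,
        cross_map_fraction=cross_map_fraction,
        max_level=level,
    )


def nine_category_sites() -> NineCategoryFixture:
    """One hand-crafted site per category on a 70-nt hairpin.

    The mature 5p arm spans positions 10-31; positions 32-34 fall in the
    3' tail window; position 5 precedes the mature start. The SNP site is
    fully edited (level 1.0) and matches a variant record on the plus
    strand at genomic origin 1000.
    """
    seq = list(("ACGT" * 18)[:70])
    placements = {5: "G", 15: "A", 18: "C", 21: "T", 24: "A", 27: "A",
                  32: "G", 33: "C", 34: "A"}
    for pos, nt in placements.items():
        seq[pos - 1] = nt
    hairpin = PreMiRNA(
        id="ex-mir-1",
        sequence="".join(seq),
        matures=[Mature("ex-mir-1-5p", "5p", 10, 31)],
        flank3="ACGTACGTAC",
        flank5="TTTTTTTTTT",
    )

    sites = [
        _site(hairpin, 5, "a"),                               # 5'
        _site(hairpin, 15, "g"),                              # A-to-I
        _site(hairpin, 18, "u"),                              # C-to-U
        _site(hairpin, 21, "g"),                              # Other (U->g)
        _site(hairpin, 24, "g", level=1.0),                   # SNP
        _site(hairpin, 27, "g", cross_map_fraction=0.8),      # Pseudo
        _site(hairpin, 32, "a"),                              # 3'-A
        _site(hairpin, 33, "u"),                              # 3'-U
        _site(hairpin, 34, "c"),                              # 3'-Other
    ]
    expected = {
        sites[0].key: "5'",
        sites[1].key: "A-to-I",
        sites[2].key: "C-to-U",
        sites[3].key: "Other",
        sites[4].key: "SNP",
        sites[5].key: "Pseudo",
        sites[6].key: "3'-A",
        sites[7].key: "3'-U",
        sites[8].key: "3'-Other",
    }
    origin = 1000  # genomic coordinate of hairpin position 1, plus strand
    variants = [VariantRecord(chrom="chr1", position=origin + 24 - 1, ref="A", alt="G", id="rs_ex1")]
    return NineCategoryFixture(
        hairpin=hairpin,
        sites=sites,
        expected=expected,
        variants=variants,
        genomic_location=("chr1", origin, "+"),
    )
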