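"""End-to-end orchestration: reads in, annotated cohort results out.

Glue over the stage modules so tests, the command-line interface and the
validation experiments run the same path: preprocess -> align ->
cross-mapping correction -> pileup -> per-sample calls -> combination ->
classification -> cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import io
from .align import Alignment, align_to_premirnas, cross_map_correct
from .classify import (
    CrossSpeciesSite,
    SiteAnnotation,
    VariantRecord,
    classify_site,
    flag_conserved,
    match_snp,
    resolve_mature,
)
from .cohort import ComparisonResult, CorrelationResult, run_cohort_analysis
from .errors import ClassificationError
from .preprocess import UniqueRead, preprocess_reads
from .simulate import ReferenceSet
from .sitecall import (
    CombinedSite,
    EditingSiteCall,
    Pileup,
    build_pileup,
    call_sites,
    combine_samples,
)


@dataclass
class SampleResult:
    sample_id: str
    unique_reads: list[UniqueRead]
    alignments: list[Alignment]
    pileup: Pileup
    calls: list[EditingSiteCall]
    library_total: int


@dataclass
class StudyResult:
    samples: dict[str, SampleResult]
    combined: list[CombinedSite]
    annotations: dict[str, SiteAnnotation] = field(default_factory=dict)
    level_matrix: pd.DataFrame | None = None
    correlations: dict[str, list[CorrelationResult]] | None = None
    comparisons: list[ComparisonResult] | None = None

    @property
    def retained(self) -> list[CombinedSite]:
        return [s for s in self.combined if s.retained]


def process_sample(
    reads: Sequence[tuple[str, str, str]] | Sequence[tuple[str, str]],
    ref: ReferenceSet,
    *,
    sample_id: str = "sample",
    adapter: str | None = None,
    min_len: int = 18,
    min_phred: int = 30,
    max_mismatches: int = 2,
    max_tail: int = 3,
    phred_threshold: int = 30,
    min_level: float = 0.05,
    min_support_rptm: float = 10.0,
    alpha: float = 0.05,
) -> SampleResult:
    """Run one library through preprocessing, alignment and site calling."""
    uniques, library_total = preprocess_reads(
        reads, adapter=adapter, min_len=min_len, min_phred=min_phred
    )
    if library_total == 0:
        return SampleResult(sample_id, [], [], Pileup(), [], 0)
    alignments = align_to_premirnas(
        uniques, ref.pre_mirnas, decoys=ref.decoy_loci,
        max_mismatches=max_mismatches, max_tail=max_tail,
    )
    alignments = cross_map_correct(alignments)
    pileup = build_pileup(alignments)
    calls = call_sites(
        pileup, library_total, phred_threshold=phred_threshold,
        min_level=min_level, min_support_rptm=min_support_rptm, alpha=alpha,
    )
    return SampleResult(sample_id, uniques, alignments, pileup, calls, library_total)


def annotate_sites(
    sites: Sequence[CombinedSite],
    ref: ReferenceSet,
    *,
    variants: Sequence[VariantRecord] = (),
    genomic_locations: Mapping[str, tuple[str, int, str]] | None = None,
    cross_sites: Sequence[CrossSpeciesSite] = (),
) -> dict[str, SiteAnnotation]:
    """Classify retained hairpin sites; decoy-locus sites are skipped.

    SNP matching runs only for hairpins with a known genomic location.
    """
    known = {pm.id for pm in ref.pre_mirnas}
    out: dict[str, SiteAnnotation] = {}
    for site in sites:
        if not site.retained or site.locus_id not in known:
            continue
        hairpin = ref.hairpin(site.locus_id)
        is_snp = False
        if genomic_locations and site.locus_id in genomic_locations and variants:
            is_snp = match_snp(site, variants, genomic_locations[site.locus_id])
        try:
            ann = classify_site(site, hairpin, is_snp=is_snp)
        except ClassificationError:
            continue
        if cross_sites and ann.category in ("A-to-I", "C-to-U"):
            mature = resolve_mature(hairpin, site.position)
            ann.is_conserved = flag_conserved(ann, mature, cross_sites)
        out[site.key] = ann
    return out


def run_study(
    sample_reads: Mapping[str, Sequence[tuple[str, str, str]]],
    ref: ReferenceSet,
    *,
    design: pd.DataFrame | None = None,
    min_frac: float = 0.10,
    subgroup_max_age: float | None = None,
    variants: Sequence[VariantRecord] = (),
    genomic_locations: Mapping[str, tuple[str, int, str]] | None = None,
    cross_sites: Sequence[CrossSpeciesSite] = (),
    **sample_kwargs,
) -> StudyResult:
    """Process every sample, combine, classify and (optionally) run the
    cohort statistics when a design table is supplied."""
    samples = {
        sid: process_sample(reads, ref, sample_id=sid, **sample_kwargs)
        for sid, reads in sorted(sample_reads.items())
    }
    combined = combine_samples(
        {sid: res.calls for sid, res in samples.items()}, min_frac=min_frac
    )
    result = StudyResult(samples=samples, combined=combined)
    result.annotations = annotate_sites(
        result.retained, ref, variants=variants,
        genomic_locations=genomic_locations, cross_sites=cross_sites,
    )
    result.level_matrix = io.combined_to_level_matrix(combined)
    if design is not None and len(result.level_matrix):
        result.correlations, result.comparisons = run_cohort_analysis(
            result.level_matrix, design, subgroup_max_age=subgroup_max_age
        )
    return result
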