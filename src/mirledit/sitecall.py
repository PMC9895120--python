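"""Per-position pileups, per-sample site calls, cross-sample combination.

A mutation/editing (M/E) site candidate is any hairpin position where
aligned reads carry a nucleotide that differs from the reference. Each
candidate is tested against a sequencing-error null: under Phred quality q
the per-base error probability is 10^(-q/10), and the probability of
observing at least the seen number of alternative reads by chance is the
binomial upper tail at that rate. P-values are Benjamini-Hochberg
corrected across all candidates of the sample. A candidate is significant
when simultaneously

* its editing level (alt / coverage) is at least 5%,
* its support is at least 10 reads per ten million sequencing tags, and
* its BH-adjusted p-value is below 0.05.

Samples are then combined: a site is retained for cohort analysis when it
is significant in at least 10% of the samples, with the threshold rounded
half-up (0.10 x 131 samples -> 13) and floored at one sample.

The error null directs the whole per-base error rate at the specific
alternative nucleotide (conservative); pass ``error_split_three=True`` to
divide it equally over the three non-reference nucleotides instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from scipy import stats

from .align import Alignment
from .cohort import bh_correct
from .errors import InputError, ParameterError
from .util import make_site_key, parse_site_key, round_half_up, rna_lower, rna_upper


@dataclass
class PositionPile:
    """Nucleotide counters at one (locus, position).

    ``weighted`` accumulates read count x cross-mapping weight and drives
    levels and tests; ``raw`` accumulates unweighted counts and is kept so
    the fraction of support attributed away by cross-mapping can be
    measured (the basis of the Pseudo category).
    Keys are upper-case RNA for reference support and lower-case RNA for
    each alternative nucleotide.
    """

    ref: str
    weighted: dict[str, float] = field(default_factory=dict)
    raw: dict[str, float] = field(default_factory=dict)

    def add(self, nt: str, weighted: float, raw: float) -> None:
        self.weighted[nt] = self.weighted.get(nt, 0.0) + weighted
        self.raw[nt] = self.raw.get(nt, 0.0) + raw

    @property
    def coverage(self) -> float:
        return sum(self.weighted.values())


@dataclass
class Pileup:
    positions: dict[tuple[str, int], PositionPile] = field(default_factory=dict)

    def pile(self, locus: str, position: int, ref: str) -> PositionPile:
        key = (locus, position)
        entry = self.positions.get(key)
        if entry is None:
            entry = self.positions[key] = PositionPile(ref=ref)
        return entry

    def __len__(self) -> int:
        return len(self.positions)


class SampleSiteStat(NamedTuple):
    level: float
    support_rptm: float
    significant: bool


@dataclass
class EditingSiteCall:
    """A per-sample M/E site candidate with its level, support and test."""

    key: str
    locus_id: str
    position: int
    ref: str
    alt: str
    level: float
    support_raw: float  # weighted alternative read count
    support_raw_unweighted: float
    support_rptm: float
    coverage: float
    p_value: float
    q_value: float
    significant: bool

    @property
    def cross_map_fraction(self) -> float:
        """Fraction of the alternative read mass attributed to other loci."""
        if self.support_raw_unweighted <= 0:
            return 0.0
        return 1.0 - self.support_raw / self.support_raw_unweighted


@dataclass
class CombinedSite:
    """A site across samples with its retention decision."""

    key: str
    locus_id: str
    position: int
    ref: str
    alt: str
    per_sample: dict[str, SampleSiteStat]
    n_significant: int
    retained: bool
    cross_map_fraction: float
    max_level: float


def build_pileup(alignments: Iterable[Alignment]) -> Pileup:
    """Accumulate weighted and raw nucleotide counts per hairpin position.

    Every aligned body base contributes raw_count x weight to the counter
    matching its nucleotide; tail bases contribute at their post-body
    positions, as reference support when they match the template and as
    alternative support when they do not.
    """
    pileup = Pileup()
    for a in alignments:
        c = float(a.read.raw_count)
        w = a.weight * c
        mism = {pos: (ref, alt) for pos, ref, alt in a.mismatches}
        for i in range(a.body_length):
            pos = a.start + i
            hit = mism.get(pos)
            if hit is None:
                ref = rna_upper(a.read.sequence[i])
                pileup.pile(a.locus_id, pos, ref).add(ref, w, c)
            else:
                ref, alt = hit
                pileup.pile(a.locus_id, pos, ref).add(alt, w, c)
        for pos, ref, alt in a.tail:
            pile = pileup.pile(a.locus_id, pos, ref)
            if rna_upper(alt) == ref:
                pile.add(ref, w, c)
            else:
                pile.add(alt, w, c)
    return pileup


def binomial_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0); the sequencing-error null."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return float(stats.binom.sf(k - 1, n, p0))


def call_sites(
    pileup: Pileup,
    library_total: int,
    phred_threshold: int = 30,
    min_level: float = 0.05,
    min_support_rptm: float = 10.0,
    alpha: float = 0.05,
    *,
    error_split_three: bool = False,
) -> list[EditingSiteCall]:
    """Test every observed alternative nucleotide against the error null.

    Fractional weighted counts are rounded half-up to integers for the
    binomial test; BH correction runs over all candidates of this sample.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if library_total < 1:
        raise ParameterError("library_total must be at least 1")
    p0 = 10.0 ** (-phred_threshold / 10.0)
    if error_split_three:
        p0 /= 3.0

    calls: list[EditingSiteCall] = []
    for (locus, position), pile in sorted(pileup.positions.items()):
        coverage = pile.coverage
        n = round_half_up(coverage)
        for nt, alt_w in sorted(pile.weighted.items()):
            if nt == pile.ref or alt_w <= 0:
                continue
            k = round_half_up(alt_w)
            level = alt_w / coverage
            calls.append(
                EditingSiteCall(
                    key=make_site_key(locus, position, pile.ref, nt),
                    locus_id=locus,
                    position=position,
                    ref=pile.ref,
                    alt=rna_lower(nt),
                    level=level,
                    support_raw=alt_w,
                    support_raw_unweighted=pile.raw.get(nt, 0.0),
                    support_rptm=alt_w * 1e7 / library_total,
                    coverage=coverage,
                    p_value=binomial_tail(k, n, p0),
                    q_value=1.0,
                    significant=False,
                )
            )

    if calls:
        qvals = bh_correct([c.p_value for c in calls])
        for c, q in zip(calls, qvals):
            c.q_value = float(q)
            c.significant = (
                c.level >= min_level
                and c.support_rptm >= min_support_rptm
                and c.q_value < alpha
            )
    return calls


def retention_threshold(n_samples: int, min_frac: float = 0.10) -> int:
    """Samples a site must be significant in to be retained.

    Round-half-up of ``min_frac x n_samples`` with a floor of one sample:
    10% of 131 samples gives 13.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be at least 1")
    return max(1, round_half_up(min_frac * n_samples))


def combine_samples(
    per_sample_calls: Mapping[str, list[EditingSiteCall]]
    | Iterable[tuple[str, list[EditingSiteCall]]],
    n_samples: int | None = None,
    min_frac: float = 0.10,
) -> list[CombinedSite]:
    """Union per-sample calls into cohort-level sites with retention flags.

    Samples where a site was not even a candidate contribute level 0.
    The pooled cross-mapping fraction aggregates alternative read mass
    over all samples.
    """
    if isinstance(per_sample_calls, Mapping):
        items = list(per_sample_calls.items())
    else:
        items = list(per_sample_calls)
    seen: set[str] = set()
    for sample, _ in items:
        if sample in seen:
            raise InputError(f"duplicate sample id: {sample!r}")
        seen.add(sample)
    if n_samples is None:
        n_samples = len(items)
    threshold = retention_threshold(n_samples, min_frac)

    site_calls: dict[str, dict[str, EditingSiteCall]] = {}
    for sample, calls in items:
        for c in calls:
            site_calls.setdefault(c.key, {})[sample] = c

    combined: list[CombinedSite] = []
    for key in sorted(site_calls):
        locus, position, ref, alt = parse_site_key(key)
        per_sample: dict[str, SampleSiteStat] = {}
        weighted_sum = raw_sum = 0.0
        for sample, _ in items:
            c = site_calls[key].get(sample)
            if c is None:
                per_sample[sample] = SampleSiteStat(0.0, 0.0, False)
            else:
                per_sample[sample] = SampleSiteStat(c.level, c.support_rptm, c.significant)
                weighted_sum += c.support_raw
                raw_sum += c.support_raw_unweighted
        n_sig = sum(1 for s in per_sample.values() if s.significant)
        combined.append(
            CombinedSite(
                key=key,
                locus_id=locus,
                position=position,
                ref=ref,
                alt=alt,
                per_sample=per_sample,
                n_significant=n_sig,
                retained=n_sig >= threshold,
                cross_map_fraction=(1.0 - weighted_sum / raw_sum) if raw_sum > 0 else 0.0,
                max_level=max(s.level for s in per_sample.values()),
            )
        )
    return combined
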