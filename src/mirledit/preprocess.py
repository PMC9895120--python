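"""Raw small-RNA reads to unique tags with counts and RPTM.

The pipeline's first stage: strip the 3' sequencing adapter, drop short or
low-quality reads, collapse identical sequences into unique reads and
normalise their counts to Reads Per Ten Million sequencing tags (RPTM),
the support unit used by the significance criteria downstream.

Quality filtering is tied to a single Phred threshold (default 30): a read
is discarded if any base falls below it. The RPTM denominator is the
number of reads surviving trimming and the length filter, i.e. the usable
sequencing tags of the library.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import FastqParseError, ParameterError

PHRED_OFFSET = 33
RPTM_SCALE = 10_000_000


@dataclass(frozen=True)
class UniqueRead:
    """A collapsed unique sequence with its raw count and normalised support.

    ``min_phred`` is the minimum per-base quality observed among the copies
    that were collapsed into this record (all of them are at or above the
    filter threshold by construction).
    """

    sequence: str
    raw_count: int
    rptm: float
    min_phred: int


def trim_adapter(
    read_seq: str,
    read_qual: str,
    adapter: str,
    *,
    min_overlap: int = 8,
    max_full_mismatches: int = 1,
) -> tuple[str, str] | None:
    """Remove the 3' adapter and everything after it.

    The earliest position where the remainder of the read matches the
    adapter is taken as the adapter start: either the full adapter with at
    most ``max_full_mismatches`` substitutions, or an exact match to an
    adapter prefix of at least ``min_overlap`` nt (the read may end inside
    the adapter). Reads with no hit are returned unchanged; a read that is
    adapter from its first base (or an empty read) yields ``None``, the
    discard signal.
    """
    if len(adapter) < min_overlap:
        raise ParameterError(
            f"adapter must be at least {min_overlap} nt, got {len(adapter)}"
        )
    if len(read_seq) != len(read_qual):
        raise FastqParseError("sequence and quality strings differ in length")
    if not read_seq:
        return None

    n = len(read_seq)
    la = len(adapter)
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, la)
        segment = read_seq[i : i + overlap]
        hit = False
        if overlap == la:
            mismatches = sum(a != b for a, b in zip(segment, adapter))
            hit = mismatches <= max_full_mismatches
        if not hit:
            hit = segment == adapter[:overlap]
        if hit:
            if i == 0:
                return None
            return read_seq[:i], read_qual[:i]
    return read_seq, read_qual


def _decode_qual(qual: str) -> list[int]:
    scores = []
    for ch in qual:
        code = ord(ch)
        if code < PHRED_OFFSET or code > 126:
            raise FastqParseError(f"invalid Phred+33 quality character {ch!r}")
        scores.append(code - PHRED_OFFSET)
    return scores


def filter_and_collapse(
    reads: Iterable[tuple[str, str]],
    min_len: int = 18,
    min_phred: int = 30,
) -> list[UniqueRead]:
    """Drop short/low-quality reads and collapse survivors by sequence.

    A read survives if it is at least ``min_len`` nt and every base is at
    or above ``min_phred``. Survivors are collapsed by exact sequence;
    ``raw_count`` sums the copies, and RPTM is computed against the total
    number of surviving reads. The result is sorted by sequence so that
    collapsing is order-invariant.
    """
    counts: Counter[str] = Counter()
    min_quals: dict[str, int] = {}
    for seq, qual in reads:
        if len(seq) != len(qual):
            raise FastqParseError("sequence and quality strings differ in length")
        if len(seq) < min_len:
            continue
        scores = _decode_qual(qual)
        lowest = min(scores)
        if lowest < min_phred:
            continue
        counts[seq] += 1
        prev = min_quals.get(seq)
        min_quals[seq] = lowest if prev is None else min(prev, lowest)

    library_total = sum(counts.values())
    uniques = [
        UniqueRead(
            sequence=seq,
            raw_count=c,
            rptm=normalize_rptm(c, library_total),
            min_phred=min_quals[seq],
        )
        for seq, c in sorted(counts.items())
    ]
    return uniques


def normalize_rptm(raw_count: int, library_total: int) -> float:
    """Reads Per Ten Million sequencing tags: count x 10^7 / library total."""
    if library_total < 1:
        raise ParameterError("library_total must be at least 1")
    if raw_count < 0:
        raise ParameterError("raw_count must be non-negative")
    return raw_count * RPTM_SCALE / library_total


def preprocess_reads(
    reads: Sequence[tuple[str, str, str]] | Sequence[tuple[str, str]],
    *,
    adapter: str | None = None,
    min_len: int = 18,
    min_phred: int = 30,
) -> tuple[list[UniqueRead], int]:
    """Full preprocessing for one sample: trim, filter, collapse.

    ``reads`` are (name, sequence, quality) triples or (sequence, quality)
    pairs. Returns the unique reads and the library total (number of reads
    surviving trimming and filtering) used as the RPTM denominator.
    """
    pairs: list[tuple[str, str]] = []
    for rec in reads:
        seq, qual = rec[-2], rec[-1]
        if adapter is not None:
            trimmed = trim_adapter(seq, qual, adapter)
            if trimmed is None:
                continue
            seq, qual = trimmed
        pairs.append((seq, qual))
    uniques = filter_and_collapse(pairs, min_len=min_len, min_phred=min_phred)
    return uniques, sum(u.raw_count for u in uniques)
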