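"""Placement of unique reads on pre-miRNA hairpins.

The aligner is a deterministic ungapped matcher over a tiny search space
(tens of hairpins plus optional decoy loci): for every read it examines
every window of every locus, so no placement within the mismatch/tail
tolerance can be missed. A read is split into an aligned *body* (matched
against the hairpin, allowing up to ``max_mismatches`` substitutions) and
an optional untemplated 3' *tail* of up to ``max_tail`` nt whose bases are
compared against the hairpin and, past its 3' end, the genomic flank.
The split minimises (body mismatches + tail length); on ties the longer
tail wins, so a trailing mismatch is coded as a 3' tail nucleotide — the
representation under which untemplated adenylation/uridylation appears as
``..._G_a`` / ``..._C_u`` sites.

Multi-mapped reads are down-weighted by cross-mapping correction:
each placement's weight is proportional to the locally supported
perfect-match expression times the sequencing-error likelihood of its
mismatches, iterated to a fixed point. Weights of one read always sum to
1, so total read mass is conserved.

Coordinates are 1-based and inclusive throughout, matching the miRBase
GFF3 convention and the ``_9_A_g`` site naming.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .preprocess import UniqueRead
from .util import rna_lower, rna_upper


@dataclass(frozen=True)
class Mature:
    """A mature miRNA annotation on a hairpin (1-based inclusive)."""

    name: str
    arm: str  # "5p" or "3p"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ParameterError(f"mature arm must be 5p or 3p, got {self.arm!r}")
        if not 1 <= self.start <= self.end:
            raise ParameterError(
                f"invalid mature interval [{self.start}, {self.end}] for {self.name}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PreMiRNA:
    """A pre-miRNA hairpin with its mature annotations and 3' genomic flank."""

    id: str
    sequence: str
    matures: list[Mature] = field(default_factory=list)
    flank3: str = ""
    flank5: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.flank3 = self.flank3.upper()
        self.flank5 = self.flank5.upper()
        for seq, label in ((self.sequence, "sequence"), (self.flank3, "flank3"), (self.flank5, "flank5")):
            if set(seq) - set("ACGT"):
                raise ParameterError(f"{label} of {self.id} contains non-ACGT characters")
        for m in self.matures:
            if m.end > len(self.sequence):
                raise ParameterError(
                    f"mature {m.name} [{m.start}, {m.end}] outside hairpin {self.id}"
                    f" of length {len(self.sequence)}"
                )

    @property
    def extended(self) -> str:
        """Hairpin plus 3' flank, the template for tail comparison."""
        return self.sequence + self.flank3


@dataclass
class Alignment:
    """One placement of a unique read on a locus.

    ``mismatches`` are (position, REF, alt) with REF in upper-case RNA and
    alt in lower-case RNA, positions strictly inside the body. ``tail``
    holds the trailing untemplated candidates as (position, template
    nucleotide, read nucleotide in lower-case RNA); a tail base equal to
    its template is a templated genomic extension, not an edit.
    """

    read: UniqueRead
    locus_id: str
    start: int
    body_length: int
    mismatches: tuple[tuple[int, str, str], ...] = ()
    tail: tuple[tuple[int, str, str], ...] = ()
    weight: float = 1.0

    @property
    def end(self) -> int:
        """Last body position (1-based inclusive)."""
        return self.start + self.body_length - 1

    @property
    def n_nontemplated(self) -> int:
        """Body mismatches plus tail bases disagreeing with the template."""
        return len(self.mismatches) + sum(
            1 for _, ref, alt in self.tail if rna_upper(alt) != ref
        )

    @property
    def is_perfect(self) -> bool:
        return self.n_nontemplated == 0


class _WindowIndex:
    """All fixed-length windows of all loci, cached per read length.

    Window starts are restricted to lie inside the hairpin body of the
    locus while the window itself may run into the 3' flank (where only
    tail bases are allowed to fall).
    """

    def __init__(self, loci: Sequence[tuple[str, int, str]]):
        # loci: (locus_id, hairpin_length, extended_sequence)
        self._loci = [
            (locus_id, hairpin_len, np.frombuffer(ext.encode("ascii"), dtype=np.uint8))
            for locus_id, hairpin_len, ext in loci
        ]
        self._cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray] | None] = {}

    def windows(self, m: int):
        if m in self._cache:
            return self._cache[m]
        mats, locus_idx, starts = [], [], []
        for li, (_, hairpin_len, ext) in enumerate(self._loci):
            n_starts = min(hairpin_len, len(ext) - m + 1)
            if n_starts <= 0:
                continue
            view = np.lib.stride_tricks.sliding_window_view(ext, m)[:n_starts]
            mats.append(view)
            locus_idx.append(np.full(n_starts, li, dtype=np.int32))
            starts.append(np.arange(n_starts, dtype=np.int32))
        if not mats:
            self._cache[m] = None
            return None
        out = (np.vstack(mats), np.concatenate(locus_idx), np.concatenate(starts))
        self._cache[m] = out
        return out

    def locus(self, index: int) -> tuple[str, int, np.ndarray]:
        return self._loci[index]


def _choose_split(
    diffs: np.ndarray, m: int, overhang: int, max_mismatches: int, max_tail: int
) -> tuple[int, int] | None:
    """Pick the tail length minimising (body mismatches + tail length).

    ``overhang`` bases hang past the hairpin 3' end and are forced into the
    tail. Ties prefer the longer tail so trailing mismatches are coded as
    untemplated 3' additions. Returns (tail_length, body_mismatches).
    """
    best: tuple[int, int] | None = None
    best_cost = None
    for t in range(overhang, max_tail + 1):
        body = m - t
        if body < 1:
            break
        body_mm = int(np.count_nonzero(diffs < body))
        if body_mm > max_mismatches:
            continue
        cost = body_mm + t
        if best_cost is None or cost < best_cost or (cost == best_cost and t > best[0]):
            best, best_cost = (t, body_mm), cost
    return best


def align_to_premirnas(
    reads: Iterable[UniqueRead],
    refs: Sequence[PreMiRNA],
    decoys: Sequence[tuple[str, str]] = (),
    max_mismatches: int = 2,
    max_tail: int = 3,
) -> list[Alignment]:
    """Find every ungapped placement of each read on hairpins and decoys.

    Output order is deterministic: reads in input order, placements sorted
    by (locus id, start). Reads with no placement are simply absent.
    """
    if max_mismatches < 0 or max_tail < 0:
        raise ParameterError("max_mismatches and max_tail must be non-negative")
    loci = [(pm.id, len(pm.sequence), pm.extended) for pm in refs]
    loci += [(decoy_id, len(seq), seq.upper()) for decoy_id, seq in decoys]
    index = _WindowIndex(loci)

    alignments: list[Alignment] = []
    for read in reads:
        m = len(read.sequence)
        bundle = index.windows(m)
        if bundle is None:
            continue
        windows, locus_idx, starts = bundle
        arr = np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)
        mm_counts = (windows != arr).sum(axis=1)
        candidates = np.nonzero(mm_counts <= max_mismatches + max_tail)[0]
        placements: list[Alignment] = []
        for c in candidates:
            locus_id, hairpin_len, ext = index.locus(int(locus_idx[c]))
            s0 = int(starts[c])
            overhang = max(0, s0 + m - hairpin_len)
            if overhang > max_tail:
                continue
            diffs = np.nonzero(windows[c] != arr)[0]
            split = _choose_split(diffs, m, overhang, max_mismatches, max_tail)
            if split is None:
                continue
            t, _ = split
            body = m - t
            mismatches = tuple(
                (
                    s0 + int(d) + 1,
                    rna_upper(chr(ext[s0 + int(d)])),
                    rna_lower(read.sequence[int(d)]),
                )
                for d in diffs
                if d < body
            )
            tail = tuple(
                (
                    s0 + i + 1,
                    rna_upper(chr(ext[s0 + i])),
                    rna_lower(read.sequence[i]),
                )
                for i in range(body, m)
            )
            placements.append(
                Alignment(
                    read=read,
                    locus_id=locus_id,
                    start=s0 + 1,
                    body_length=body,
                    mismatches=mismatches,
                    tail=tail,
                )
            )
        placements.sort(key=lambda a: (a.locus_id, a.start))
        alignments.extend(placements)
    return alignments


def cross_map_correct(
    alignments: list[Alignment],
    loci_expression_prior: Mapping[str, float] | None = None,
    *,
    pseudocount: float = 0.5,
    mismatch_error: float = 1e-3,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> list[Alignment]:
    """Reallocate multi-mapped read weight by local perfect-match expression.

    Iterative proportional allocation: a placement's weight is proportional
    to (weighted perfect-match read mass at the locus + pseudocount) times
    ``mismatch_error`` raised to the number of non-templated bases of the
    placement — the sequencing-error likelihood term of the cross-mapping
    correction method. Uniquely placed reads keep weight 1. Iteration stops
    when the largest weight change is below ``tol`` or after ``max_iter``
    rounds. Returns new Alignment objects; input objects are not mutated.
    """
    if not alignments:
        return []
    prior = dict(loci_expression_prior) if loci_expression_prior else {}

    by_read: dict[str, list[int]] = {}
    for i, a in enumerate(alignments):
        by_read.setdefault(a.read.sequence, []).append(i)

    weights = np.ones(len(alignments))
    multi = [idxs for idxs in by_read.values() if len(idxs) > 1]
    for idxs in multi:
        weights[idxs] = 1.0 / len(idxs)

    penalties = np.array(
        [mismatch_error ** a.n_nontemplated for a in alignments]
    )
    perfect = [i for i, a in enumerate(alignments) if a.is_perfect]
    counts = np.array([a.read.raw_count for a in alignments], dtype=float)

    for _ in range(max_iter):
        mass: dict[str, float] = dict(prior)
        for i in perfect:
            locus = alignments[i].locus_id
            mass[locus] = mass.get(locus, 0.0) + weights[i] * counts[i]
        delta = 0.0
        for idxs in multi:
            scores = np.array(
                [
                    (mass.get(alignments[i].locus_id, 0.0) + pseudocount) * penalties[i]
                    for i in idxs
                ]
            )
            total = scores.sum()
            new = scores / total if total > 0 else np.full(len(idxs), 1.0 / len(idxs))
            delta = max(delta, float(np.max(np.abs(new - weights[idxs]))))
            weights[idxs] = new
        if delta < tol:
            break

    return [replace(a, weight=float(w)) for a, w in zip(alignments, weights)]
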