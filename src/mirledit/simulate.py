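"""Synthetic references, planted editing events and small-RNA reads.

The generator emulates the statistical structure the detection pipeline
assumes: hairpin-derived reads concentrated on mature arms with small
isomiR-like end jitter, central substitutions planted at controlled
per-read probabilities, untemplated 3' tail nucleotides, homozygous SNP
positions (every read carries the alternative), and uniform per-base
sequencing errors calibrated to a single Phred score. Each simulated
sample ships with a ground-truth table keyed by the site naming
convention so parameter-recovery tests can compare estimated against
planted levels.

Read starts are mature-anchored with geometric 5'/3' extension (p = 0.7,
capped at 3 nt), one uniform Phred value per sample, and an optional
fixed 3' adapter so the preprocessing stage has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .align import Mature, PreMiRNA
from .errors import ParameterError, UnknownReferenceError
from .preprocess import PHRED_OFFSET
from .util import dna_upper, make_site_key, rna_lower, rna_upper

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # common small-RNA kit 3' adapter
_JITTER_P = 0.7
_MAX_JITTER = 3
_MAX_TAIL = 3
_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class ErrorModel:
    """Uniform per-base sequencing error calibrated to one Phred score.

    The error probability defaults to 10^(-phred_q/10) and is distributed
    uniformly over the three non-reference nucleotides; pass
    ``per_base_error`` explicitly (including 0 for noiseless simulations)
    to decouple it from the quality string.
    """

    phred_q: int = 30
    per_base_error: float | None = None

    def __post_init__(self) -> None:
        if self.per_base_error is None:
            self.per_base_error = 10.0 ** (-self.phred_q / 10.0)
        if not 0.0 <= self.per_base_error <= 0.25:
            raise ParameterError(
                f"per_base_error must be in [0, 0.25], got {self.per_base_error}"
            )
        if self.phred_q < 1:
            raise ParameterError("phred_q must be positive")


@dataclass(frozen=True)
class EditSpec:
    """One planted mutation/editing event.

    ``position`` is 1-based in the hairpin (tail positions run past the
    mature 3' end, into the flank if the mature reaches the hairpin end).
    ``kind`` is one of central, tail, five_prime, snp; a SNP is planted in
    every read (level 1.0).
    """

    pre_mirna_id: str
    position: int
    ref_nt: str
    alt_nt: str
    target_level: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("central", "tail", "five_prime", "snp"):
            raise ParameterError(f"unknown edit kind {self.kind!r}")
        if not 0.0 <= self.target_level <= 1.0:
            raise ParameterError("target_level must be in [0, 1]")
        if self.kind == "snp" and self.target_level != 1.0:
            raise ParameterError("snp edits must have target_level 1.0")
        if self.position < 1:
            raise ParameterError("position must be >= 1")
        object.__setattr__(self, "ref_nt", rna_upper(self.ref_nt))
        object.__setattr__(self, "alt_nt", rna_lower(self.alt_nt))
        if self.ref_nt == rna_upper(self.alt_nt):
            raise ParameterError("alt_nt must differ from ref_nt")

    @property
    def key(self) -> str:
        return make_site_key(self.pre_mirna_id, self.position, self.ref_nt, self.alt_nt)


@dataclass
class ReferenceSet:
    """Hairpins with genomic context plus decoy loci for cross-mapping."""

    pre_mirnas: list[PreMiRNA]
    genome_context: dict[str, tuple[str, str]] = field(default_factory=dict)
    decoy_loci: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for flank5, flank3 in self.genome_context.values():
            for f in (flank5, flank3):
                if set(f) - set("ACGT"):
                    raise ParameterError("flanks must contain only A/C/G/T")
        self._by_id = {pm.id: pm for pm in self.pre_mirnas}

    def hairpin(self, pre_mirna_id: str) -> PreMiRNA:
        try:
            return self._by_id[pre_mirna_id]
        except KeyError:
            raise UnknownReferenceError(pre_mirna_id) from None


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def generate_reference(
    n_hairpins: int,
    hairpin_len_range: tuple[int, int] = (60, 110),
    seed: int = 0,
    *,
    flank_len: int = 30,
    n_decoys: int | None = None,
) -> ReferenceSet:
    """Random hairpins with mature annotations, flanks and decoy loci.

    Hairpins of at least 62 nt carry both a 5p and a 3p mature arm of
    20-24 nt; shorter ones carry a single arm. Each decoy embeds a mature
    sub-sequence of one hairpin with a single substitution near its 3'
    end, so it shares an exact substring of >= 18 nt with the hairpin and
    perfectly matches reads carrying that substitution — the cross-mapping
    trap the Pseudo category guards against. Fully deterministic under a
    fixed seed.
    """
    lo, hi = hairpin_len_range
    if n_hairpins < 1:
        raise ParameterError("n_hairpins must be >= 1")
    if lo < 50 or hi < lo:
        raise ParameterError("hairpin lengths must satisfy 50 <= lo <= hi")
    rng = np.random.default_rng(seed)
    pre_mirnas: list[PreMiRNA] = []
    genome_context: dict[str, tuple[str, str]] = {}
    for i in range(n_hairpins):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        hid = f"sim-mir-{i + 1}"
        matures: list[Mature] = []
        both = length >= 62
        want_5p = both or bool(rng.integers(0, 2))
        if both or want_5p:
            start = int(rng.integers(2, 6))
            mlen = int(rng.integers(20, 25))
            matures.append(Mature(f"{hid}-5p", "5p", start, start + mlen - 1))
        if both or not want_5p:
            end = length - int(rng.integers(1, 6))
            mlen = int(rng.integers(20, 25))
            matures.append(Mature(f"{hid}-3p", "3p", end - mlen + 1, end))
        flank5 = _random_seq(rng, flank_len)
        flank3 = _random_seq(rng, flank_len)
        pre_mirnas.append(
            PreMiRNA(id=hid, sequence=seq, matures=matures, flank3=flank3, flank5=flank5)
        )
        genome_context[hid] = (flank5, flank3)

    if n_decoys is None:
        n_decoys = n_hairpins // 5
    decoys: list[tuple[str, str]] = []
    for j in range(n_decoys):
        pm = pre_mirnas[j % n_hairpins]
        m = pm.matures[0]
        insert = list(pm.sequence[m.start - 1 : m.start - 1 + 22])
        if len(insert) < 20:  # pragma: no cover - lengths guarantee 22
            continue
        mut_idx = len(insert) - 3
        current = insert[mut_idx]
        insert[mut_idx] = "ACGT"[("ACGT".index(current) + 1 + int(rng.integers(0, 3))) % 4]
        background = _random_seq(rng, 60)
        decoy = background[:20] + "".join(insert) + background[20 + len(insert):]
        decoys.append((f"decoy-{pm.id}", decoy))
    return ReferenceSet(pre_mirnas=pre_mirnas, genome_context=genome_context, decoy_loci=decoys)


def _validate_edit(ref: ReferenceSet, e: EditSpec) -> None:
    pm = ref.hairpin(e.pre_mirna_id)
    ext = pm.extended
    if e.kind == "tail":
        if not any(m.end < e.position <= m.end + _MAX_TAIL for m in pm.matures):
            raise ParameterError(
                f"tail edit at {e.position} is not just past a mature 3' end of {pm.id}"
            )
        if e.position > len(ext):
            raise ParameterError(f"tail position {e.position} beyond flank of {pm.id}")
        template = rna_upper(ext[e.position - 1])
        if template != e.ref_nt:
            raise ParameterError(
                f"edit {e.key}: template at {e.position} is {template}, not {e.ref_nt}"
            )
        if rna_upper(e.alt_nt) == template:
            raise ParameterError(f"tail edit {e.key} must disagree with the template")
    else:
        if e.position > len(pm.sequence):
            raise ParameterError(f"position {e.position} beyond hairpin {pm.id}")
        actual = rna_upper(pm.sequence[e.position - 1])
        if actual != e.ref_nt:
            raise ParameterError(
                f"edit {e.key}: hairpin has {actual} at {e.position}, not {e.ref_nt}"
            )


def edit_from_reference(
    ref: ReferenceSet,
    pre_mirna_id: str,
    position: int,
    alt_nt: str,
    target_level: float,
    kind: str = "central",
) -> EditSpec:
    """Build an EditSpec reading the reference nucleotide off the hairpin."""
    pm = ref.hairpin(pre_mirna_id)
    template = pm.extended if kind == "tail" else pm.sequence
    if position > len(template):
        raise ParameterError(f"position {position} beyond {pre_mirna_id}")
    return EditSpec(
        pre_mirna_id=pre_mirna_id,
        position=position,
        ref_nt=template[position - 1],
        alt_nt=alt_nt,
        target_level=target_level,
        kind=kind,
    )


def find_editable_position(
    ref: ReferenceSet,
    nt: str = "A",
    *,
    seed_only: bool = False,
    margin: int = 2,
) -> tuple[str, int]:
    """First hairpin position carrying ``nt`` safely inside a mature body.

    ``margin`` keeps the position away from the body edges so planted
    substitutions stay central; ``seed_only`` restricts to mature
    positions 2-8.
    """
    want = dna_upper(nt)
    for pm in ref.pre_mirnas:
        for m in pm.matures:
            for pos in range(m.start + margin, m.end - margin + 1):
                rel = pos - m.start + 1
                if seed_only and not 2 <= rel <= 8:
                    continue
                if pm.sequence[pos - 1] == want:
                    return pm.id, pos
    raise ParameterError(f"no {nt} found inside any mature body")


def _apply_errors(matrix: np.ndarray, rng: np.random.Generator, rate: float) -> None:
    if rate <= 0:
        return
    mask = rng.random(matrix.shape) < rate
    n_hits = int(mask.sum())
    if n_hits == 0:
        return
    codes = _CODE[matrix[mask]]
    shifts = rng.integers(1, 4, n_hits).astype(np.uint8)
    matrix[mask] = _NT[(codes + shifts) % 4]


def simulate_sample(
    ref: ReferenceSet,
    edits: Sequence[EditSpec],
    depth_per_arm: int = 500,
    error: ErrorModel | None = None,
    read_len_range: tuple[int, int] = (18, 41),
    seed: int = 0,
    *,
    adapter: str | None = None,
    sample_id: str = "sample",
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate one small-RNA library and its ground-truth table.

    Returns (reads, truth): reads as (name, sequence, quality) triples
    ready for FASTQ serialisation, truth as a table with one row per
    planted edit (site key, kind, planted level, expected support).
    Identical (ref, edits, seed) yield byte-identical output.
    """
    if depth_per_arm < 1:
        raise ParameterError("depth_per_arm must be >= 1")
    min_l, max_l = read_len_range
    if min_l < 1 or max_l < min_l:
        raise ParameterError("invalid read_len_range")
    error = error if error is not None else ErrorModel()
    for e in edits:
        _validate_edit(ref, e)

    rng = np.random.default_rng(seed)
    qual_char = chr(error.phred_q + PHRED_OFFSET)
    reads: list[tuple[str, str, str]] = []

    for pm in ref.pre_mirnas:
        hairpin_len = len(pm.sequence)
        for m in pm.matures:
            subs = [
                e for e in edits
                if e.pre_mirna_id == pm.id and e.kind in ("central", "snp", "five_prime")
            ]
            tails = [
                e for e in edits
                if e.pre_mirna_id == pm.id and e.kind == "tail"
                and m.end < e.position <= m.end + _MAX_TAIL
            ]
            D = depth_per_arm
            k5 = np.minimum(rng.geometric(_JITTER_P, D) - 1, _MAX_JITTER)
            k3 = np.minimum(rng.geometric(_JITTER_P, D) - 1, _MAX_JITTER)
            starts = np.maximum(1, m.start - k5)
            ends = np.minimum(hairpin_len, m.end + k3)
            too_long = ends - starts + 1 > max_l
            ends[too_long] = starts[too_long] + max_l - 1

            tail_masks = [
                (e, rng.random(D) < e.target_level) for e in sorted(tails, key=lambda t: t.position)
            ]

            seqs: list[str | None] = [None] * D
            groups: dict[tuple[int, int], np.ndarray] = {}
            for key in sorted({(int(s), int(t)) for s, t in zip(starts, ends)}):
                groups[key] = np.nonzero((starts == key[0]) & (ends == key[1]))[0]
            for (s, t), idx in groups.items():
                base = pm.sequence[s - 1 : t]
                matrix = np.tile(
                    np.frombuffer(base.encode("ascii"), dtype=np.uint8), (len(idx), 1)
                )
                for e in sorted(subs, key=lambda x: x.position):
                    if not s <= e.position <= t:
                        continue
                    col = e.position - s
                    alt_byte = ord(dna_upper(e.alt_nt))
                    if e.kind == "snp":
                        matrix[:, col] = alt_byte
                    else:
                        hit = rng.random(len(idx)) < e.target_level
                        matrix[hit, col] = alt_byte
                _apply_errors(matrix, rng, float(error.per_base_error))
                for row, read_i in enumerate(idx):
                    seq = matrix[row].tobytes().decode("ascii")
                    for e, mask in tail_masks:
                        if mask[read_i] and t >= e.position - 1:
                            seq = seq[: e.position - s] + dna_upper(e.alt_nt)
                            break
                    seqs[read_i] = seq

            for i, seq in enumerate(seqs):
                if seq is None or len(seq) < min_l:
                    continue
                if adapter is not None:
                    seq = seq + adapter
                reads.append(
                    (f"{sample_id}:{pm.id}:{m.arm}:{i}", seq, qual_char * len(seq))
                )

    truth = pd.DataFrame(
        [
            {
                "key": e.key,
                "kind": e.kind,
                "planted_level": e.target_level,
                "expected_support": e.target_level * depth_per_arm,
                "sample": sample_id,
            }
            for e in edits
        ],
        columns=["key", "kind", "planted_level", "expected_support", "sample"],
    )
    return reads, truth


def simulate_cohort(
    ref: ReferenceSet,
    sample_edits: dict[str, Sequence[EditSpec]],
    depth_per_arm: int = 500,
    error: ErrorModel | None = None,
    seed: int = 0,
    **kwargs,
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Simulate one library per sample with per-sample derived seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sample_edits))
    all_reads: dict[str, list[tuple[str, str, str]]] = {}
    truths = []
    for child, (sample, edits) in zip(children, sorted(sample_edits.items())):
        reads, truth = simulate_sample(
            ref,
            list(edits),
            depth_per_arm=depth_per_arm,
            error=error,
            seed=int(child.generate_state(1)[0] % (2**31)),
            sample_id=sample,
            **kwargs,
        )
        all_reads[sample] = reads
        truths.append(truth)
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=["key", "kind", "planted_level", "expected_support", "sample"])
    )
    return all_reads, truth
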