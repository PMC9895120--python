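"""Simulation-based validation experiments for the detection pipeline.

Three experiments characterise the pipeline on data whose ground truth is
known because the simulator planted it:

* specificity — no planted edits, Phred-30 sequencing noise: how many
  candidate sites survive the significance criteria anyway,
* level recovery — planted editing levels re-estimated from reads and
  compared against their binomial sampling tolerance,
* end-to-end recovery — a case/control cohort with one differentially
  edited A-to-I site: is the site retained, classified A-to-I and called
  significantly hyper-edited?

Each experiment derives per-replicate seeds from a single master seed and
reports summary fractions plus the raw per-replicate outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .pipeline import process_sample, run_study
from .simulate import (
    ErrorModel,
    ReferenceSet,
    edit_from_reference,
    find_editable_position,
    generate_reference,
    simulate_sample,
)
from .sitecall import combine_samples


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


@dataclass
class FalsePositiveSummary:
    n_seeds: int
    n_candidates: int
    n_retained: int

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_candidates if self.n_candidates else 0.0


def false_positive_retention(
    n_seeds: int = 20,
    n_hairpins: int = 50,
    depth_per_arm: int = 500,
    phred_q: int = 30,
    seed: int = 0,
) -> FalsePositiveSummary:
    """Retained-site fraction on edit-free libraries with Phred-q noise.

    Each replicate is an independent single-sample study on a fresh
    reference; candidates are pooled over replicates.
    """
    n_candidates = n_retained = 0
    for child in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(child)
        ref = generate_reference(
            n_hairpins, (60, 100), seed=int(rng.integers(2**31))
        )
        reads, _ = simulate_sample(
            ref, [], depth_per_arm=depth_per_arm,
            error=ErrorModel(phred_q), seed=int(rng.integers(2**31)),
        )
        result = process_sample(reads, ref)
        combined = combine_samples({"s1": result.calls})
        n_candidates += len(combined)
        n_retained += sum(1 for s in combined if s.retained)
    return FalsePositiveSummary(n_seeds, n_candidates, n_retained)


@dataclass
class LevelRecoverySummary:
    checks: pd.DataFrame  # seed, level, estimate, tolerance, ok

    @property
    def fraction_within(self) -> float:
        return float(self.checks["ok"].mean()) if len(self.checks) else 1.0


def level_recovery(
    levels: tuple[float, ...] = (0.1, 0.3, 0.7),
    coverage: int = 1000,
    n_seeds: int = 100,
    seed: int = 0,
) -> LevelRecoverySummary:
    """Planted-level estimation error against the 3-sigma binomial bound.

    One hairpin per level per replicate, with a single edit planted at a
    central position of the mature arm — so every planted site sits under
    exactly ``coverage`` reads and edits never stack on the same read. A
    check passes when the estimated level is within
    3*sqrt(L(1-L)/coverage) of the planted L.
    """
    rows = []
    for rep, child in enumerate(_child_seeds(seed, n_seeds)):
        rng = np.random.default_rng(child)
        ref = generate_reference(
            len(levels), (60, 61), seed=int(rng.integers(2**31)), n_decoys=0
        )
        edits = []
        for pm, level in zip(ref.pre_mirnas, levels):
            mature = pm.matures[0]
            pos = mature.start + 4
            ref_nt = pm.sequence[pos - 1]
            alt = "ACGT"[("ACGT".index(ref_nt) + 1) % 4]
            edits.append(edit_from_reference(ref, pm.id, pos, alt, level))
        reads, _ = simulate_sample(
            ref, edits, depth_per_arm=coverage,
            error=ErrorModel(30), seed=int(rng.integers(2**31)),
        )
        result = process_sample(reads, ref)
        by_key = {c.key: c for c in result.calls}
        for e, level in zip(edits, levels):
            call = by_key.get(e.key)
            estimate = call.level if call is not None else 0.0
            tol = 3.0 * math.sqrt(level * (1 - level) / coverage)
            rows.append(
                {"seed": rep, "level": level, "estimate": estimate,
                 "tolerance": tol, "ok": abs(estimate - level) <= tol}
            )
    return LevelRecoverySummary(pd.DataFrame(rows))


@dataclass
class EndToEndSummary:
    outcomes: pd.DataFrame  # seed, retained, category_ok, hyper_significant, ok

    @property
    def success_fraction(self) -> float:
        return float(self.outcomes["ok"].mean()) if len(self.outcomes) else 0.0


def end_to_end_recovery(
    n_seeds: int = 100,
    n_case: int = 20,
    n_control: int = 25,
    case_level: float = 0.35,
    control_level: float = 0.12,
    coverage: int = 800,
    seed: int = 0,
) -> EndToEndSummary:
    """Full-pipeline recovery of one differential A-to-I site.

    Each replicate simulates a cohort in which every sample carries an
    A->g edit at the same mature-body position, at the case level in
    cases and the control level in controls, then checks that the site is
    retained, classified A-to-I, and called a significant hyper-edited
    site by the case-control comparison.
    """
    rows = []
    for rep, child in enumerate(_child_seeds(seed, n_seeds)):
        rng = np.random.default_rng(child)
        ref = _reference_with_adenosine(int(rng.integers(2**31)))
        hid, pos = find_editable_position(ref, "A", margin=3)
        design_rows = []
        sample_reads = {}
        for i in range(n_case + n_control):
            group = "case" if i < n_case else "control"
            level = case_level if group == "case" else control_level
            sid = f"{group}{i:02d}"
            edits = [edit_from_reference(ref, hid, pos, "g", level)]
            reads, _ = simulate_sample(
                ref, edits, depth_per_arm=coverage,
                error=ErrorModel(30), seed=int(rng.integers(2**31)), sample_id=sid,
            )
            sample_reads[sid] = reads
            design_rows.append(
                {"sample": sid, "group": group, "region": "SFG",
                 "age": float(rng.integers(1, 60))}
            )
        design = pd.DataFrame(design_rows)
        study = run_study(sample_reads, ref, design=design)

        target = next((s for s in study.combined if s.locus_id == hid and s.position == pos
                       and s.alt == "g"), None)
        retained = target is not None and target.retained
        category_ok = False
        if retained:
            ann = study.annotations.get(target.key)
            category_ok = ann is not None and ann.category == "A-to-I"
        hyper = False
        if retained and study.comparisons:
            cmp_ = next((c for c in study.comparisons if c.site == target.key), None)
            hyper = cmp_ is not None and cmp_.significant and cmp_.direction == "hyper"
        rows.append(
            {"seed": rep, "retained": retained, "category_ok": category_ok,
             "hyper_significant": hyper, "ok": retained and category_ok and hyper}
        )
    return EndToEndSummary(pd.DataFrame(rows))


def _reference_with_adenosine(seed: int) -> ReferenceSet:
    """A one-hairpin reference guaranteed to offer a central adenosine."""
    for attempt in range(10):
        ref = generate_reference(1, (60, 61), seed=seed + attempt, n_decoys=0)
        try:
            find_editable_position(ref, "A", margin=3)
            return ref
        except ParameterError:
            continue
    raise ParameterError("could not generate a hairpin with a central adenosine")
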