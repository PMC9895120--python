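"""Reference generation and read simulation with planted ground truth."""

import pytest

from mirledit import io
from mirledit.errors import ParameterError
from mirledit.pipeline import process_sample
from mirledit.simulate import (
    EditSpec,
    ErrorModel,
    edit_from_reference,
    generate_reference,
    simulate_sample,
)

NOISELESS = ErrorModel(30, per_base_error=0.0)


class TestGenerateReference:
    def test_single_hairpin_respects_bounds(self):
        ref = generate_reference(1, (60, 60), seed=7)
        (pm,) = ref.pre_mirnas
        assert len(pm.sequence) == 60
        assert pm.matures
        for m in pm.matures:
            assert 1 <= m.start <= m.end <= 60
            assert 20 <= m.length <= 24

    def test_fixed_seed_gives_byte_identical_serialisation(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            ref = generate_reference(20, (60, 110), seed=1)
            fa = tmp_path / f"hairpins_{run}.fa"
            gff = tmp_path / f"matures_{run}.gff3"
            io.write_fasta([(p.id, p.sequence) for p in ref.pre_mirnas], fa)
            io.write_mature_gff3(ref.pre_mirnas, gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_different_seeds_give_different_sequences(self):
        a = generate_reference(5, (60, 90), seed=1)
        b = generate_reference(5, (60, 90), seed=2)
        assert [p.sequence for p in a.pre_mirnas] != [p.sequence for p in b.pre_mirnas]

    def test_invalid_length_range_rejected(self):
        with pytest.raises(ParameterError):
            generate_reference(1, (40, 60), seed=0)
        with pytest.raises(ParameterError):
            generate_reference(1, (90, 60), seed=0)

    def test_decoys_share_long_exact_substring_with_a_hairpin(self):
        ref = generate_reference(10, (62, 90), seed=3)
        assert ref.decoy_loci
        for decoy_id, decoy_seq in ref.decoy_loci:
            hid = decoy_id.removeprefix("decoy-")
            pm = ref.hairpin(hid)
            m = pm.matures[0]
            shared = pm.sequence[m.start - 1 : m.start - 1 + 19]
            assert shared in decoy_seq


class TestSimulateSample:
    def test_noiseless_reads_are_exact_hairpin_substrings(self, small_reference):
        reads, _ = simulate_sample(
            small_reference, [], depth_per_arm=100, error=NOISELESS, seed=0
        )
        seqs = {p.id: p.sequence for p in small_reference.pre_mirnas}
        assert reads
        for name, seq, qual in reads:
            hid = name.split(":")[1]
            assert seq in seqs[hid]
            assert len(seq) == len(qual)

    def test_level_one_edit_in_every_covering_read(self, small_reference):
        pm = small_reference.pre_mirnas[0]
        m = pm.matures[0]
        pos = m.start + 5
        edit = edit_from_reference(small_reference, pm.id, pos, _other(pm.sequence[pos - 1]), 1.0)
        reads, _ = simulate_sample(
            small_reference, [edit], depth_per_arm=200, error=NOISELESS, seed=1
        )
        covering = carrying = 0
        for name, seq, _ in reads:
            if name.split(":")[1] != pm.id:
                continue
            start = _locate(seq, pm.sequence)
            if start + 1 <= pos <= start + len(seq):
                covering += 1
                carrying += seq[pos - start - 1] == edit.alt_nt.upper().replace("U", "T")
        assert covering > 0 and carrying == covering

    def test_planted_level_recovered_within_binomial_tolerance(self, small_reference):
        pm = small_reference.pre_mirnas[0]
        m = pm.matures[0]
        pos = m.start + 5
        level, depth = 0.30, 2000
        edit = edit_from_reference(small_reference, pm.id, pos, _other(pm.sequence[pos - 1]), level)
        reads, _ = simulate_sample(
            small_reference, [edit], depth_per_arm=depth, error=NOISELESS, seed=11
        )
        result = process_sample(reads, small_reference)
        call = next(c for c in result.calls if c.key == edit.key)
        assert abs(call.level - level) <= 0.03

    def test_identical_inputs_give_identical_fastq_bytes(self, small_reference, tmp_path):
        blobs = []
        for run in ("a", "b"):
            reads, _ = simulate_sample(
                small_reference, [], depth_per_arm=100, error=ErrorModel(30), seed=9
            )
            path = tmp_path / f"{run}.fastq"
            io.write_fastq(reads, path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]

    def test_unknown_hairpin_in_edit_is_rejected(self, small_reference):
        edit = EditSpec("nonexistent", 5, "A", "g", 0.5, "central")
        with pytest.raises(Exception):
            simulate_sample(small_reference, [edit], depth_per_arm=10, seed=0)

    def test_noiseless_editfree_sample_yields_no_significant_sites(self, small_reference):
        reads, _ = simulate_sample(
            small_reference, [], depth_per_arm=300, error=NOISELESS, seed=4
        )
        result = process_sample(reads, small_reference)
        assert all(not c.significant for c in result.calls)

    def test_truth_table_has_one_row_per_edit(self, small_reference):
        pm = small_reference.pre_mirnas[0]
        m = pm.matures[0]
        edits = [
            edit_from_reference(
                small_reference, pm.id, m.start + off, _other(pm.sequence[m.start + off - 1]), 0.2
            )
            for off in (3, 6)
        ]
        _, truth = simulate_sample(small_reference, edits, depth_per_arm=10, seed=0)
        assert list(truth["key"]) == [e.key for e in edits]
        assert list(truth["planted_level"]) == [0.2, 0.2]


def _other(nt):
    return "ACGT"[("ACGT".index(nt) + 1) % 4]


def _locate(seq, hairpin):
    """0-based start of the best (fewest-mismatch) placement of seq."""
    best, best_mm = 0, len(seq) + 1
    for start in range(len(hairpin) - len(seq) + 1):
        mm = sum(a != b for a, b in zip(seq, hairpin[start:]))
        if mm < best_mm:
            best, best_mm = start, mm
    return best
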