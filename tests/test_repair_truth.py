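"""Read-pool consolidation, simple-indel alignment, and truth labeling."""

import numpy as np
import pytest

from mendelscan.repair_truth import (
    Category,
    SchemaError,
    align_simple_indel,
    junction_microhomology,
    label_event,
    load_events,
    make_event,
    reconstruct_read,
)

from conftest import (
    FIXTURE_CUT,
    FIXTURE_WT,
    brute_force_simple_indel,
    random_dna,
)


class TestAlignSimpleIndel:
    def test_deletion_leftmost(self):
        call = align_simple_indel(FIXTURE_WT, "AAGCATCC")
        assert (call.kind, call.length, call.left) == ("deletion", 6, 2)

    def test_identical_read_is_excluded(self):
        assert align_simple_indel(FIXTURE_WT, FIXTURE_WT) is None

    def test_single_base_insertion(self):
        call = align_simple_indel(FIXTURE_WT, "AAGCATTATGCATCC")
        assert (call.kind, call.length, call.inserted_seq) \
            == ("insertion", 1, "A")

    @pytest.mark.parametrize("read", [
        "AAGCATGTGCATCC",      # substitution
        "AACATTTGCTCC",        # two separate deletions
        "AAGCTTTGCATCCA",      # deletion + insertion
    ])
    def test_non_simple_edits_rejected(self, read):
        assert align_simple_indel(FIXTURE_WT, read) is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_simple_indel("", "ACGT")

    def test_agrees_with_bruteforce_placement(self, rng):
        """Call exists iff a single-indel explanation exists; leftmost."""
        for _ in range(300):
            wt = random_dna(rng, int(rng.integers(20, 50)))
            mode = rng.random()
            if mode < 0.4:      # plant a deletion
                left = int(rng.integers(0, len(wt) - 5))
                dlen = int(rng.integers(1, 6))
                read = wt[:left] + wt[left + dlen:]
            elif mode < 0.8:    # plant an insertion
                left = int(rng.integers(0, len(wt)))
                ins = random_dna(rng, int(rng.integers(1, 4)))
                read = wt[:left] + ins + wt[left:]
            else:               # scramble: usually not a simple indel
                read = random_dna(rng, int(rng.integers(15, 55)))
            placements = brute_force_simple_indel(wt, read)
            call = align_simple_indel(wt, read)
            if wt == read or not placements:
                assert call is None
            else:
                assert call is not None
                assert (call.kind, call.left, call.length) == placements[0]
                assert reconstruct_read(wt, call) == read

    def test_matches_heavy_mismatch_penalty_alignment(self):
        """The accepted calls coincide with the optimal global alignment
        under match 1 / mismatch -50 / gap open 10, extend 4."""
        aligner = _biostrings_like_aligner()
        rng = np.random.default_rng(7)
        for _ in range(40):
            wt = random_dna(rng, 30)
            if rng.random() < 0.5:
                left = int(rng.integers(0, 25))
                dlen = int(rng.integers(1, 5))
                read = wt[:left] + wt[left + dlen:]
            else:
                read = random_dna(rng, 30)
            call = align_simple_indel(wt, read)
            if wt == read:
                continue
            if call is not None:
                gap = call.length
                expected = min(len(wt), len(read)) - 10 - 4 * gap
                assert aligner.score(wt, read) == expected


def _biostrings_like_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -50
    # a length-L gap costs 10 + 4L
    aligner.open_gap_score = -14
    aligner.extend_gap_score = -4
    return aligner


class TestJunctionMicrohomology:
    def test_fixture_deletion_has_4nt_junction(self):
        assert junction_microhomology(FIXTURE_WT, 2, 6) == 4

    def test_short_junction_is_not_mmej(self):
        assert junction_microhomology("AAACGTGAC", 3, 2) < 3

    def test_homopolymer_always_mmej(self):
        assert junction_microhomology("AAAAAAAA", 2, 3) >= 3

    def test_placement_invariant(self, rng):
        for _ in range(100):
            wt = random_dna(rng, 40)
            left = int(rng.integers(1, 30))
            dlen = int(rng.integers(1, 8))
            product = wt[:left] + wt[left + dlen:]
            ks = {
                junction_microhomology(wt, l, dlen)
                for l in range(len(product) + 1)
                if wt[:l] + wt[l + dlen:] == product
            }
            assert len(ks) == 1

    def test_bounds(self):
        with pytest.raises(ValueError):
            junction_microhomology("ACGT", 2, 5)


class TestLoadEvents(object):
    def _write(self, tmp_path, rows, header=True, extra_cols=()):
        path = tmp_path / "events.tsv"
        cols = ["event_id", "wt", "cut_index", "read_seq", "count"]
        cols += list(extra_cols)
        lines = ["\t".join(cols)] if header else []
        lines += ["\t".join(map(str, r)) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_consolidation_and_ranking(self, tmp_path):
        path = self._write(tmp_path, [
            ("e1", FIXTURE_WT, 7, "AAGCATCC", 60),
            ("e1", FIXTURE_WT, 7, "AAGCTTTGCATCC", 30),
            ("e1", FIXTURE_WT, 7, "AAGATTTGCATCC", 10),
        ])
        events = load_events(path)
        assert len(events) == 1
        ev = events[0]
        assert ev.total_reads == 100
        assert ev.top_read == "AAGCATCC"
        assert ev.top_freq == pytest.approx(0.60)

    def test_duplicate_rows_summed(self, tmp_path):
        path = self._write(tmp_path, [
            ("e1", FIXTURE_WT, 7, "AAGCATCC", 40),
            ("e1", FIXTURE_WT, 7, "AAGCATCC", 20),
            ("e1", FIXTURE_WT, 7, "AAGCTTTGCATCC", 40),
        ])
        ev = load_events(path)[0]
        assert ev.reads[0] == ("AAGCATCC", 60)

    def test_empty_file_warns(self, tmp_path):
        path = self._write(tmp_path, [])
        with pytest.warns(UserWarning):
            assert load_events(path) == []

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("event_id\twt\tread_seq\n")
        with pytest.raises(SchemaError):
            load_events(path)

    def test_bad_rows_rejected_with_warning(self, tmp_path, caplog):
        path = self._write(tmp_path, [
            ("e1", FIXTURE_WT, 7, "AAGCATCC", 60),
            ("e1", FIXTURE_WT, 7, "AAGNNTCC", 30),
        ])
        import logging

        with caplog.at_level(logging.WARNING, "mendelscan.repair_truth"):
            ev = load_events(path)[0]
        assert ev.total_reads == 60
        assert any("line 3" in r.getMessage() for r in caplog.records)

    def test_non_genomic_events_dropped(self, tmp_path):
        path = self._write(tmp_path, [
            ("e1", FIXTURE_WT, 7, "AAGCATCC", 60, "true"),
            ("e2", FIXTURE_WT, 7, "AAGCATCC", 60, "false"),
        ], extra_cols=("genomic",))
        events = load_events(path)
        assert [e.event_id for e in events] == ["e1"]


class TestLabelEvent:
    def test_prema_majority_mmej(self):
        ev = make_event("e", FIXTURE_WT, FIXTURE_CUT, [
            ("AAGCATCC", 60),            # the MMEJ deletion product
            ("AAGCTTTGCATCC", 25),       # 1 nt non-MMEJ deletion
            ("AAGATTTGCATCC", 15),
        ])
        lab = label_event(ev)
        assert lab.included
        assert lab.category is Category.MMEJ_DEL
        assert lab.is_prema
        assert not lab.is_sm_frameshift  # deletion of 6 is in frame

    def test_below_majority_is_not_prema(self):
        ev = make_event("e", FIXTURE_WT, FIXTURE_CUT, [
            ("AAGCATCC", 45),
            ("AAGCTTTGCATCC", 30),
            ("AAGATTTGCATCC", 25),
        ])
        lab = label_event(ev)
        assert lab.included and lab.category is Category.MMEJ_DEL
        assert not lab.is_prema

    def test_majority_one_bp_insertion_is_frameshift(self):
        ev = make_event("e", FIXTURE_WT, FIXTURE_CUT, [
            ("AAGCATTATGCATCC", 55),
            ("AAGCTTTGCATCC", 45),
        ])
        lab = label_event(ev)
        assert lab.category is Category.INS_1BP
        assert lab.is_sm_insertion and lab.is_sm_frameshift
        assert not lab.is_prema

    def test_wild_type_top_read_excluded(self):
        ev = make_event("e", FIXTURE_WT, FIXTURE_CUT, [
            (FIXTURE_WT, 80), ("AAGCATCC", 20),
        ])
        lab = label_event(ev)
        assert not lab.included and lab.category is None

    def test_category_partition_is_exhaustive(self, rng):
        """Every included event lands in exactly one of the 4 groups."""
        cats = set()
        for _ in range(60):
            wt = random_dna(rng, 40)
            choice = rng.random()
            if choice < 0.5:
                left = int(rng.integers(5, 30))
                dlen = int(rng.integers(1, 8))
                top = wt[:left] + wt[left + dlen:]
            else:
                left = int(rng.integers(5, 30))
                ins = random_dna(rng, int(rng.integers(1, 4)))
                top = wt[:left] + ins + wt[left:]
            ev = make_event("e", wt, 20, [(top, 60), (wt[:10] + wt[12:], 40)])
            lab = label_event(ev)
            if lab.included:
                assert lab.category in set(Category)
                cats.add(lab.category)
        assert len(cats) >= 3
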