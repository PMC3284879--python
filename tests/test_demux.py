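"""Sequential dual-barcode decoding: matching, per-read decode, run stats."""

import itertools

import pytest

from pairbc import (
    ReadLayout,
    ReadRecord,
    SimConfig,
    decode_read,
    demux_run,
    find_adaptor,
    match_barcode,
    simulate_run,
)
from pairbc.colorspace import encode_colors
from pairbc.demux import FAILURE_CLASSES


def mutate(seq, pos, alphabet="ACGT"):
    for b in alphabet:
        if b != seq[pos]:
            yield seq[:pos] + b + seq[pos + 1:]


class TestMatchBarcode:
    def test_exact_match_distance_zero(self, f_set):
        for b in f_set:
            m = match_barcode(b.seq, f_set)
            assert m.status == "unique" and m.barcode_id == b.id and m.distance == 0

    def test_every_single_error_corruption_decodes_uniquely(self, f_set, r_set):
        """min_d_nt >= 3 guarantees unique decoding at tolerance 1 —
        exhaustive over all 1-substitution corruptions of both default sets."""
        for bset in (f_set, r_set):
            for b in bset:
                for pos in range(len(b.seq)):
                    for corrupted in mutate(b.seq, pos):
                        m = match_barcode(corrupted, bset)
                        assert m.status == "unique" and m.barcode_id == b.id

    def test_distance_two_from_everything_is_none(self, f_set):
        # walk 2 substitutions away from one barcode, verify none of the
        # set is within tolerance before asserting
        from pairbc.colorspace import hamming_nt

        b = f_set.seqs[0]
        for cand in ("".join(c) for c in itertools.product("ACGT", repeat=6)):
            if all(hamming_nt(cand, s) >= 2 for s in f_set.seqs):
                assert match_barcode(cand, f_set).status == "none"
                break

    def test_ambiguous_on_equidistant_tie(self):
        from pairbc import Barcode, BarcodeSet

        bset = BarcodeSet([Barcode("x", "AAAAAA"), Barcode("y", "AAAATT")],
                          min_d_nt=0, min_d_color=0)
        # AAAAAT is 1 mismatch from both
        assert match_barcode("AAAAAT", bset).status == "ambiguous"

    def test_color_space_matching(self, f_set):
        for b in f_set:
            window = encode_colors(b.seq, f_set.anchor)
            m = match_barcode(window, f_set, space="color")
            assert m.status == "unique" and m.barcode_id == b.id

    def test_window_length_mismatch_rejected(self, f_set):
        with pytest.raises(ValueError):
            match_barcode("AAAA", f_set)


class TestFindAdaptor:
    ADAPTOR = "CTGTAGGCACCATCAAT"

    def test_exact_junction(self):
        insert = "ACGTACGTACGTACGTACGTA"
        read = insert + self.ADAPTOR[:10]
        assert find_adaptor(read, self.ADAPTOR) == len(insert)

    def test_no_adaptor_cuts_at_end(self):
        read = "ACGTACGTACGTACGTACGTA"
        assert find_adaptor(read, self.ADAPTOR) == len(read)

    def test_one_error_in_eight_bases_tolerated(self):
        insert = "ACGTACGTACGTACGTACGTA"
        adap = list(self.ADAPTOR[:8])
        adap[3] = "A" if adap[3] != "A" else "C"
        read = insert + "".join(adap)
        assert find_adaptor(read, self.ADAPTOR) == len(insert)  # 1/8 <= 0.2

    def test_short_terminal_overlap_needs_min_overlap(self):
        insert = "ACGTACGTACGTACGTACGTA"
        read = insert + self.ADAPTOR[:3]  # below min_overlap=5
        assert find_adaptor(read, self.ADAPTOR) == len(read)


class TestDecodeRead:
    def make_read(self, f_set, r_set, insert="ACGTTGCAGTCAGGATCCAGT",
                  adaptor="CTGTAGGCACC"):
        return ReadRecord(
            id="r1",
            seq=f_set.seqs[0] + insert + adaptor,
            mate_seq=r_set.seqs[0],
        )

    def test_error_free_read_recovers_sample_and_insert(self, f_set, r_set, sheet):
        insert = "ACGTTGCAGTCAGGATCCAGT"
        layout = ReadLayout(adaptor3="CTGTAGGCACCATCAAT")
        read = self.make_read(f_set, r_set, insert)
        res = decode_read(read, sheet, f_set, r_set, layout)
        assert res.assigned
        assert res.sample_id == sheet.entries[0][0]
        assert res.insert == insert

    def test_one_error_in_each_barcode_still_assigned(self, f_set, r_set, sheet):
        insert = "ACGTTGCAGTCAGGATCCAGT"
        layout = ReadLayout(adaptor3="CTGTAGGCACCATCAAT")
        f_bad = next(mutate(f_set.seqs[0], 2))
        r_bad = next(mutate(r_set.seqs[0], 4))
        read = ReadRecord(id="r1", seq=f_bad + insert + "CTGTAGGCACC", mate_seq=r_bad)
        res = decode_read(read, sheet, f_set, r_set, layout)
        assert res.assigned and res.sample_id == sheet.entries[0][0]

    def test_unexpected_pair_class(self, f_set, r_set):
        from pairbc import assign_pairs

        partial = assign_pairs(f_set, r_set, ["only_one"])  # uses (F1,R1) only
        read = ReadRecord(id="r1", seq=f_set.seqs[1] + "A" * 25,
                          mate_seq=r_set.seqs[1])
        res = decode_read(read, partial, f_set, r_set, ReadLayout())
        assert not res.assigned and res.failure_class == "unexpected_pair"

    def test_missing_mate_is_malformed_not_crash(self, f_set, r_set, sheet):
        read = ReadRecord(id="r1", seq=f_set.seqs[0] + "A" * 25, mate_seq=None)
        res = decode_read(read, sheet, f_set, r_set, ReadLayout())
        assert res.failure_class == "malformed"

    def test_sequential_decode_skips_r_when_f_fails(self, f_set, r_set, sheet):
        read = ReadRecord(id="r1", seq="N" * 0 + "GGGGGG" + "A" * 25,
                          mate_seq=r_set.seqs[0])
        # force F failure by choosing a window far from all F barcodes
        from pairbc.colorspace import hamming_nt

        if all(hamming_nt("GGGGGG", s) >= 2 for s in f_set.seqs):
            res = decode_read(read, sheet, f_set, r_set, ReadLayout())
            if res.f_status != "unique":
                assert res.r_status == "none" and res.r_id is None

    def test_single_read_fixed_offset_mode(self, f_set, r_set, sheet):
        layout = ReadLayout(r_source="read", r_span=(6, 12))
        insert = "ACGTTGCAGTCAGGATCCAGT"
        read = ReadRecord(id="r1", seq=f_set.seqs[0] + r_set.seqs[0] + insert)
        res = decode_read(read, sheet, f_set, r_set, layout)
        assert res.assigned and res.sample_id == sheet.entries[0][0]


class TestDemuxRun:
    def test_zero_reads_zero_stats(self, f_set, r_set, sheet):
        stats = demux_run([], sheet, f_set, r_set, ReadLayout())
        assert stats.total == 0 and stats.both_decoded == 0
        assert int(stats.pair_counts.values.sum()) == 0

    def test_clean_simulated_run_conserves_and_assigns_all(self, tmp_path):
        cfg = SimConfig(mean_reads=120, depth_sigma=0.3, n_de=0, seed=5)
        reads, truth, f_set, r_set, sheet, _ = simulate_run(cfg)
        layout = ReadLayout(adaptor3=cfg.adaptor3)
        stats, results = demux_run(
            reads, sheet, f_set, r_set, layout,
            out_dir=str(tmp_path), collect_results=True,
        )
        assert stats.total == len(reads)
        assert stats.both_decoded == stats.total  # error 0, junk 0
        # per-pair counts == planted per-sample depths
        pair_of = {s: (f, r) for s, f, r in sheet.entries}
        for s in truth.counts.columns:
            f, r = pair_of[s]
            assert stats.pair_counts.loc[f, r] == truth.counts[s].sum()
        # arithmetic invariants
        assert stats.both_decoded == int(stats.pair_counts.values.sum())
        assert stats.assigned + sum(stats.failures.values()) == stats.total
        # conservation across output sinks
        import glob

        n_out = 0
        for path in glob.glob(str(tmp_path / "*.fasta")):
            n_out += sum(1 for line in open(path) if line.startswith(">"))
        assert n_out == stats.total
        # every insert written equals a planted mature sequence
        for res in results:
            assert res.insert is not None

    def test_sequential_rate_identity(self):
        cfg = SimConfig(mean_reads=100, depth_sigma=0.2, n_de=0,
                        junk_fraction=0.3, seed=6)
        reads, truth, f_set, r_set, sheet, _ = simulate_run(cfg)
        stats = demux_run(reads, sheet, f_set, r_set, ReadLayout(adaptor3=cfg.adaptor3))
        assert stats.both_decoded <= stats.f_decoded <= stats.total
        if stats.f_decoded:
            lhs = stats.both_decoded / stats.total
            rhs = (stats.f_decoded / stats.total) * (
                stats.r_decoded_of_f / stats.f_decoded
            )
            assert lhs == pytest.approx(rhs)

    def test_color_space_run_decodes(self):
        cfg = SimConfig(mean_reads=60, depth_sigma=0.2, n_de=0, space="color", seed=7)
        reads, truth, f_set, r_set, sheet, _ = simulate_run(cfg)
        layout = ReadLayout(space="color", adaptor3=cfg.adaptor3)
        stats, results = demux_run(reads, sheet, f_set, r_set, layout,
                                   collect_results=True)
        assert stats.both_decoded == stats.total
        for res in results:
            assert res.sample_id == truth.read_truth[res.read_id]

    def test_failure_classes_cover_all_bins(self):
        assert set(FAILURE_CLASSES) >= {
            "f_none", "r_none", "unexpected_pair", "malformed",
        }
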