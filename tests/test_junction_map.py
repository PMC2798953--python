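"""Mapper and MMES scoring: oracle equivalence, score properties, SAM."""

import itertools

import pandas as pd
import pytest

from mmes_splice.junction_map import (
    JunctionAlignment,
    admissible_offsets,
    alignments_to_frame,
    compute_mmes,
    export_sam,
    ingest_sam,
    map_reads,
    map_reads_frame,
    mmes_histogram,
)


from conftest import naive_oracle


class TestMapperOracle:
    def test_equivalence_on_mixed_fixture(self, mapping_fixture):
        """Built-in mapper == exhaustive Hamming scan, all placements."""
        reads, db = mapping_fixture
        frame = map_reads_frame(reads, db, max_mismatch=2, hit_policy="all")
        got = sorted(
            zip(frame.read_id, frame.junction_id, frame.offset, frame.M,
                frame.L_mismatch)
        )
        assert got == naive_oracle(reads, db, 2, db.min_overlap)

    def test_higher_mismatch_budget(self, mapping_fixture):
        reads, db = mapping_fixture
        frame = map_reads_frame(reads[:120], db, max_mismatch=3, hit_policy="all")
        got = sorted(
            zip(frame.read_id, frame.junction_id, frame.offset, frame.M,
                frame.L_mismatch)
        )
        assert got == naive_oracle(reads[:120], db, 3, db.min_overlap)

    def test_exact_unique_hit(self, mapping_fixture):
        _, db = mapping_fixture
        rec = db.records[7]
        read = [("r", rec.sequence[9 : 9 + 25])]
        frame = map_reads_frame(read, db, hit_policy="best")
        exact = frame[frame.M == 0]
        assert len(exact) == 1
        row = exact.iloc[0]
        assert (row["junction_id"], row["offset"], bool(row["is_unique"])) == (
            rec.junction_id, 9, len(frame) == 1,
        )

    def test_unmappable_read_yields_nothing(self, mapping_fixture):
        _, db = mapping_fixture
        # a homopolymer is > 2 mismatches from every random 25-mer window
        # in this fixture (verified by the oracle)
        read = [("r", "A" * 25)]
        assert naive_oracle(read, db, 2, 4) == []
        assert map_reads_frame(read, db).empty

    def test_read_length_mismatch_rejected(self, mapping_fixture):
        _, db = mapping_fixture
        with pytest.raises(ValueError):
            map_reads_frame([("r", "ACGT" * 5)], db)

    def test_n_bases_count_as_mismatches(self, mapping_fixture):
        _, db = mapping_fixture
        rec = db.records[0]
        window = rec.sequence[5 : 5 + 25]
        read = [("r", "NNN" + window[3:])]
        frame = map_reads_frame(read, db, max_mismatch=3, hit_policy="all")
        sub = frame[(frame.junction_id == rec.junction_id) & (frame.offset == 5)]
        assert len(sub) == 1 and sub.iloc[0].M == 3

    def test_best_policy_keeps_only_minimum(self, mapping_fixture):
        reads, db = mapping_fixture
        best = map_reads_frame(reads, db, hit_policy="best")
        allf = map_reads_frame(reads, db, hit_policy="all")
        min_m = allf.groupby("read_id").M.min()
        assert (best.M.to_numpy() == min_m.loc[best.read_id].to_numpy()).all()
        # every best placement appears in the all-placements output
        key = ["read_id", "junction_id", "offset"]
        merged = best.merge(allf[key], on=key, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()


class TestMMES:
    def test_centered_exact_read(self):
        aln = JunctionAlignment("r", "j", 9, 25, 12, 13, 0, 0, (), True)
        assert compute_mmes(aln) == 12

    def test_boundary_read_right_arm_mismatches(self):
        aln = JunctionAlignment("r", "j", 0, 25, 21, 4, 0, 2, (22, 24), True)
        assert compute_mmes(aln) == 2

    def test_long_arm_mismatch_invariance(self):
        with_mm = JunctionAlignment("r", "j", 8, 25, 13, 12, 1, 0, (3,), True)
        without = JunctionAlignment("r", "j", 8, 25, 13, 12, 0, 0, (), True)
        assert compute_mmes(with_mm) == compute_mmes(without) == 12

    def test_exhaustive_bounds_and_monotonicity(self):
        """All placements of a 25 bp read on a 42-mer with <= 2 mismatches:
        bounds min_overlap - M <= N <= 12, and adding a mismatch anywhere
        never increases the score."""
        rl, arm, mo = 25, 21, 4
        for off in admissible_offsets(rl, arm, mo):
            l_arm = arm - off
            r_arm = rl - l_arm
            assert 0 <= off <= rl - 2 * mo  # 18 admissible offsets

            def score(positions):
                lm = sum(1 for p in positions if p < l_arm)
                return min(l_arm - lm, r_arm - (len(positions) - lm))

            for k in (0, 1, 2):
                for pos in itertools.combinations(range(rl), k):
                    n = score(pos)
                    assert mo - k <= n <= rl // 2
                    if k == 0:
                        assert n >= mo
                    # monotonicity: removing any one mismatch cannot lower N
                    for drop in range(k):
                        assert score(pos[:drop] + pos[drop + 1 :]) >= n

    def test_admissible_offset_count(self):
        assert len(admissible_offsets(25, 21, 4)) == 25 - 2 * 4 + 1 == 18

    def test_mapped_scores_match_direct_formula(self, mapping_fixture):
        reads, db = mapping_fixture
        alns = map_reads(reads[:60], db, hit_policy="all")
        frame = map_reads_frame(reads[:60], db, hit_policy="all")
        assert len(alns) == len(frame)
        for a, n in zip(alns, frame.N):
            assert compute_mmes(a) == n
            assert a.L_arm + a.R_arm == a.read_len
            assert a.L_mismatch == sum(1 for p in a.mismatch_positions if p < a.L_arm)


class TestHistogram:
    def test_empty_input_all_zero(self):
        h = mmes_histogram(pd.DataFrame(columns=["N", "M", "is_unique"]), 25, 4, 2)
        assert (h.to_numpy() == 0).all()
        assert list(h.index) == list(range(2, 13))

    def test_point_mass(self):
        frame = pd.DataFrame({"N": [12] * 10, "M": [0] * 10, "is_unique": True})
        h = mmes_histogram(frame, 25, 4, 2)
        assert h.loc[12, 0] == 10 and h.to_numpy().sum() == 10

    def test_recount_matches_naive_loop(self, mapping_fixture):
        reads, db = mapping_fixture
        frame = map_reads_frame(reads, db, hit_policy="all")
        h = mmes_histogram(frame, 25, 4, 2)
        assert h.to_numpy().sum() == len(frame)
        for (n, m), group in frame.groupby(["N", "M"]):
            assert h.loc[n, m] == len(group)

    def test_unique_stratification(self, mapping_fixture):
        reads, db = mapping_fixture
        frame = map_reads_frame(reads, db, hit_policy="best")
        h_all = mmes_histogram(frame, 25, 4, 2, unique_only=False)
        h_uniq = mmes_histogram(frame, 25, 4, 2, unique_only=True)
        assert h_uniq.to_numpy().sum() == frame.is_unique.sum()
        assert (h_all.to_numpy() >= h_uniq.to_numpy()).all()


class TestSamInterchange:
    def test_round_trip_identity(self, mapping_fixture, tmp_path):
        reads, db = mapping_fixture
        frame = map_reads_frame(reads[:150], db, hit_policy="best")
        path = str(tmp_path / "out.sam")
        export_sam(frame, reads[:150], db, path)
        back = alignments_to_frame(ingest_sam(path, db))
        a = frame.sort_values(["read_id", "junction_id", "offset"]).reset_index(drop=True)
        b = back.sort_values(["read_id", "junction_id", "offset"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b.astype(a.dtypes.to_dict()))

    def test_window_violation_dropped(self, mapping_fixture, tmp_path):
        _, db = mapping_fixture
        rec = db.records[0]
        sam = str(tmp_path / "bad.sam")
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n")
            for r in db.records:
                fh.write(f"@SQ\tSN:{r.junction_id}\tLN:42\n")
            # offset 0 -> R_arm 4: at the boundary of a 4 bp overlap, but
            # below a stricter 5 bp requirement and therefore dropped
            fh.write(
                f"edge\t0\t{rec.junction_id}\t1\t255\t25M\t*\t0\t0\t"
                f"{rec.sequence[:25]}\tIIIIIIIIIIIIIIIIIIIIIIIII\tNM:i:0\n"
            )
            fh.write(
                f"mid\t0\t{rec.junction_id}\t10\t255\t25M\t*\t0\t0\t"
                f"{rec.sequence[9:34]}\tIIIIIIIIIIIIIIIIIIIIIIIII\tNM:i:0\n"
            )
        alns = ingest_sam(sam, db)  # default overlap: both admissible
        assert [a.read_id for a in alns] == ["edge", "mid"]
        assert alns[0].L_arm == 21 and alns[0].R_arm == 4 and alns[0].M == 0
        with pytest.warns(UserWarning, match="dropped"):
            strict = ingest_sam(sam, db, min_overlap=5)
        assert [a.read_id for a in strict] == ["mid"]

    def test_gapped_and_untagged_skipped(self, mapping_fixture, tmp_path):
        _, db = mapping_fixture
        rec = db.records[1]
        sam = str(tmp_path / "gapped.sam")
        with open(sam, "w") as fh:
            fh.write(f"@SQ\tSN:{rec.junction_id}\tLN:42\n")
            fh.write(
                f"gap\t0\t{rec.junction_id}\t3\t255\t10M2D15M\t*\t0\t0\t"
                f"{rec.sequence[2:27]}\t*\tNM:i:2\n"
            )
            fh.write(
                f"untagged\t0\t{rec.junction_id}\t3\t255\t25M\t*\t0\t0\t"
                f"{rec.sequence[2:27]}\t*\n"
            )
        with pytest.warns(UserWarning, match="dropped"):
            assert ingest_sam(sam, db) == []
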