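"""Guide-anchored scanning, BIME pairing and planted-truth genomes."""

import pytest

from conftest import brute_force_scan, random_dna
from reptron.genome_scan import (
    PRESETS,
    BimeHit,
    RepHit,
    ScanParams,
    bimes_to_bed,
    hits_to_bed,
    hits_to_gff3,
    pair_bimes,
    plant_reps,
    scan_genome,
)
from reptron.rep_model import REP_EC_Y, REP_SM, FoldResult, build_rep_template, revcomp

GROUP3 = PRESETS["group3"]
GROUP2 = PRESETS["group2"]


def _hit_set(hits):
    return {(h.start, h.end, h.strand) for h in hits}


def _dummy_hit(start, end, strand, seq_id="chr"):
    fold = FoldResult(folded=True, stem_len=8, loop_len=3, start=0, end=19)
    return RepHit(seq_id=seq_id, start=start, end=end, strand=strand,
                  fold=fold, group="group3", spacer_len=0)


class TestScan:
    def test_planted_sm_rep_found_at_exact_interval(self):
        record, truth = plant_reps(2000, REP_SM, n_copies=1, seed=5)
        hits = scan_genome([record], GROUP3)
        row = truth.iloc[0]
        assert (row.start, row.end, row.strand) in _hit_set(hits)

    def test_planted_irep_reported_on_minus_strand(self):
        elem = build_rep_template(REP_SM, seed=9).seq
        genome = "A" * 60 + revcomp(elem) + "A" * 60
        hits = scan_genome([("g", genome)], GROUP3)
        assert _hit_set(hits) == {(60, 60 + len(elem), "-")}
        assert hits[0].kind == "iREP"

    def test_full_recall_of_planted_copies(self):
        record, truth = plant_reps(8000, REP_SM, n_copies=10, seed=1)
        found = _hit_set(scan_genome([record], GROUP3))
        for row in truth.itertuples():
            assert (row.start, row.end, row.strand) in found

    def test_group2_recall_with_bulged_template(self):
        record, truth = plant_reps(6000, REP_EC_Y, n_copies=6, seed=2)
        found = _hit_set(scan_genome([record], GROUP2))
        for row in truth.itertuples():
            assert (row.start, row.end, row.strand) in found

    def test_precision_on_seeded_background(self):
        record, truth = plant_reps(20000, REP_SM, n_copies=8, n_bimes=2, seed=3)
        hits = scan_genome([record], GROUP3)
        truth_set = {(r.start, r.end, r.strand) for r in truth.itertuples()}
        tp = sum(1 for h in hits if (h.start, h.end, h.strand) in truth_set)
        assert tp == len(truth_set)  # 100% recall
        precision = tp / len(hits)
        assert precision >= 0.8  # random background yields few chance hits

    def test_matches_bruteforce_oracle_random_sequences(self, rng):
        for _ in range(3):
            seq = random_dna(rng, 3000)
            for preset in (GROUP2, GROUP3):
                got = _hit_set(scan_genome([("s", seq)], preset))
                expected = brute_force_scan(
                    seq, guide=preset.guide, spacer_range=preset.spacer_range,
                    min_stem=preset.min_stem, loop_range=preset.loop_range,
                    max_mismatches=preset.max_mismatches, max_stem=preset.max_stem,
                )
                assert got == expected

    def test_matches_bruteforce_oracle_planted_genome(self):
        record, _ = plant_reps(5000, REP_SM, n_copies=5, n_bimes=1, seed=11)
        seq = str(record.seq)
        got = _hit_set(scan_genome([record], GROUP3))
        expected = brute_force_scan(
            seq, spacer_range=GROUP3.spacer_range, min_stem=GROUP3.min_stem,
            loop_range=GROUP3.loop_range, max_mismatches=GROUP3.max_mismatches,
            max_stem=GROUP3.max_stem,
        )
        assert got == expected

    def test_strand_symmetry(self, rng):
        record, _ = plant_reps(4000, REP_SM, n_copies=4, seed=7)
        seq = str(record.seq)
        fwd = _hit_set(scan_genome([("g", seq)], GROUP3))
        rev = _hit_set(scan_genome([("g", revcomp(seq))], GROUP3))
        L = len(seq)
        flipped = {(L - e, L - s, "+" if strand == "-" else "-")
                   for s, e, strand in rev}
        assert fwd == flipped

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            scan_genome([], GROUP3)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ScanParams(min_stem=2)
        with pytest.raises(ValueError):
            ScanParams(loop_range=(5, 3))
        with pytest.raises(ValueError):
            ScanParams(min_stem=10, max_stem=8)


class TestBimes:
    def test_adjacent_inverse_pair_forms_bime(self):
        hits = [_dummy_hit(100, 130, "+"), _dummy_hit(140, 170, "-")]
        bimes = pair_bimes(hits, max_linker=50)
        assert len(bimes) == 1
        assert bimes[0].linker_len == 10
        assert bimes[0].interval == (100, 170)

    def test_same_orientation_pair_rejected(self):
        hits = [_dummy_hit(100, 130, "+"), _dummy_hit(140, 170, "+")]
        assert pair_bimes(hits, max_linker=50) == []

    def test_long_linker_rejected(self):
        hits = [_dummy_hit(100, 130, "+"), _dummy_hit(330, 360, "-")]
        assert pair_bimes(hits, max_linker=50) == []

    def test_greedy_each_hit_in_at_most_one_bime(self):
        hits = [
            _dummy_hit(0, 20, "+"),
            _dummy_hit(30, 50, "-"),
            _dummy_hit(60, 80, "+"),
        ]
        bimes = pair_bimes(hits, max_linker=50)
        assert len(bimes) == 1
        assert bimes[0].rep.start == 0

    def test_planted_bimes_recovered(self):
        record, truth = plant_reps(6000, REP_SM, n_copies=0, n_bimes=3, seed=13)
        hits = scan_genome([record], GROUP3)
        bimes = pair_bimes(hits, max_linker=50)
        assert len(bimes) == 3
        for b in bimes:
            assert b.rep.strand == "+" and b.irep.strand == "-"
            sub = truth[truth.start == b.rep.start]
            assert len(sub) == 1 and int(sub.iloc[0].bime_id) > 0

    def test_invalid_bime_construction(self):
        with pytest.raises(ValueError):
            BimeHit(rep=_dummy_hit(0, 20, "+"), irep=_dummy_hit(30, 50, "+"),
                    linker_len=10)
        with pytest.raises(ValueError):
            BimeHit(rep=_dummy_hit(0, 20, "+"),
                    irep=_dummy_hit(30, 50, "-", seq_id="other"), linker_len=10)


class TestPlant:
    def test_same_seed_identical_genome(self):
        a, ta = plant_reps(3000, REP_SM, n_copies=3, seed=17)
        b, tb = plant_reps(3000, REP_SM, n_copies=3, seed=17)
        assert str(a.seq) == str(b.seq)
        assert ta.equals(tb)

    def test_overcrowded_genome_rejected(self):
        with pytest.raises(ValueError):
            plant_reps(100, REP_SM, n_copies=10, seed=0)

    def test_truth_table_matches_genome(self):
        record, truth = plant_reps(4000, REP_SM, n_copies=4, n_bimes=1, seed=19)
        seq = str(record.seq)
        assert len(seq) == 4000
        for row in truth.itertuples():
            planted = seq[row.start : row.end]
            if row.strand == "-":
                planted = revcomp(planted)
            assert planted.startswith("GTAG")
            assert len(planted) == REP_SM.total_len


class TestOutputs:
    def test_bed_round_trip_lossless(self):
        record, _ = plant_reps(3000, REP_SM, n_copies=3, seed=23)
        hits = scan_genome([record], GROUP3)
        lines = hits_to_bed(hits).strip().splitlines()
        assert len(lines) == len(hits)
        for line, h in zip(lines, hits):
            chrom, start, end, name, score, strand = line.split("\t")
            assert (int(start), int(end), strand) == (h.start, h.end, h.strand)
            assert name == h.kind and int(score) == h.fold.stem_len

    def test_gff3_one_based_inclusive(self):
        record, _ = plant_reps(2000, REP_SM, n_copies=2, seed=29)
        hits = scan_genome([record], GROUP3)
        gff = hits_to_gff3(hits).splitlines()
        assert gff[0] == "##gff-version 3"
        for line, h in zip(gff[1:], hits):
            fields = line.split("\t")
            assert (int(fields[3]), int(fields[4])) == (h.start + 1, h.end)

    def test_bime_bed_spans_both_elements(self):
        hits = [_dummy_hit(100, 130, "+"), _dummy_hit(140, 170, "-")]
        line = bimes_to_bed(pair_bimes(hits, 50)).strip()
        assert line.split("\t")[:4] == ["chr", "100", "170", "BIME"]
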