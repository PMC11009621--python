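import numpy as np
import pytest

from retroinvade import ht_donor, scenarios, synthetic
from retroinvade.ht_donor import RepeatHit
from retroinvade.io_utils import revcomp

from .oracles import merge_with_gap


def hit(start, end, fam="fam", strand="+", score=100.0, div=0.0, span=None,
        contig="c1", assembly="a1"):
    return RepeatHit(
        assembly_id=assembly, contig=contig, start=start, end=end,
        strand=strand, family_id=fam, score=score, divergence=div,
        consensus_span=span or (0, end - start),
    )


class TestParseRepeatTable:
    HEADER = "h1\nh2\n\n"

    def test_coordinates_become_zero_based_half_open(self, tmp_path):
        row = "1234 5.10 0.0 0.0 contigA 1001 1500 (100) + blood LTR/Gypsy 1 500 (0) 1\n"
        path = tmp_path / "t.out"
        path.write_text(self.HEADER + row)
        (h,) = ht_donor.parse_repeat_table(path)
        assert (h.start, h.end) == (1000, 1500)
        assert h.divergence == pytest.approx(0.051)
        assert h.consensus_span == (0, 500)

    def test_complement_orientation_becomes_minus_strand(self, tmp_path):
        row = "900 2.0 0.0 0.0 contigA 51 250 (0) C blood LTR/Gypsy (10) 400 201 1\n"
        path = tmp_path / "t.out"
        path.write_text(self.HEADER + row)
        (h,) = ht_donor.parse_repeat_table(path)
        assert h.strand == "-"
        assert (h.start, h.end) == (50, 250)
        assert h.consensus_span == (200, 400)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "t.out"
        path.write_text(self.HEADER + "not a valid row\n")
        with pytest.raises(ValueError, match="line 4"):
            ht_donor.parse_repeat_table(path)

    def test_round_trip(self, tmp_path):
        hits = [
            hit(100, 600, strand="+", score=450, div=0.021, span=(0, 500)),
            hit(900, 1200, strand="-", score=250, div=0.12, span=(100, 400)),
        ]
        path = tmp_path / "rt.out"
        ht_donor.write_repeat_table(hits, path)
        back = ht_donor.parse_repeat_table(path, assembly_id="a1")
        for orig, parsed in zip(hits, back):
            assert (parsed.start, parsed.end) == (orig.start, orig.end)
            assert parsed.strand == orig.strand
            assert parsed.consensus_span == orig.consensus_span
            assert parsed.divergence == pytest.approx(orig.divergence, abs=1e-4)


class TestFindHits:
    def test_exact_planted_copy_single_full_score_hit(self, library):
        fam = library.families[0]
        rng = np.random.default_rng(1)
        backbone = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        contig = backbone[:1500] + fam.sequence + backbone[1500:]
        hits = [
            h for h in ht_donor.find_hits({"c": contig}, library, min_score=50)
            if h.family_id == fam.family_id
        ]
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (1500, 1500 + fam.length)
        assert h.divergence == 0.0
        assert h.score == fam.length

    def test_minus_strand_copy_found(self, library):
        fam = library.families[1]
        rng = np.random.default_rng(2)
        backbone = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        contig = backbone[:1000] + revcomp(fam.sequence) + backbone[1000:]
        hits = [
            h for h in ht_donor.find_hits({"c": contig}, library, min_score=50)
            if h.family_id == fam.family_id
        ]
        assert any(
            h.strand == "-" and (h.start, h.end) == (1000, 1000 + fam.length)
            for h in hits
        )

    def test_diverged_copy_divergence_estimated(self, library):
        fam = library.families[0]
        rng = np.random.default_rng(3)
        mutated = synthetic._mutate_exact(fam.sequence, round(0.1 * fam.length), rng)
        backbone = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        contig = backbone[:900] + mutated + backbone[900:]
        hits = ht_donor.defragment(
            [h for h in ht_donor.find_hits({"c": contig}, library, min_score=50)
             if h.family_id == fam.family_id]
        )
        total = sum(h.length for h in hits)
        assert total >= 0.9 * fam.length
        weighted = sum(h.divergence * h.length for h in hits) / total
        assert 0.08 <= weighted <= 0.12

    def test_no_homology_no_hits(self, library):
        rng = np.random.default_rng(4)
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        assert ht_donor.find_hits({"c": contig}, library, min_score=50) == []


class TestDefragment:
    def test_colinear_fragments_within_gap_merge(self):
        frags = [
            hit(1000, 1400, span=(0, 400), score=400),
            hit(1480, 1900, span=(450, 870), score=420),
        ]
        (merged,) = ht_donor.defragment(frags, max_gap=100)
        assert (merged.start, merged.end) == (1000, 1900)
        assert merged.score == 820
        assert merged.consensus_span == (0, 870)

    def test_distant_fragments_stay_separate(self):
        frags = [
            hit(1000, 1400, span=(0, 400)),
            hit(1550, 1900, span=(450, 800)),
        ]
        assert len(ht_donor.defragment(frags, max_gap=100)) == 2

    def test_tandem_copies_not_merged_when_colinearity_required(self):
        frags = [
            hit(1000, 1900, span=(0, 900), score=900),
            hit(1950, 2850, span=(0, 900), score=900),
        ]
        assert len(ht_donor.defragment(frags, max_gap=100)) == 2
        # the distance-only mode of the original merge script does merge them
        assert len(ht_donor.defragment(frags, max_gap=100, require_colinear=False)) == 1

    def test_merged_divergence_is_length_weighted(self):
        frags = [
            hit(0, 100, span=(0, 100), div=0.10, score=80),
            hit(150, 450, span=(120, 420), div=0.02, score=280),
        ]
        (merged,) = ht_donor.defragment(frags, max_gap=100)
        assert merged.divergence == pytest.approx((0.10 * 100 + 0.02 * 300) / 400)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        frags = []
        pos = 0
        for i in range(30):
            pos += int(rng.integers(0, 300))
            length = int(rng.integers(50, 400))
            frags.append(hit(pos, pos + length, span=(0, length), score=length))
            pos += length
        once = ht_donor.defragment(frags, max_gap=100)
        twice = ht_donor.defragment(once, max_gap=100)
        assert [(h.start, h.end) for h in once] == [(h.start, h.end) for h in twice]

    def test_matches_interval_union_oracle(self):
        rng = np.random.default_rng(6)
        frags = []
        pos = 0
        cpos = 0
        for i in range(40):
            pos += int(rng.integers(0, 250))
            length = int(rng.integers(40, 300))
            frags.append(
                hit(pos, pos + length, span=(cpos, cpos + length), score=length)
            )
            pos += length
            cpos += length + 10
        merged = ht_donor.defragment(frags, max_gap=100)
        expected = merge_with_gap([(h.start, h.end) for h in frags], 100)
        assert [(h.start, h.end) for h in merged] == expected


class TestSimilarity:
    def test_donor_scores_one_and_ladder_decreases(self):
        order, s, truth = scenarios.donor_ladder(seed=7)
        donor_row = s.loc[truth["donor"]]
        assert np.allclose(donor_row.to_numpy(), 1.0)
        for fam in s.columns:
            vals = s[fam].to_numpy()
            assert np.all(np.diff(vals) < 0)

    def test_assembly_without_hits_scores_zero(self):
        table = ht_donor.similarity_scores(
            {"a1": [hit(0, 500, score=500)], "a2": []}
        )
        assert table.s.loc["a1", "fam"] == 1.0
        assert table.s.loc["a2", "fam"] == 0.0
        assert table.best_assembly["fam"] == "a1"

    def test_scale_invariance(self):
        hits1 = {"a1": [hit(0, 500, score=500)], "a2": [hit(0, 300, score=300)]}
        hits2 = {
            "a1": [hit(0, 500, score=5000)],
            "a2": [hit(0, 300, score=3000)],
        }
        t1 = ht_donor.similarity_scores(hits1)
        t2 = ht_donor.similarity_scores(hits2)
        assert np.allclose(t1.s.to_numpy(), t2.s.to_numpy())


class TestLengthDivergence:
    def test_recent_and_degraded_clusters(self, library):
        assemblies, _ = synthetic.build_species_panel(library, [0.0, 0.25], seed=8)
        rows = []
        for name, contigs in assemblies.items():
            hits = ht_donor.defragment(
                ht_donor.find_hits(contigs, library, assembly_id=name)
            )
            rows.append(ht_donor.length_divergence_table(hits))
        import pandas as pd

        table = pd.concat(rows, ignore_index=True)
        recent = table[table["divergence"] < 0.01]
        old = table[table["divergence"] > 0.15]
        assert (recent["length"] >= 0.9 * 900).any()
        assert len(old) > 0

    def test_empty_hits_empty_table(self):
        table = ht_donor.length_divergence_table([])
        assert table.empty


class TestExtraction:
    def test_full_length_window_selects_planted_copy(self, library):
        fam = library.families[0]
        rng = np.random.default_rng(9)
        backbone = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        contig = backbone[:700] + revcomp(fam.sequence) + backbone[700:]
        hits = ht_donor.defragment(
            ht_donor.find_hits({"c": contig}, library, min_score=50)
        )
        records = ht_donor.extract_full_length(
            [h for h in hits if h.family_id == fam.family_id],
            {"c": contig},
            (800, 1000),
        )
        assert len(records) == 1
        name, seq = records[0]
        assert seq == fam.sequence  # re-oriented to consensus strand

    def test_short_fragment_excluded(self):
        records = ht_donor.extract_full_length(
            [hit(0, 300, span=(0, 300))], {"c1": "A" * 1000}, (800, 1000)
        )
        assert records == []

    def test_out_of_bounds_coordinates_error(self):
        with pytest.raises(ValueError, match="bounds"):
            ht_donor.extract_full_length(
                [hit(0, 900, span=(0, 900))], {"c1": "A" * 500}, (800, 1000)
            )


class TestLtrAge:
    def test_identical_ltrs_age_zero(self):
        seq = "ACGT" * 100 + "TTTT" * 50 + "ACGT" * 100
        assert ht_donor.ltr_age(seq, 400, 5e-9) == 0.0

    def test_closed_form(self):
        # d = 0.01 at rate 5e-9 / site / year -> 1.0 My
        ltr = "A" * 400
        mutated = "C" * 4 + "A" * 396
        seq = ltr + "G" * 200 + mutated
        age = ht_donor.ltr_age(seq, 400, 5e-9)
        assert age == pytest.approx(0.01 / (2 * 5e-9))
        assert age == pytest.approx(1.0e6)

    def test_planted_divergence_recovered_exactly(self, library):
        fam = library.families[0]
        rng = np.random.default_rng(10)
        ltr = fam.sequence[: fam.ltr_length]
        n_mut = 12
        mutated = synthetic._mutate_exact(ltr, n_mut, rng)
        insertion = ltr + fam.sequence[fam.ltr_length : -fam.ltr_length] + mutated
        d = n_mut / fam.ltr_length
        rate = 5e-9
        assert ht_donor.ltr_age(insertion, fam.ltr_length, rate) == pytest.approx(
            d / (2 * rate)
        )

    def test_invalid_ltr_length_error(self):
        with pytest.raises(ValueError):
            ht_donor.ltr_age("ACGT" * 10, 25, 5e-9)
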