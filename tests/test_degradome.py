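"""Unit and property tests of degradome cleavage calling."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from photosrna.core_io import DegradomeProfile, SrnaCatalogEntry, Transcript, revcomp
from photosrna.degradome import (
    DegradomeParams,
    allen_score,
    call_targets,
    categorize,
    cleavage_pvalue,
    dinucleotide_shuffle,
    expected_cleavage_position,
    find_candidate_sites,
    site_signal,
    tplot_data,
)

SRNA = "TGGAGAAGCAGGGCACGTGCA"  # 21 nt


def _mutate(seq, idx, base):
    return seq[:idx] + base + seq[idx + 1:]


class TestAllenScore:
    def test_perfect_complement_scores_zero(self):
        assert allen_score(SRNA, revcomp(SRNA))[0] == 0.0

    def test_gu_wobble_outside_seed(self):
        site = revcomp(SRNA)
        srna_pos = 19  # a G outside the 2-13 seed region
        assert SRNA[srna_pos - 1] == "G"
        site_idx = len(SRNA) - srna_pos  # antiparallel partner
        score, states = allen_score(SRNA, _mutate(site, site_idx, "T"))
        assert score == 0.5
        assert states[srna_pos - 1] == "wobble"

    def test_mismatch_in_seed_doubled(self):
        site = revcomp(SRNA)
        srna_pos = 10
        site_idx = len(SRNA) - srna_pos
        # replace the partner with the sRNA base itself: never complementary
        score, states = allen_score(SRNA, _mutate(site, site_idx, SRNA[srna_pos - 1]))
        assert score == 2.0
        assert states[srna_pos - 1] == "mismatch"

    def test_bulge_penalty(self):
        # single-position target bulge opposite sRNA position 17 (weight 1)
        srna_gapped = SRNA[:16] + "-" + SRNA[16:]
        site = revcomp(srna_gapped.replace("-", "A"))
        score, states = allen_score(srna_gapped, site)
        assert states[16] == "bulge"
        assert score == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            allen_score("", "")

    @given(st.text(alphabet="ACGT", min_size=18, max_size=24))
    def test_score_symmetry_revcomp(self, s):
        assert allen_score(s, revcomp(s))[0] == 0.0


class TestFindCandidateSites:
    def test_exact_complement_found(self):
        flank = "A" * 40
        tx = Transcript("t", flank + revcomp(SRNA) + flank)
        sites = find_candidate_sites(SRNA, tx)
        perfect = [s for s in sites if s.allen_score == 0.0]
        assert len(perfect) == 1
        s = perfect[0]
        assert (s.start, s.end) == (40, 61)
        assert s.expected_cleavage_position == 40 + 21 - 9

    def test_no_site_under_cutoff(self):
        tx = Transcript("t", "A" * 100)
        assert find_candidate_sites("GCGCGCGCGCGCGCGCGCGCG", tx, max_score=3.0) == []

    def test_seed_mismatch_site_cutoff_behavior(self):
        """Oracle check: brute-force score of every window locates the
        planted single-seed-mismatch site (score 2) at cutoff 3, not 1."""
        site = _mutate(revcomp(SRNA), 11, SRNA[9])  # sRNA position 10 mismatch
        tx = Transcript("t", "ACGT" * 10 + site + "ACGT" * 10)
        brute = [
            (allen_score(SRNA, tx.sequence[i:i + 21])[0], i)
            for i in range(len(tx) - 20)
        ]
        best_score, best_start = min(brute)
        assert best_score == 2.0
        found3 = find_candidate_sites(SRNA, tx, max_score=3.0)
        assert [s.start for s in found3 if s.allen_score == 2.0] == [best_start]
        assert find_candidate_sites(SRNA, tx, max_score=1.0) == []

    def test_overlap_dedup_keeps_minimum_score(self):
        tx = Transcript("t", "A" * 40 + revcomp(SRNA) + "A" * 40)
        sites = find_candidate_sites(SRNA, tx, max_score=8.0)
        for a, b in zip(sites, sites[1:]):
            assert b.start >= a.end


class TestCategorize:
    @pytest.mark.parametrize(
        "profile,pos,expected",
        [
            ([0, 9, 2, 2, 0], 2, 0),   # unique maximum
            ([5, 5, 1], 1, 1),          # tied maximum
            ([1, 0, 0], 1, 4),          # single read
            ([9, 3, 2, 2, 0], 2, 2),    # above median, below max
            ([9, 3, 2, 2, 0], 3, 3),    # at/below median
            ([1, 9, 0], 3, None),       # zero count: no category
        ],
    )
    def test_examples(self, profile, pos, expected):
        assert categorize(DegradomeProfile("t", profile), pos) == expected

    def test_position_outside_transcript(self):
        with pytest.raises(IndexError):
            categorize(DegradomeProfile("t", [1, 2]), 3)

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=30))
    def test_partition_property(self, counts):
        """Every nonzero position gets exactly one category; category 0
        implies a strictly unique maximum."""
        if sum(counts) == 0:
            return
        prof = DegradomeProfile("t", counts)
        arr = np.asarray(counts)
        for pos0, c in enumerate(counts):
            cat = categorize(prof, pos0 + 1)
            if c == 0:
                assert cat is None
            else:
                assert cat in (0, 1, 2, 3, 4)
                if cat == 0:
                    assert c == arr.max() and (arr == c).sum() == 1


class TestDinucleotideShuffle:
    @given(st.text(alphabet="ACGT", min_size=5, max_size=30))
    def test_preserves_dinucleotide_composition(self, seq):
        rng = np.random.default_rng(0)
        shuf = dinucleotide_shuffle(seq, rng)
        assert len(shuf) == len(seq)
        assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))
        assert shuf[0] == seq[0]

    def test_seeded_determinism(self):
        a = dinucleotide_shuffle(SRNA, np.random.default_rng(5))
        b = dinucleotide_shuffle(SRNA, np.random.default_rng(5))
        assert a == b


class TestCleavagePvalue:
    def _world(self):
        flank = "TTCAGT" * 12
        tx = Transcript("t", flank + revcomp(SRNA) + flank)
        counts = np.zeros(len(tx), dtype=int)
        counts[expected_cleavage_position(72, 21) - 1] = 10
        return [tx], {"t": DegradomeProfile("t", counts)}

    def test_lower_bound_when_no_shuffle_qualifies(self):
        txs, profs = self._world()
        p = cleavage_pvalue(0.0, 0, SRNA, txs, profs, n_shuffles=20, seed=3)
        assert p == pytest.approx(1 / 21)

    def test_homopolymer_shuffles_equal_original(self):
        srna = "A" * 21
        tx = Transcript("t", "G" * 30 + "T" * 21 + "G" * 30)
        counts = np.zeros(len(tx), dtype=int)
        counts[expected_cleavage_position(30, 21) - 1] = 10
        profs = {"t": DegradomeProfile("t", counts)}
        p = cleavage_pvalue(0.0, 0, srna, [tx], profs, n_shuffles=20, seed=1)
        assert p == 1.0

    def test_b_matches_independent_recount(self):
        """Recount qualifying shuffles with an independent brute-force loop
        over the same seeded shuffle sequence."""
        txs, profs = self._world()
        observed_score, observed_cat = 4.0, 2
        n_shuffles, seed = 20, 11
        p = cleavage_pvalue(
            observed_score, observed_cat, SRNA, txs, profs,
            n_shuffles=n_shuffles, seed=seed,
        )
        rng = np.random.default_rng(seed)
        b = 0
        for _ in range(n_shuffles):
            shuf = dinucleotide_shuffle(SRNA, rng)
            qualifies = False
            for tx in txs:
                for i in range(len(tx) - 20):
                    score = allen_score(shuf, tx.sequence[i:i + 21])[0]
                    if score > 3.0 or score > observed_score:
                        continue
                    pos, count = site_signal(
                        profs[tx.id], expected_cleavage_position(i, 21), 1
                    )
                    if count == 0:
                        continue
                    cat = categorize(profs[tx.id], pos)
                    if cat is not None and cat <= observed_cat:
                        qualifies = True
            b += qualifies
        assert p == pytest.approx((1 + b) / (n_shuffles + 1))

    def test_invalid_shuffle_count(self):
        with pytest.raises(ValueError):
            cleavage_pvalue(0.0, 0, SRNA, [], {}, n_shuffles=0)


class TestCallTargets:
    def _setup(self, site_reads):
        flank = "TTCAGT" * 12
        tx = Transcript("t", flank + revcomp(SRNA) + flank)
        counts = np.zeros(len(tx), dtype=int)
        counts[expected_cleavage_position(72, 21) - 1] = site_reads
        srna = SrnaCatalogEntry("mir-x", SRNA)
        profs = {"t": DegradomeProfile("t", counts)}
        return [srna], [tx], profs

    def test_planted_event_valid_category_zero(self):
        srnas, txs, profs = self._setup(10)
        calls = call_targets(srnas, txs, profs, DegradomeParams(n_shuffles=20, seed=2))
        assert calls and calls[0].valid
        assert calls[0].category == 0
        assert calls[0].site_reads == 10

    def test_four_reads_insufficient(self):
        srnas, txs, profs = self._setup(4)
        calls = call_targets(srnas, txs, profs, DegradomeParams(n_shuffles=20, seed=2))
        assert calls and not calls[0].valid

    def test_category_three_invalid_despite_low_p(self):
        srnas, txs, profs = self._setup(10)
        # bury the site: many stronger peaks push it to/below the median
        prof = profs["t"]
        prof.position_counts[:20] = [50] * 10 + [10] * 10
        calls = call_targets(srnas, txs, profs, DegradomeParams(n_shuffles=20, seed=2))
        planted = [c for c in calls if c.alignment.srna_id == "mir-x"]
        assert planted and planted[0].category >= 3
        assert not planted[0].valid


class TestTplot:
    def test_called_site_flagged(self):
        flank = "TTCAGT" * 12
        tx = Transcript("t", flank + revcomp(SRNA) + flank)
        counts = np.zeros(len(tx), dtype=int)
        pos = expected_cleavage_position(72, 21)
        counts[pos - 1] = 10
        profs = {"t": DegradomeProfile("t", counts)}
        calls = call_targets(
            [SrnaCatalogEntry("m", SRNA)], [tx], profs,
            DegradomeParams(n_shuffles=20, seed=2),
        )
        table = tplot_data(profs["t"], calls)
        assert len(table) == len(tx)
        assert table.loc[table["flagged"], "position"].tolist() == [pos]

    def test_no_calls_no_flags(self):
        prof = DegradomeProfile("t", [0, 1, 2])
        assert not tplot_data(prof, []).flagged.any()
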