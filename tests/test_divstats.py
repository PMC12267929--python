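import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from superbarcode import divstats
from superbarcode.seqio import GenomeRecord

from conftest import make_alignment, random_seq
from _oracles import pi_by_columns


class TestSiteCounts:
    def test_definitions_on_hand_columns(self):
        # col0 AAAA invariant; col1 A,A,A,T variable, not informative;
        # col2 A,A,T,T informative; col3 A,C,G,T variable, not informative
        aln = make_alignment(["AAAA", "AAAC", "AATG", "ATTT"])
        assert divstats.variable_sites(aln) == 3
        assert divstats.parsimony_informative_sites(aln) == 1

    def test_identical_sequences(self):
        aln = make_alignment(["ACGT", "ACGT", "ACGT"])
        assert divstats.variable_sites(aln) == 0
        assert divstats.parsimony_informative_sites(aln) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_alignment_vs_bruteforce_census(self, seed):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list("ACGT-N"), size=200)) for _ in range(6)]
        aln = make_alignment(rows)
        var = pi_count = 0
        for c in range(200):
            col = [r[c] for r in rows if r[c] in "ACGT"]
            states = {}
            for ch in col:
                states[ch] = states.get(ch, 0) + 1
            if len(states) >= 2:
                var += 1
            if sum(1 for v in states.values() if v >= 2) >= 2:
                pi_count += 1
        assert divstats.variable_sites(aln) == var
        assert divstats.parsimony_informative_sites(aln) == pi_count

    def test_row_reordering_invariance(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(5)]
        a1 = make_alignment(rows)
        a2 = make_alignment(rows[::-1])
        assert divstats.variable_sites(a1) == divstats.variable_sites(a2)
        assert divstats.pi(a1) == pytest.approx(divstats.pi(a2))
        assert divstats.pairwise_identity(a1) == pytest.approx(
            divstats.pairwise_identity(a2)
        )


class TestIdentityGC:
    def test_identical_sequences_full_identity(self):
        aln = make_alignment(["ACGT", "ACGT"])
        assert divstats.pairwise_identity(aln) == pytest.approx(100.0)

    def test_hand_counted_three_sequences(self):
        # pairs: (1,2) 3/4, (1,3) 2/4, (2,3) 3/4 -> mean 66.67+...
        aln = make_alignment(["ACGT", "ACGA", "ACTA"])
        expected = 100 * (3 / 4 + 2 / 4 + 3 / 4) / 3
        assert divstats.pairwise_identity(aln) == pytest.approx(expected)

    def test_gc_simple(self):
        assert divstats.gc_content("ACGT") == pytest.approx(50.0)
        assert divstats.gc_content("AT-N") == pytest.approx(0.0)
        assert divstats.gc_content(GenomeRecord("g", "GGCC")) == pytest.approx(100.0)


class TestPi:
    def test_identical_zero(self):
        aln = make_alignment(["ACGT" * 5] * 4)
        assert divstats.pi(aln) == 0.0

    def test_hand_enumerated_toy(self):
        # 4 sequences of length 10 with pairwise difference multiset
        # {d12,d13,d14,d23,d24,d34} = {1,2,0,1,1,2}: pi = (7/6)/10
        s1 = "AAAAAAAAAA"
        s2 = "CAAAAAAAAA"   # vs s1: 1
        s3 = "CGAAAAAAAA"   # vs s1: 2, vs s2: 1
        s4 = s1             # vs s1: 0, vs s2: 1, vs s3: 2
        aln = make_alignment([s1, s2, s3, s4])
        assert divstats.pi(aln) == pytest.approx((7 / 6) / 10)

    def test_pairwise_deletion(self):
        aln = make_alignment(["AC-T", "ACGT", "TCGT"])
        # pair(1,2): 3 compared 0 diff; pair(1,3): 3 compared 1 diff;
        # pair(2,3): 4 compared 1 diff
        expected = (0 / 3 + 1 / 3 + 1 / 4) / 3
        assert divstats.pi(aln) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_site_decomposition_identity(self, seed):
        # gap-free: pi equals mean per-column pairwise heterozygosity
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(6)]
        aln = make_alignment(rows)
        assert divstats.pi(aln) == pytest.approx(pi_by_columns(rows), abs=1e-12)


class TestWindows:
    @given(
        L=st.integers(10, 3000),
        window=st.integers(5, 700),
        step=st.integers(1, 300),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_window_count_formula(self, L, window, step):
        got = divstats.expected_window_count(L, window, step)
        if L < window:
            assert got == 0
        else:
            assert got == (L - window) // step + 1
        # and gc_windows agrees with the formula
        rng = np.random.default_rng(1)
        track = divstats.gc_windows(random_seq(rng, L), window, step)
        assert len(track.values) == got

    def test_pi_windows_on_alignment(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), size=1000)) for _ in range(4)]
        aln = make_alignment(rows)
        track = divstats.pi_windows(aln, window=600, step=100)
        assert len(track.values) == (1000 - 600) // 100 + 1
        assert (track.values >= 0).all()
        # first window value equals pi on the column slice
        sub = make_alignment([r[:600] for r in rows])
        assert track.values[0] == pytest.approx(divstats.pi(sub))

    def test_mdc_density_counts_conserved(self, rng):
        sites = sorted(int(x) for x in rng.integers(0, 5500, size=40))
        track = divstats.mdc_density(sites, length=5500, window=1000)
        assert track.partial_last
        assert int(track.values.sum()) == 40
        # histogram oracle
        hist = np.histogram(sites, bins=np.arange(0, 7000, 1000))[0][:6]
        assert np.array_equal(track.values, hist)

    def test_mdc_density_first_window(self):
        track = divstats.mdc_density([0, 10, 500, 999, 999], length=3000,
                                     window=1000)
        assert list(track.values) == [5, 0, 0]
        assert not track.partial_last


class TestDivergentBlocks:
    def test_planted_block_recovered(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=2000))
        rows = [base, base, base]
        focal = list(base)
        # 243-column block at ~50% divergence
        for c in range(900, 1143):
            if rng.random() < 0.5:
                focal[c] = {"A": "C", "C": "G", "G": "T", "T": "A"}[focal[c]]
        rows.append("".join(focal))
        aln = make_alignment(rows)
        blocks = divstats.divergent_block_scan(aln, "s4", min_run=100,
                                               min_frac=0.3)
        assert len(blocks) == 1
        s, e = blocks[0]
        assert s >= 850 and e <= 1200
        assert e - s >= 150

    def test_no_divergence_empty(self):
        aln = make_alignment(["ACGT" * 100] * 4)
        assert divstats.divergent_block_scan(aln, "s1") == []

    def test_two_separated_blocks(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=3000))
        focal = list(base)
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for c in list(range(200, 400)) + list(range(2400, 2600)):
            focal[c] = flip[focal[c]]
        aln = make_alignment([base, base, base, "".join(focal)])
        blocks = divstats.divergent_block_scan(aln, "s4", min_run=100,
                                               min_frac=0.3)
        assert len(blocks) == 2
        assert blocks[0][0] < 400 < 2400 < blocks[1][1]
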