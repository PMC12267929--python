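import shutil
import subprocess

import numpy as np
import pytest

from superbarcode import homology
from superbarcode.errors import ConfigurationError
from superbarcode.homology import (
    HomologyHit,
    ScoringScheme,
    dedupe_hits,
    evalue,
    find_hits,
    merge_intervals,
    mtpt_share,
    self_repeats,
)
from superbarcode.seqio import Feature, GenomeRecord

from conftest import random_seq
from _oracles import cluster_pairs, sw_score

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(rng, s, n):
    arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
    for p in rng.choice(len(s), size=n, replace=False):
        choices = _BASES[_BASES != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return arr.tobytes().decode()


class TestScoring:
    def test_lambda_solves_identity(self):
        s = ScoringScheme()
        lam = s.karlin_lambda
        val = 0.25 * np.exp(lam * s.match) + 0.75 * np.exp(-lam * s.mismatch)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_scheme_rejected(self):
        with pytest.raises(ConfigurationError, match="degenerate"):
            ScoringScheme(match=3, mismatch=0, karlin_k=0.1)

    def test_unknown_scheme_needs_k(self):
        with pytest.raises(ConfigurationError, match="Karlin"):
            ScoringScheme(match=5, mismatch=4)


class TestEvalue:
    def test_linear_in_search_space(self):
        s = ScoringScheme()
        assert evalue(120, 2000, 1000, s) == pytest.approx(
            2 * evalue(120, 1000, 1000, s)
        )

    def test_monotone_decreasing_in_score(self):
        s = ScoringScheme()
        assert evalue(90, 1e5, 1e5, s) > evalue(110, 1e5, 1e5, s)

    def test_nonpositive_space_rejected(self):
        with pytest.raises(ConfigurationError):
            evalue(100, 0, 10, ScoringScheme())

    def test_cutoff_score_matches_bisection(self):
        # score solving E = 1e-5 at m = n = 4e5 vs an inverted oracle
        s = ScoringScheme()
        m = n = 4e5
        target = 1e-5
        closed = (np.log(s.karlin_k * m * n) - np.log(target)) / s.karlin_lambda
        lo, hi = 0.0, 1000.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if evalue(mid, m, n, s) > target:
                lo = mid
            else:
                hi = mid
        assert closed == pytest.approx((lo + hi) / 2, abs=1e-6)


class TestFindHits:
    def test_planted_verbatim_block(self, rng):
        B = random_seq(rng, 5000, gc=0.44)
        A = random_seq(rng, 2000, gc=0.44) + B[1000:1200] + random_seq(rng, 2000, gc=0.44)
        hits = find_hits(GenomeRecord("A", A), GenomeRecord("B", B))
        assert len(hits) == 1
        h = hits[0]
        assert h.pct_identity == pytest.approx(100.0)
        # covers the full planted 200 bp
        assert h.query_start <= 2000 and h.query_end >= 2200
        assert h.subject_start <= 1000 and h.subject_end >= 1200

    @pytest.mark.parametrize("seed", range(20))
    def test_unrelated_sequences_no_hits(self, seed):
        rng = np.random.default_rng(seed)
        a = GenomeRecord("a", random_seq(rng, 10_000))
        b = GenomeRecord("b", random_seq(rng, 10_000))
        assert find_hits(a, b, min_raw_score=100) == []

    def test_unrelated_oracle_confirms_below_threshold(self, rng):
        # full Smith-Waterman on short unrelated pair stays below 100
        a = random_seq(rng, 800)
        b = random_seq(rng, 800)
        assert sw_score(a, b) < 100

    def test_mutated_insert_recovered(self, rng):
        B = random_seq(rng, 8000, gc=0.44)
        insert = _mutate(rng, B[2000:2500], 25)  # 5% divergence
        A = random_seq(rng, 3000, gc=0.44) + insert + random_seq(rng, 3000, gc=0.44)
        hits = find_hits(GenomeRecord("A", A), GenomeRecord("B", B))
        assert len(hits) == 1
        h = hits[0]
        cover = min(h.query_end, 3500) - max(h.query_start, 3000)
        assert cover >= 0.9 * 500
        assert 93 <= h.pct_identity <= 97

    def test_score_agrees_with_smith_waterman(self, rng):
        # on short sequences the best hit equals the global SW optimum
        B = random_seq(rng, 900)
        insert = _mutate(rng, B[200:500], 9)
        A = random_seq(rng, 300) + insert + random_seq(rng, 300)
        hits = find_hits(GenomeRecord("A", A), GenomeRecord("B", B))
        assert len(hits) == 1
        assert hits[0].raw_score == pytest.approx(sw_score(A, B))

    def test_strand_symmetry(self, rng):
        B = random_seq(rng, 4000)
        A = random_seq(rng, 1000) + B[500:800] + random_seq(rng, 1000)
        ga = GenomeRecord("A", A)
        fwd = find_hits(ga, GenomeRecord("B", B))
        rev = find_hits(ga, GenomeRecord("Brc", homology.revcomp(B)))
        assert len(fwd) == len(rev) == 1
        assert fwd[0].strand != rev[0].strand
        assert fwd[0].raw_score == rev[0].raw_score
        assert fwd[0].query_interval == rev[0].query_interval

    def test_short_seed_rejected(self, rng):
        g = GenomeRecord("g", random_seq(rng, 100))
        with pytest.raises(ConfigurationError):
            find_hits(g, g, seed_len=4)


@pytest.mark.skipif(shutil.which("blastn") is None, reason="blastn not on PATH")
class TestBlastnCrossCheck:
    def test_planted_hit_matches_blastn(self, rng, tmp_path):
        B = random_seq(rng, 6000, gc=0.44)
        insert = _mutate(rng, B[1500:2300], 16)  # 2% divergence
        A = random_seq(rng, 2000, gc=0.44) + insert + random_seq(rng, 2000, gc=0.44)
        q = tmp_path / "q.fa"
        s = tmp_path / "s.fa"
        q.write_text(f">q\n{A}\n")
        s.write_text(f">s\n{B}\n")
        out = subprocess.run(
            [
                "blastn", "-query", str(q), "-subject", str(s),
                "-outfmt", "6 qstart qend sstart send pident score",
                "-evalue", "1e-5",
            ],
            capture_output=True, text=True, check=True,
        ).stdout.strip().splitlines()
        assert out, "blastn found no hit"
        qs, qe, ss, se, pid, _sc = out[0].split("\t")
        hits = find_hits(GenomeRecord("A", A), GenomeRecord("B", B))
        assert len(hits) == 1
        h = hits[0]
        # blastn is 1-based inclusive
        assert abs(h.query_start - (int(qs) - 1)) <= 10
        assert abs(h.query_end - int(qe)) <= 10
        assert h.pct_identity == pytest.approx(float(pid), abs=1.0)


def _hit(q, s, strand="+"):
    return HomologyHit(q[0], q[1], s[0], s[1], strand, 200, 50, 1e-10, 99.0,
                       q[1] - q[0])


class TestDedupe:
    def test_identical_hits_merge(self):
        hits = [_hit((0, 100), (500, 600)), _hit((0, 100), (500, 600))]
        assert len(dedupe_hits(hits)) == 1

    def test_disjoint_hits_stay(self):
        hits = [_hit((0, 100), (500, 600)), _hit((1000, 1100), (2000, 2100))]
        assert len(dedupe_hits(hits)) == 2

    def test_duplicate_insertion_clusters_on_subject(self):
        # one plastid locus hit at two mitogenome loci
        hits = [_hit((0, 100), (500, 600)), _hit((5000, 5100), (500, 600))]
        pairs = dedupe_hits(hits)
        assert len(pairs) == 1
        assert pairs[0].members == [0, 1]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_clustering(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        qs = [
            (int(a), int(a) + int(rng.integers(50, 200)))
            for a in rng.integers(0, 2000, size=n)
        ]
        ss = [
            (int(a), int(a) + int(rng.integers(50, 200)))
            for a in rng.integers(0, 2000, size=n)
        ]
        hits = [_hit(q, s) for q, s in zip(qs, ss)]
        pairs = dedupe_hits(hits, overlap_frac=0.5)
        got = sorted(p.members for p in pairs)
        assert got == cluster_pairs(qs, ss, 0.5)


class TestGeneContent:
    def _pairs(self, region):
        return [homology.RegionPair(region, region, [0])]

    def test_contained_gene_complete(self):
        pairs = [homology.RegionPair((0, 10), (50, 500), [0])]
        feats = [Feature("atpE", 100, 400, "+", "gene")]
        table = homology.classify_gene_content(pairs, feats)
        assert table.iloc[0]["completeness"] == "complete"

    def test_straddling_gene_fragment(self):
        pairs = [homology.RegionPair((0, 10), (200, 300), [0])]
        feats = [Feature("rbcL", 100, 400, "+", "gene")]
        table = homology.classify_gene_content(pairs, feats)
        assert table.iloc[0]["completeness"] == "fragment"

    def test_nonoverlapping_gene_absent(self):
        pairs = [homology.RegionPair((0, 10), (200, 300), [0])]
        feats = [Feature("ndhI", 500, 700, "+", "gene")]
        assert homology.classify_gene_content(pairs, feats).empty


class TestSelfRepeats:
    def test_duplicated_segment_masked(self, rng):
        seg = random_seq(rng, 1000)
        g = GenomeRecord(
            "g", random_seq(rng, 3000) + seg + random_seq(rng, 3000) + seg
            + random_seq(rng, 1000)
        )
        mask = self_repeats(g, min_len=500)
        covered = [
            iv for iv in mask
            if (iv[0] < 4000 and iv[1] > 3000) or (iv[0] < 8000 and iv[1] > 7000)
        ]
        assert len(covered) >= 2
        # both planted loci inside the mask
        loci = [(3000, 4000), (7000, 8000)]
        for s, e in loci:
            assert any(ms <= s + 20 and me >= e - 20 for ms, me in mask)

    def test_clean_sequence_empty_mask(self, rng):
        g = GenomeRecord("g", random_seq(rng, 8000))
        assert self_repeats(g, min_len=100) == []

    def test_tandem_microsatellite_masked(self, rng):
        g = GenomeRecord(
            "g", random_seq(rng, 2000) + "AT" * 150 + random_seq(rng, 2000)
        )
        mask = self_repeats(g, min_len=100)
        assert any(s < 2300 and e > 2000 for s, e in mask)

    def test_mask_sorted_disjoint_in_bounds(self, rng):
        seg = random_seq(rng, 800)
        g = GenomeRecord(
            "g", seg + random_seq(rng, 2000) + seg + random_seq(rng, 500) + seg
        )
        mask = self_repeats(g, min_len=300)
        for (s1, e1), (s2, e2) in zip(mask, mask[1:]):
            assert e1 < s2
        assert all(0 <= s < e <= len(g) for s, e in mask)


class TestIntervalHelpers:
    def test_merge_intervals(self):
        assert merge_intervals([(5, 10), (0, 6), (20, 30)]) == [(0, 10), (20, 30)]

    def test_mtpt_share_printed_arithmetic(self):
        # merged transfer length over genome length, as a percent
        assert mtpt_share([(0, 19_293)], 424_370) == pytest.approx(4.55, abs=0.005)

    def test_size_difference(self):
        assert homology.genome_size_difference(424_370, 399_005) == pytest.approx(
            6.4, abs=0.05
        )
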