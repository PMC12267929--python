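import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from superbarcode import codon
from superbarcode.errors import ConfigurationError


class TestExtractCodons:
    def test_simple_gene(self):
        cc = codon.extract_codons(["ATGAAAAAGTAA"])
        assert cc.counts == {"ATG": 1, "AAA": 1, "AAG": 1}
        assert cc.stops == {"TAA": 1}

    def test_length_filter_excludes_short_gene(self):
        short = "ATG" + "AAA" * 78  # 79 sense codons
        with pytest.raises(ConfigurationError):
            codon.extract_codons([short], min_len_aa=80)
        cc = codon.extract_codons([short, "ATG" + "CCC" * 79], min_len_aa=80)
        assert cc.n_genes == 1

    def test_trailing_remainder_dropped(self):
        with pytest.warns(UserWarning, match="divisible"):
            cc = codon.extract_codons(["ATGAAAC"])
        assert cc.counts == {"ATG": 1, "AAA": 1}

    @pytest.mark.parametrize("seed", range(3))
    def test_counts_match_bruteforce_stepping(self, seed):
        rng = np.random.default_rng(seed)
        cds = [
            "".join(rng.choice(list("ACGT"), size=3 * int(rng.integers(5, 60))))
            for _ in range(3)
        ]
        cc = codon.extract_codons(cds)
        from Bio.Data import CodonTable

        stops = set(CodonTable.unambiguous_dna_by_id[1].stop_codons)
        want: dict = {}
        for s in cds:
            for i in range(0, len(s) - 2, 3):
                c = s[i : i + 3]
                if c not in stops:
                    want[c] = want.get(c, 0) + 1
        assert cc.counts == want


class TestRscu:
    def test_twofold_family(self):
        cc = codon.CodonCounts({"AAA": 3, "AAG": 1})
        r = codon.rscu(cc)
        assert r["AAA"] == pytest.approx(1.5)
        assert r["AAG"] == pytest.approx(0.5)

    def test_uniform_fourfold_family(self):
        cc = codon.CodonCounts({c: 7 for c in ("GCT", "GCC", "GCA", "GCG")})
        r = codon.rscu(cc)
        for c in ("GCT", "GCC", "GCA", "GCG"):
            assert r[c] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_family_sums_equal_degeneracy(self, seed):
        rng = np.random.default_rng(seed)
        fam = codon.codon_families()
        counts = {c: int(rng.integers(0, 50)) for c in fam}
        r = codon.rscu(codon.CodonCounts(counts))
        groups: dict = {}
        for c, aa in fam.items():
            groups.setdefault(aa, []).append(c)
        for aa, codons in groups.items():
            if sum(counts[c] for c in codons) == 0:
                assert all(math.isnan(r[c]) for c in codons)
            else:
                assert sum(r[c] for c in codons) == pytest.approx(
                    len(codons), abs=1e-12
                )

    def test_sixfold_family_whole_by_default(self):
        fam = codon.codon_families()
        leu = [c for c, aa in fam.items() if aa == "L"]
        assert len(leu) == 6
        split = codon.codon_families(split_sixfold=True)
        leu2 = {split[c] for c in leu}
        assert leu2 == {"L2", "L4"}


def _matrix_from_rows(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows)


class TestKruskalWallis:
    def test_identical_values_p_one(self):
        m = _matrix_from_rows({"AAA": [1.0] * 6, "AAG": [1.0] * 6})
        assert codon.kw_by_amino_acid(m, "K") == 1.0

    def test_separated_ranges_significant(self):
        m = _matrix_from_rows(
            {"AAA": np.linspace(1.4, 1.6, 10), "AAG": np.linspace(0.4, 0.6, 10)}
        )
        assert codon.kw_by_amino_acid(m, "K") < 0.01

    def test_matches_scipy_on_fourfold(self, rng):
        cods = ("GCT", "GCC", "GCA", "GCG")
        m = _matrix_from_rows({c: rng.random(8) for c in cods})
        p = codon.kw_by_amino_acid(m, "A")
        want = stats.kruskal(*[m[c].to_numpy() for c in cods]).pvalue
        assert p == pytest.approx(want)

    def test_rank_invariance_under_monotone_transform(self, rng):
        cods = ("GCT", "GCC", "GCA", "GCG")
        vals = {c: rng.random(8) for c in cods}
        p1 = codon.kw_by_amino_acid(_matrix_from_rows(vals), "A")
        p2 = codon.kw_by_amino_acid(
            _matrix_from_rows({c: np.exp(3 * v) for c, v in vals.items()}), "A"
        )
        assert p1 == pytest.approx(p2)

    def test_singleton_family_rejected(self):
        m = _matrix_from_rows({"ATG": [1.0, 1.0]})
        with pytest.raises(ConfigurationError):
            codon.kw_by_amino_acid(m, "M")


class TestDunn:
    def test_identical_groups_all_padj_one(self):
        m = _matrix_from_rows({"AAA": [1.0] * 5, "AAG": [1.0] * 5})
        t = codon.dunn_posthoc(m, "K")
        assert (t["p_adj"] == 1.0).all()

    def test_fourfold_family_six_comparisons(self, rng):
        cods = ("GCT", "GCC", "GCA", "GCG")
        m = _matrix_from_rows({c: rng.random(6) for c in cods})
        t = codon.dunn_posthoc(m, "A")
        assert len(t) == 6
        # Bonferroni factor 6
        unadj = t["p"].to_numpy()
        assert np.allclose(t["p_adj"], np.minimum(1.0, unadj * 6))

    def test_twofold_family_single_comparison_no_correction(self, rng):
        m = _matrix_from_rows({"AAA": rng.random(6), "AAG": rng.random(6)})
        t = codon.dunn_posthoc(m, "K")
        assert len(t) == 1
        assert t["p_adj"].iloc[0] == pytest.approx(t["p"].iloc[0])

    def test_z_matches_hand_rank_computation(self):
        # no ties: z = (R1-R2)/sqrt(N(N+1)/12 * (1/n1+1/n2))
        a = np.array([0.1, 0.2, 0.3, 0.4])
        b = np.array([0.5, 0.6, 0.7, 0.8])
        m = _matrix_from_rows({"AAA": a, "AAG": b})
        t = codon.dunn_posthoc(m, "K")
        N = 8
        r1, r2 = np.mean([1, 2, 3, 4]), np.mean([5, 6, 7, 8])
        z = (r1 - r2) / math.sqrt(N * (N + 1) / 12 * (1 / 4 + 1 / 4))
        assert t["z"].iloc[0] == pytest.approx(z, abs=1e-9)

    def test_bonferroni_subset_of_uncorrected(self, rng):
        cods = ("GCT", "GCC", "GCA", "GCG")
        m = _matrix_from_rows({c: rng.random(10) + (0.5 if c == "GCT" else 0)
                               for c in cods})
        adj = codon.dunn_posthoc(m, "A", correction="bonferroni")
        raw = codon.dunn_posthoc(m, "A", correction="none")
        sig_adj = set(map(tuple, adj.loc[adj.significant, ["codon_i", "codon_j"]].values))
        sig_raw = set(map(tuple, raw.loc[raw.significant, ["codon_i", "codon_j"]].values))
        assert sig_adj <= sig_raw


class TestOrganelleContrast:
    def test_identical_matrices_nothing_significant(self, rng):
        rows = pd.DataFrame({c: rng.random(6) for c in ("AAA", "AAG", "GCT")})
        t = codon.compare_organelles(rows, rows.copy())
        assert not t["significant"].any()

    def test_planted_shift_detected_with_direction(self, rng):
        codons = [f"C{i}" for i in range(20)]
        mt = pd.DataFrame({c: rng.random(12) for c in codons})
        pt = mt + 0.0
        shifted = codons[:5]
        pt = pt.copy()
        pt[shifted] = pt[shifted] + 2.0
        # perturb the unshifted codons slightly so values are not identical
        pt[codons[5:]] = pt[codons[5:]] + rng.normal(0, 0.01, size=(12, 15))
        t = codon.compare_organelles(mt, pt).set_index("codon")
        assert set(t.index[t.significant]) == set(shifted)
        assert (t.loc[shifted, "direction"] == -1).all()

    def test_label_swap_flips_direction(self, rng):
        mt = pd.DataFrame({"AAA": rng.random(8), "AAG": rng.random(8) + 1})
        pt = pd.DataFrame({"AAA": rng.random(8) + 1, "AAG": rng.random(8)})
        t1 = codon.compare_organelles(mt, pt).set_index("codon")
        t2 = codon.compare_organelles(pt, mt).set_index("codon")
        assert (t1["direction"] == -t2["direction"]).all()


class TestPearson:
    def test_identical_vectors(self):
        v = pd.Series({"AAA": 3.0, "AAG": 1.0, "GCT": 5.0})
        assert codon.pearson_concordance(v, v) == pytest.approx(1.0)

    def test_negated_vector(self):
        v = pd.Series({"AAA": 3.0, "AAG": 1.0, "GCT": 5.0})
        assert codon.pearson_concordance(v, -v) == pytest.approx(-1.0)

    def test_matches_closed_form(self, rng):
        codons = [f"X{i}" for i in range(30)]
        a = pd.Series(rng.random(30), index=codons)
        b = pd.Series(rng.random(30), index=codons)
        r = codon.pearson_concordance(a, b)
        av, bv = a.to_numpy(), b.to_numpy()
        want = np.mean((av - av.mean()) * (bv - bv.mean())) / (
            av.std() * bv.std()
        )
        assert r == pytest.approx(want, abs=1e-12)

    def test_zero_variance_nan(self):
        a = pd.Series({"AAA": 1.0, "AAG": 1.0})
        b = pd.Series({"AAA": 1.0, "AAG": 2.0})
        assert math.isnan(codon.pearson_concordance(a, b))


class TestMilc:
    def test_zero_when_observed_equals_expected(self):
        # uniform usage in every family matches the uniform expectation:
        # sum of M_a vanishes, leaving only the correction
        counts = {c: 10 for c in codon.codon_families()}
        cc = codon.CodonCounts(counts)
        fam = codon.codon_families()
        L = cc.total
        corr = sum(
            len([x for x in fam if fam[x] == aa]) - 1
            for aa in set(fam.values())
        ) / L - 0.5
        assert codon.milc(cc) == pytest.approx(-corr, abs=1e-12)

    def test_short_gene_excluded(self):
        cc = codon.CodonCounts({"AAA": 79})
        with pytest.raises(ConfigurationError, match="80"):
            codon.milc(cc)

    def test_zero_expected_with_observed_errors(self):
        cc = codon.CodonCounts({"AAA": 50, "AAG": 50})
        expected = {c: 1.0 for c in codon.codon_families()}
        expected["AAA"] = 0.0
        with pytest.raises(ConfigurationError, match="expected"):
            codon.milc(cc, expected=expected)

    def test_decreases_toward_floor_with_length(self):
        # genes drawn from the expected model: mean MILC shrinks with length
        from superbarcode.synthetic_data import sim_cds

        means = []
        for L in (100, 400, 1600):
            vals = []
            for rep in range(30):
                genes = sim_cds(1, (L, L), seed=1000 * L + rep)
                cc = codon.extract_codons(list(genes.values()))
                vals.append(codon.milc(cc))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_milc_table_filters(self):
        genes = {
            "long": codon.CodonCounts({"AAA": 60, "AAG": 40}),
            "short": codon.CodonCounts({"AAA": 30}),
        }
        t = codon.milc_table(genes)
        assert list(t["gene"]) == ["long"]
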