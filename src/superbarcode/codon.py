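"""Codon-usage statistics: RSCU, rank tests within amino-acid families,
organelle contrasts, Pearson concordance, and the MILC distance.

Relative synonymous codon usage for codon c of an amino acid with
degeneracy r is RSCU_c = r * n_c / sum(family counts); 1 means no bias, and
RSCU sums to r over each family with nonzero counts.

The statistical procedure is two-level: within each amino-acid family a
Kruskal-Wallis test across codons (rows = genomes/species as replicates),
followed by Dunn's post hoc z-tests with Bonferroni correction over that
family's codon pairs.  The plastid-vs-mitochondrion contrast applies the
same rank machinery per codon, correcting over all tested codons.

MILC ("Measure Independent of Length and Composition") for a gene with L
codons is sum_a(M_a)/L - C with M_a = 2 * sum_c o_c * ln(f_c/g_c), where
o_c are observed codon counts, f_c observed within-family frequencies and
g_c expected within-family frequencies, and the small-sample correction is
C = (sum_a (r_a - 1))/L - 0.5 over amino acids present in the gene.

Plant mitochondria and plastids both translate with the standard genetic
code, which is therefore the default; any NCBI translation table id can be
configured.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .errors import ConfigurationError

_BASES = "TCAG"


def codon_families(table_id: int = 1, split_sixfold: bool = False) -> dict[str, str]:
    """Map codon -> amino acid for sense codons of an NCBI translation table.

    With ``split_sixfold`` the Leu/Ser/Arg six-codon families are split into
    their two- and four-fold sub-families (suffixing the amino acid letter);
    by default they are kept whole (r = 6), the common RSCU convention.
    """
    tbl = CodonTable.unambiguous_dna_by_id[table_id]
    fam = dict(tbl.forward_table)  # codon -> AA, stops excluded
    if split_sixfold:
        out = {}
        for codon, aa in fam.items():
            group = aa
            members = [c for c, a in fam.items() if a == aa]
            if len(members) == 6:
                # sub-family by first two codon positions
                prefix_counts: dict[str, int] = {}
                for c in members:
                    prefix_counts[c[:2]] = prefix_counts.get(c[:2], 0) + 1
                group = f"{aa}{'2' if prefix_counts[codon[:2]] == 2 else '4'}"
            out[codon] = group
        return out
    return fam


@dataclass
class CodonCounts:
    """Pooled sense-codon counts (stop codons kept separately)."""

    counts: dict[str, int]
    stops: dict[str, int] = field(default_factory=dict)
    table_id: int = 1
    n_genes: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def extract_codons(
    cds_set: Sequence[str], min_len_aa: int = 0, table_id: int = 1
) -> CodonCounts:
    """Count codons pooled over coding sequences.

    Sequences shorter than ``min_len_aa`` codons are excluded (hard length
    filter).  A trailing remainder not divisible by 3 is dropped with a
    warning-free truncation; stop codons are tallied separately.
    """
    tbl = CodonTable.unambiguous_dna_by_id[table_id]
    stops = set(tbl.stop_codons)
    counts: dict[str, int] = {}
    stop_counts: dict[str, int] = {}
    kept = 0
    for seq in cds_set:
        s = str(seq).upper().replace("U", "T")
        if len(s) % 3:
            warnings.warn(
                f"CDS length {len(s)} not divisible by 3; trailing "
                f"{len(s) % 3} nt dropped"
            )
        n_codons = len(s) // 3
        # the length filter counts amino acids, i.e. sense codons
        codons = [s[i * 3 : i * 3 + 3] for i in range(n_codons)]
        sense = [c for c in codons if c not in stops]
        if len(sense) < min_len_aa:
            continue
        kept += 1
        for c in codons:
            if len(set(c) - set("ACGT")) > 0:
                continue
            if c in stops:
                stop_counts[c] = stop_counts.get(c, 0) + 1
            else:
                counts[c] = counts.get(c, 0) + 1
    if kept == 0:
        raise ConfigurationError("no coding sequence passes the length filter")
    return CodonCounts(counts, stop_counts, table_id, n_genes=kept)


def rscu(counts: CodonCounts, split_sixfold: bool = False) -> pd.Series:
    """RSCU per sense codon: r * observed / family total.

    Families with zero total get NA for every member.
    """
    fam = codon_families(counts.table_id, split_sixfold)
    groups: dict[str, list[str]] = {}
    for codon, aa in fam.items():
        groups.setdefault(aa, []).append(codon)
    out = {}
    for aa, codons in groups.items():
        r = len(codons)
        total = sum(counts.counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = r * counts.counts.get(c, 0) / total if total else np.nan
    return pd.Series(out).sort_index()


def rscu_matrix(
    rows: dict[str, CodonCounts], split_sixfold: bool = False
) -> pd.DataFrame:
    """Species/genome x codon RSCU matrix."""
    return pd.DataFrame(
        {name: rscu(cc, split_sixfold) for name, cc in rows.items()}
    ).T


def kw_by_amino_acid(
    matrix: pd.DataFrame, amino_acid: str, table_id: int = 1,
    split_sixfold: bool = False,
) -> float:
    """Kruskal-Wallis p-value across a family's codons (rows as replicates).

    Mid-ranks with tie correction; all-equal degenerate data returns p = 1.
    """
    fam = codon_families(table_id, split_sixfold)
    codons = sorted(c for c, aa in fam.items() if aa == amino_acid)
    if len(codons) < 2:
        raise ConfigurationError(
            f"family {amino_acid!r} has degeneracy < 2; no within-family test"
        )
    if matrix.shape[0] < 2:
        raise ConfigurationError("need >= 2 rows")
    groups = [matrix[c].dropna().to_numpy() for c in codons]
    groups = [g for g in groups if g.size]
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


def dunn_posthoc(
    matrix: pd.DataFrame,
    amino_acid: str,
    table_id: int = 1,
    correction: str = "bonferroni",
    split_sixfold: bool = False,
) -> pd.DataFrame:
    """Dunn's z-tests between a family's codons with Bonferroni correction.

    z is computed from pooled mid-ranks with the tie correction
    T = sum(t^3 - t) / (12 (N - 1)); p_adj = min(1, p * #pairs).
    """
    if correction not in ("bonferroni", "none"):
        raise ConfigurationError(f"unknown correction {correction!r}")
    fam = codon_families(table_id, split_sixfold)
    codons = sorted(c for c, aa in fam.items() if aa == amino_acid)
    if len(codons) < 2:
        raise ConfigurationError(f"family {amino_acid!r} has degeneracy < 2")
    groups = {c: matrix[c].dropna().to_numpy() for c in codons}
    rows = _dunn_table(groups, correction)
    return rows


def _dunn_table(groups: dict[str, np.ndarray], correction: str) -> pd.DataFrame:
    names = list(groups)
    sizes = {c: groups[c].size for c in names}
    pooled = np.concatenate([groups[c] for c in names])
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    off = 0
    for c in names:
        n = sizes[c]
        mean_rank[c] = ranks[off : off + n].mean() if n else np.nan
        off += n
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - T
    k = sum(1 for _ in combinations(names, 2))
    rows = []
    for ci, cj in combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[ci] + 1.0 / sizes[cj]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[ci] - mean_rank[cj]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * k) if correction == "bonferroni" else p
        rows.append(
            {"codon_i": ci, "codon_j": cj, "z": z, "p": p, "p_adj": p_adj,
             "significant": p_adj < 0.05}
        )
    return pd.DataFrame(rows)


def compare_organelles(
    mt: pd.DataFrame, pt: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-codon rank test between mitochondrial and plastid RSCU rows.

    For each shared codon a two-group Kruskal-Wallis test is applied;
    Bonferroni correction runs over all tested codons.  Direction is the
    sign of median(MT) - median(PT).
    """
    shared = sorted(set(mt.columns) & set(pt.columns))
    if not shared:
        raise ConfigurationError("no shared codon columns")
    rows = []
    for c in shared:
        a = mt[c].dropna().to_numpy()
        b = pt[c].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            p = 1.0
        else:
            p = float(stats.kruskal(a, b).pvalue)
        direction = float(np.sign(np.median(a) - np.median(b)))
        rows.append({"codon": c, "p": p, "direction": direction})
    df = pd.DataFrame(rows)
    k = len(df)
    df["p_adj"] = np.minimum(1.0, df["p"] * k)
    df["significant"] = df["p_adj"] < alpha
    return df


def pearson_concordance(
    mt_counts: "pd.Series | CodonCounts", pt_counts: "pd.Series | CodonCounts"
) -> float:
    """Pearson r between paired codon vectors over shared codons.

    Returns NaN when either vector has zero variance.
    """
    if isinstance(mt_counts, CodonCounts):
        mt_counts = pd.Series(mt_counts.counts)
    if isinstance(pt_counts, CodonCounts):
        pt_counts = pd.Series(pt_counts.counts)
    shared = sorted(set(mt_counts.index) & set(pt_counts.index))
    a = mt_counts.loc[shared].astype(float).to_numpy()
    b = pt_counts.loc[shared].astype(float).to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def milc(
    gene_counts: CodonCounts,
    expected: dict[str, float] | str = "uniform",
    min_len_aa: int = 80,
) -> float:
    """MILC distance of a gene's codon usage from an expected model.

    ``expected`` maps codons to expected frequencies (any normalization;
    only within-family proportions matter) or ``"uniform"`` for equal usage
    within each family.  Genes shorter than ``min_len_aa`` sense codons
    raise a configuration error (hard length filter).
    """
    fam = codon_families(gene_counts.table_id)
    L = gene_counts.total
    if L < min_len_aa:
        raise ConfigurationError(
            f"gene has {L} sense codons, shorter than the {min_len_aa} AA filter"
        )
    groups: dict[str, list[str]] = {}
    for codon, aa in fam.items():
        groups.setdefault(aa, []).append(codon)

    total_m = 0.0
    correction_sum = 0
    for aa, codons in groups.items():
        obs = {c: gene_counts.counts.get(c, 0) for c in codons}
        fam_total = sum(obs.values())
        if fam_total == 0:
            continue
        r = len(codons)
        correction_sum += r - 1
        if expected == "uniform":
            g = {c: 1.0 / r for c in codons}
        else:
            g_raw = {c: float(expected.get(c, 0.0)) for c in codons}
            g_tot = sum(g_raw.values())
            if g_tot == 0:
                raise ConfigurationError(
                    f"expected model assigns zero mass to family {aa!r}"
                )
            g = {c: g_raw[c] / g_tot for c in codons}
        m_a = 0.0
        for c in codons:
            o = obs[c]
            if o == 0:
                continue
            if g[c] == 0:
                raise ConfigurationError(
                    f"expected frequency 0 for observed codon {c}"
                )
            f = o / fam_total
            m_a += 2.0 * o * math.log(f / g[c])
        total_m += m_a
    C = correction_sum / L - 0.5
    return total_m / L - C


def milc_table(
    genes: dict[str, CodonCounts],
    expected: dict[str, float] | str = "uniform",
    min_len_aa: int = 80,
) -> pd.DataFrame:
    """MILC per gene, excluding genes below the length filter."""
    rows = []
    for name, cc in genes.items():
        if cc.total < min_len_aa:
            continue
        rows.append({"gene": name, "length_aa": cc.total,
                     "milc": milc(cc, expected, min_len_aa)})
    return pd.DataFrame(rows, columns=["gene", "length_aa", "milc"])
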