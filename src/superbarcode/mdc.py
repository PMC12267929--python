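"""Molecular diagnostic characters (MDCs) and species-discrimination reports.

An MDC is an alignment column at which every sample of the query taxon
carries the same unambiguous base and no reference-taxon sample carries a
state compatible with it.  Columns where the query taxon is polymorphic, or
where any query sample has a gap or ambiguity code, are excluded.

Two reference-side policies are provided:

``conservative`` (default)
    any reference gap, N, or ambiguity code compatible with the query base
    disqualifies the column.  This policy can only under-count.
``strict_acgt``
    non-ACGT reference characters are ignored; the column qualifies if no
    unambiguous reference base equals the query base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .seqio import AMBIGUITY, Alignment, SpeciesPanel

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)

# per-character bitmask of compatible ACGT bases (A=1, C=2, G=4, T=8)
_BITS = np.zeros(256, dtype=np.uint8)
for code, bases in AMBIGUITY.items():
    _BITS[ord(code)] = sum(
        {"A": 1, "C": 2, "G": 4, "T": 8}[b] for b in bases
    )
# gap has mask 0: compatible with nothing


@dataclass(frozen=True)
class MdcSite:
    fragment_id: str
    column: int              # 0-based alignment column
    query_state: str         # single unambiguous base
    reference_states: frozenset[str]


@dataclass
class MdcReport:
    """Per-(species, fragment) counts and panel discrimination efficiency."""

    counts: pd.DataFrame          # index species, columns fragment ids
    combined: pd.Series           # per species, sum over fragments
    identified: pd.Series         # bool, >= 1 MDC among evaluable species
    not_evaluable: list[str]      # species with no congener under genus scope
    efficiency: float             # percent of evaluable species identified
    denominator: int

    def summary(self) -> dict:
        return {
            "efficiency_pct": round(self.efficiency, 2),
            "denominator": self.denominator,
            "identified": int(self.identified.sum()),
            "not_evaluable": self.not_evaluable,
            "total_mdcs": int(self.combined.sum()),
        }


def _rows(aln: Alignment, samples: Iterable[str]) -> np.ndarray:
    idx = [aln.sample_ids.index(s) for s in samples]
    return aln.matrix[idx]


def find_mdcs(
    alignment: Alignment,
    query_samples: Sequence[str],
    reference_samples: Sequence[str],
    policy: str = "conservative",
) -> list[MdcSite]:
    """Columns fixed for one unambiguous base in the query taxon and
    incompatible with every reference sample under the chosen policy."""
    q = list(query_samples)
    r = list(reference_samples)
    if not q or not r:
        raise ConfigurationError("query and reference sets must be non-empty")
    if set(q) & set(r):
        raise ConfigurationError(
            f"query/reference overlap: {sorted(set(q) & set(r))}"
        )
    if policy not in ("conservative", "strict_acgt"):
        raise ConfigurationError(f"unknown policy {policy!r}")

    qm = _rows(alignment, q)
    rm = _rows(alignment, r)

    # query must be fixed for a single unambiguous base
    q_uniform = (qm == qm[0]).all(axis=0)
    q_acgt = np.isin(qm, _ACGT).all(axis=0)
    candidate = q_uniform & q_acgt

    q_bits = _BITS[qm[0]]
    r_bits = _BITS[rm]
    if policy == "conservative":
        # any reference state whose compatibility set contains the query
        # base (incl. N) or is a gap disqualifies
        compat = (r_bits & q_bits[None, :]) != 0
        gap = rm == ord("-")
        disqualified = (compat | gap).any(axis=0)
    else:  # strict_acgt
        is_base = np.isin(rm, _ACGT)
        same = (rm == qm[0][None, :]) & is_base
        disqualified = same.any(axis=0)

    cols = np.flatnonzero(candidate & ~disqualified)
    sites = []
    for c in cols:
        refs = frozenset(chr(x) for x in np.unique(rm[:, c]))
        sites.append(
            MdcSite(alignment.fragment_id, int(c), chr(qm[0, c]), refs)
        )
    return sites


def compare_taxa(
    alignment: Alignment,
    taxon_a_samples: Sequence[str],
    taxon_b_samples: Sequence[str],
    policy: str = "conservative",
) -> tuple[int, int]:
    """Reciprocal MDC counts between two taxa (fixed-in-A-absent-in-B and
    the converse); asymmetric by design."""
    count_a = len(find_mdcs(alignment, taxon_a_samples, taxon_b_samples, policy))
    count_b = len(find_mdcs(alignment, taxon_b_samples, taxon_a_samples, policy))
    return count_a, count_b


def count_pairwise_variants(
    alignment: Alignment, sample_a: str, sample_b: str
) -> int:
    """Columns where both samples have unambiguous, differing bases
    (pairwise deletion of gap/ambiguity columns)."""
    ra = alignment.row(sample_a)
    rb = alignment.row(sample_b)
    both = np.isin(ra, _ACGT) & np.isin(rb, _ACGT)
    return int(((ra != rb) & both).sum())


def discrimination(
    alignments: Sequence[Alignment],
    panel: SpeciesPanel,
    scope: str = "genus",
    policy: str = "conservative",
) -> MdcReport:
    """Per-species MDC counts per fragment and panel discrimination efficiency.

    Under ``scope='genus'`` each species is compared against all samples of
    the other species of its genus; a species that is its genus's sole
    member is flagged not-evaluable and excluded from the efficiency
    denominator.  Under ``scope='panel'`` the reference set is every other
    species in the panel.
    """
    if scope not in ("genus", "panel"):
        raise ConfigurationError(f"unknown scope {scope!r}")
    species = panel.species
    frag_ids = [a.fragment_id for a in alignments]
    counts = pd.DataFrame(0, index=species, columns=frag_ids, dtype=int)
    not_evaluable: list[str] = []

    for sp in species:
        if scope == "genus":
            genus = panel.genus_of(sp)
            ref_species = [s for s in panel.species_in_genus(genus) if s != sp]
        else:
            ref_species = [s for s in species if s != sp]
        if not ref_species:
            not_evaluable.append(sp)
            continue
        for aln in alignments:
            present = set(aln.sample_ids)
            q = [s for s in panel.samples_of(sp) if s in present]
            r = [
                smp
                for rs in ref_species
                for smp in panel.samples_of(rs)
                if smp in present
            ]
            if not q or not r:
                continue
            counts.loc[sp, aln.fragment_id] = len(
                find_mdcs(aln, q, r, policy)
            )

    combined = counts.sum(axis=1)
    evaluable = [s for s in species if s not in not_evaluable]
    identified = combined.loc[evaluable] >= 1
    denom = len(evaluable)
    eff = 100.0 * int(identified.sum()) / denom if denom else 0.0
    return MdcReport(counts, combined, identified, not_evaluable, eff, denom)


def per_fragment_efficiency(report: MdcReport) -> pd.Series:
    """Percent of evaluable species identified by each fragment alone."""
    evaluable = report.identified.index
    denom = len(evaluable)
    if denom == 0:
        return pd.Series(dtype=float)
    return 100.0 * (report.counts.loc[evaluable] >= 1).sum(axis=0) / denom


def sites_table(sites: Sequence[MdcSite]) -> pd.DataFrame:
    """Per-site table with 1-based columns for external reports."""
    return pd.DataFrame(
        [
            {
                "fragment": s.fragment_id,
                "column_1based": s.column + 1,
                "query_state": s.query_state,
                "ref_states": "".join(sorted(s.reference_states)),
            }
            for s in sites
        ],
        columns=["fragment", "column_1based", "query_state", "ref_states"],
    )
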