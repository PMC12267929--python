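"""Synthetic organelle genomes and species panels with exact ground truth.

The generators emulate the data structure of a multi-genus grass species
panel typed against organellar super-barcodes: per-fragment alignments with
species-specific fixed substitutions, intra-species polymorphism, hybrid
taxa sharing a parental haplotype, occasionally missing fragments, and
organelle genome pairs with planted plastid-to-mitochondrion transfers
(including duplicated insertions) and repeats.

Design choices that keep truth exact:

* sequences evolve along the tree under a Jukes-Cantor-type process
  (Poisson substitution events, uniform base exchange), a simple verifiable
  null;
* species-diagnostic sites are planted post hoc at columns invariant across
  the whole panel, so they are fixed within the species and verifiably
  absent in every other species — no homoplasy enters recovery tests;
* intra-species polymorphism is placed only at columns carrying no planted
  diagnostic, so planted counts remain exact.

All randomness flows through one ``numpy.random.default_rng(seed)`` stream
consumed in a documented order, so output is identical across platforms for
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .homology import revcomp
from .seqio import Alignment, Feature, GenomeRecord, SpeciesPanel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# trees

def sim_tree(
    n_species: int,
    seed: int = 0,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    max_tries: int = 100,
) -> dendropy.Tree:
    """Ultrametric birth-death tree with ``n_species`` extant leaves.

    A Gillespie simulation runs forward from a single lineage until the
    extant count reaches ``n_species`` (restarting on total extinction);
    extinct side branches are pruned and all surviving leaves end at the
    stop time.  Branch lengths are in time units; substitution rates are
    applied downstream.  Leaves are labelled sp01, sp02, ...
    """
    if n_species < 3:
        raise ConfigurationError("need n_species >= 3")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        result = _bd_once(n_species, birth_rate, death_rate, rng)
        if result is not None:
            return result
    raise ConfigurationError("birth-death simulation kept going extinct")


def _bd_once(n, birth, death, rng):
    ns = dendropy.TaxonNamespace()
    root = {"children": [], "t0": 0.0, "t1": None, "extinct": False}
    active = [root]
    t = 0.0
    while len(active) < n:
        k = len(active)
        if k == 0:
            return None
        t += rng.exponential(1.0 / ((birth + death) * k))
        lineage = active[int(rng.integers(k))]
        if rng.random() < birth / (birth + death):
            lineage["t1"] = t
            kids = [
                {"children": [], "t0": t, "t1": None, "extinct": False}
                for _ in range(2)
            ]
            lineage["children"] = kids
            active.remove(lineage)
            active.extend(kids)
        else:
            lineage["t1"] = t
            lineage["extinct"] = True
            active.remove(lineage)
    for lineage in active:
        lineage["t1"] = t

    # prune extinct lineages bottom-up
    def prune(node):
        if not node["children"]:
            return None if node["extinct"] else node
        kept = [prune(c) for c in node["children"]]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            child["t0"] = node["t0"]
            return child
        node["children"] = kept
        return node

    root = prune(root)
    if root is None:
        return None

    counter = {"i": 0}

    def build(node):
        nd = dendropy.Node()
        nd.edge.length = node["t1"] - node["t0"]
        if not node["children"]:
            counter["i"] += 1
            label = f"sp{counter['i']:02d}"
            taxon = dendropy.Taxon(label=label)
            ns.add_taxon(taxon)
            nd.taxon = taxon
        for c in node["children"]:
            nd.add_child(build(c))
        return nd

    seed_node = build(root)
    seed_node.edge.length = None
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=seed_node)
    if len(tree.leaf_nodes()) != n:
        return None
    return tree


def expected_yule_height(n: int, birth_rate: float) -> float:
    """Closed-form expected root-to-tip height of the pure-birth simulation
    stopped at the birth that creates the n-th lineage."""
    return sum(1.0 / (birth_rate * k) for k in range(2, n))


# ---------------------------------------------------------------------------
# species panels

@dataclass
class PanelTruth:
    """Ground truth emitted alongside a simulated panel."""

    tree_newick: str
    diagnostic_sites: dict[str, list[tuple[str, int, str]]]  # species -> (frag, col, base)
    polymorphic_sites: dict[str, list[tuple[str, int]]]      # sample -> (frag, col)
    hybrids: list[tuple[str, str]]
    missing: list[tuple[str, str]]
    presence: pd.DataFrame                                   # species x fragment

    @property
    def identifiable_species(self) -> set[str]:
        return {sp for sp, sites in self.diagnostic_sites.items() if sites}

    def expected_efficiency(self, evaluable: list[str]) -> float:
        ident = [sp for sp in evaluable if self.diagnostic_sites.get(sp)]
        return 100.0 * len(ident) / len(evaluable) if evaluable else 0.0


def _random_seq(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _mutate(rng, seq: np.ndarray, n_events: int, allowed=None) -> None:
    """Apply substitution events in place: random site, random other base."""
    if n_events <= 0:
        return
    pool = allowed if allowed is not None else np.arange(seq.size)
    if pool.size == 0:
        return
    for pos in rng.choice(pool, size=n_events, replace=True):
        old = seq[pos]
        choices = _BASES[_BASES != old]
        seq[pos] = rng.choice(choices)


def sim_panel(
    tree: dendropy.Tree,
    fragment_lengths: list[int] | None = None,
    subst_rate: float = 0.001,
    diagnostic_rate_per_species: float = 2.0,
    diagnostic_counts: dict[str, int] | None = None,
    polymorphism_rate: float = 0.0,
    samples_per_species: int = 1,
    hybrids: list[tuple[str, str]] = (),
    missing: list[tuple[str, str]] = (),
    n_genera: int = 6,
    genera: dict[str, str] | None = None,
    gc: float = 0.45,
    seed: int = 0,
) -> tuple[list[Alignment], SpeciesPanel, PanelTruth]:
    """Simulate per-fragment alignments for the species on a tree.

    Fragments default to 29 lengths spread log-uniformly over the range
    typical of clean mitogenome fragments (about 1.4-26 kb).  Sequences
    evolve under a JC-type process; then species-diagnostic sites are
    planted at invariant columns (``diagnostic_counts`` overrides the
    Poisson draw from ``diagnostic_rate_per_species``), hybrids overwrite
    their haplotype with the donor's before planting, per-sample
    polymorphism is added at diagnostic-free columns, and fragments listed
    in ``missing`` become all-gap rows for that species.
    """
    if not (0 <= subst_rate <= 0.1 and 0 <= polymorphism_rate <= 0.1):
        raise ConfigurationError("rates must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if fragment_lengths is None:
        fragment_lengths = [
            int(x) for x in np.geomspace(1400, 26000, 29).round(-2)
        ]
    frag_ids = [f"c{i}" for i in range(1, len(fragment_lengths) + 1)]

    if genera is None:
        blocks = np.array_split(np.arange(len(species)), n_genera)
        genera = {}
        for g, block in enumerate(blocks, 1):
            for idx in block:
                genera[species[idx]] = f"G{g}"

    # evolve each fragment along the tree
    leaf_seqs: dict[str, dict[str, np.ndarray]] = {f: {} for f in frag_ids}
    for fid, L in zip(frag_ids, fragment_lengths):
        root_seq = _random_seq(rng, L, gc)
        stack = [(tree.seed_node, root_seq)]
        while stack:
            node, seq = stack.pop()
            for child in node.child_nodes():
                cseq = seq.copy()
                bl = child.edge.length or 0.0
                _mutate(rng, cseq, int(rng.poisson(subst_rate * bl * L)))
                if child.is_leaf():
                    leaf_seqs[fid][child.taxon.label] = cseq
                else:
                    stack.append((child, cseq))

    # hybrids copy the donor haplotype before any planting
    hybrids = list(hybrids)
    for hyb, donor in hybrids:
        for fid in frag_ids:
            leaf_seqs[fid][hyb] = leaf_seqs[fid][donor].copy()

    missing = [(sp, f) for sp, f in missing]
    missing_set = set(missing)

    # plant species-diagnostic sites at panel-invariant columns
    if diagnostic_counts is None:
        diagnostic_counts = {
            sp: int(rng.poisson(diagnostic_rate_per_species)) for sp in species
        }
    diag_truth: dict[str, list[tuple[str, int, str]]] = {sp: [] for sp in species}
    used_cols: dict[str, set[int]] = {f: set() for f in frag_ids}
    for sp in species:
        want = diagnostic_counts.get(sp, 0)
        if want == 0:
            continue
        open_frags = [f for f in frag_ids if (sp, f) not in missing_set]
        if not open_frags:
            raise ConfigurationError(f"species {sp} missing from all fragments")
        for _ in range(want):
            fid = open_frags[int(rng.integers(len(open_frags)))]
            mat = np.vstack([leaf_seqs[fid][s] for s in species])
            invariant = np.flatnonzero(
                (mat == mat[0]).all(axis=0)
            )
            invariant = [c for c in invariant if c not in used_cols[fid]]
            if not invariant:
                raise ConfigurationError(
                    f"no invariant column left in {fid} to plant a diagnostic "
                    "site; lower subst_rate or diagnostic counts"
                )
            col = int(invariant[int(rng.integers(len(invariant)))])
            old = leaf_seqs[fid][species[0]][col]
            new = rng.choice(_BASES[_BASES != old])
            leaf_seqs[fid][sp][col] = new
            used_cols[fid].add(col)
            diag_truth[sp].append((fid, col, chr(new)))

    # expand to samples, add polymorphism, apply missing fragments
    rows = []
    sample_names: dict[str, list[str]] = {}
    for sp in species:
        names = [f"{sp}_s{i}" for i in range(1, samples_per_species + 1)]
        sample_names[sp] = names
        for name in names:
            rows.append(
                {"sample_id": name, "species": sp, "genus": genera[sp],
                 "subspecies": ""}
            )
    panel = SpeciesPanel(pd.DataFrame(rows))

    poly_truth: dict[str, list[tuple[str, int]]] = {}
    alignments: list[Alignment] = []
    for fid, L in zip(frag_ids, fragment_lengths):
        free = np.array(
            sorted(set(range(L)) - used_cols[fid]), dtype=int
        )
        mat_rows = []
        ids = []
        for sp in species:
            base = leaf_seqs[fid][sp]
            for name in sample_names[sp]:
                row = base.copy()
                if (sp, fid) in missing_set:
                    row[:] = ord("-")
                elif polymorphism_rate > 0:
                    n_events = int(rng.poisson(polymorphism_rate * L))
                    before = row.copy()
                    _mutate(rng, row, n_events, allowed=free)
                    changed = np.flatnonzero(before != row)
                    poly_truth.setdefault(name, []).extend(
                        (fid, int(c)) for c in changed
                    )
                ids.append(name)
                mat_rows.append(row)
        alignments.append(Alignment(fid, ids, np.vstack(mat_rows)))

    presence = pd.DataFrame(
        True, index=species, columns=frag_ids
    )
    for sp, fid in missing:
        presence.loc[sp, fid] = False

    truth = PanelTruth(
        tree_newick=tree.as_string(schema="newick"),
        diagnostic_sites=diag_truth,
        polymorphic_sites=poly_truth,
        hybrids=hybrids,
        missing=missing,
        presence=presence,
    )
    return alignments, panel, truth


def study_panel(
    seed: int = 0,
    n_species: int = 33,
    n_identifiable: int = 25,
    samples_per_species: int = 1,
) -> tuple[list[Alignment], SpeciesPanel, PanelTruth]:
    """A study-scale panel: 33 species in six genera, 29 fragments.

    Emulates the structure of a multi-genus grass panel typed against a
    mitogenome super-barcode: 25 of the 33 species carry at least one
    planted species-diagnostic site; the eight species without diagnostics
    sit together in the largest genus (so none of them is trivially unique
    within its genus) and include one hybrid/donor pair sharing a
    haplotype; one fragment is absent from two species, which enter it as
    all-gap rows.  Between-species background substitution is switched off
    so the planted truth is the exact expectation of the discrimination
    report.
    """
    rng = np.random.default_rng(seed)
    tree = sim_tree(n_species, seed=seed)
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n_blank = n_species - n_identifiable
    blank = species[:n_blank]
    identifiable = species[n_blank:]
    # the blank species share one large genus with some identifiable ones;
    # remaining genera split the rest
    genera: dict[str, str] = {sp: "G1" for sp in blank}
    big_extra = identifiable[: max(0, 10 - n_blank)]
    for sp in big_extra:
        genera[sp] = "G1"
    rest = [sp for sp in identifiable if sp not in big_extra]
    blocks = np.array_split(np.arange(len(rest)), 5)
    for g, block in enumerate(blocks, 2):
        for idx in block:
            genera[rest[idx]] = f"G{g}"
    counts = {sp: 0 for sp in blank}
    counts.update({sp: int(rng.poisson(2.0)) + 1 for sp in identifiable})
    hybrids = [(blank[0], blank[1])] if n_blank >= 2 else []
    missing = [(identifiable[0], "c18"), (identifiable[1], "c18")]
    return sim_panel(
        tree,
        subst_rate=0.0,
        diagnostic_counts=counts,
        samples_per_species=samples_per_species,
        hybrids=hybrids,
        missing=missing,
        genera=genera,
        seed=seed + 1,
    )


# ---------------------------------------------------------------------------
# organelle genome pairs

@dataclass
class GenomeTruth:
    """Planted features of a simulated mitogenome/plastome pair."""

    mtpt: list[dict] = field(default_factory=list)     # mito/plastid intervals etc.
    repeats: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    complete_genes: list[str] = field(default_factory=list)
    partial_genes: list[str] = field(default_factory=list)

    @property
    def n_unique_sources(self) -> int:
        return len({m["source_id"] for m in self.mtpt})

    def mtpt_mask(self) -> list[tuple[int, int]]:
        return [tuple(m["mito_interval"]) for m in self.mtpt]


def _place_disjoint(rng, n_slots: int, lengths: list[int], genome_len: int,
                    margin: int = 50, max_tries: int = 2000):
    """Draw disjoint half-open intervals of given lengths, margin apart."""
    placed: list[tuple[int, int]] = []
    for L in lengths:
        for attempt in range(max_tries):
            s = int(rng.integers(margin, genome_len - L - margin))
            iv = (s, s + L)
            if all(iv[1] + margin <= p[0] or p[1] + margin <= iv[0]
                   for p in placed):
                placed.append(iv)
                break
        else:
            raise ConfigurationError(
                "could not place disjoint intervals; genome too small"
            )
    return placed


def sim_organelles(
    mito_len: int = 424_370,
    plastid_len: int = 135_000,
    n_mtpt: int = 30,
    n_unique_sources: int = 20,
    mtpt_len_range: tuple[int, int] = (64, 4310),
    mtpt_divergence: float = 0.03,
    n_repeats: int = 2,
    repeat_len: int = 1000,
    n_full_gene_transfers: int = 5,
    n_partial_gene_transfers: int = 4,
    gc: float = 0.44,
    seed: int = 0,
) -> tuple[GenomeRecord, GenomeRecord, GenomeTruth]:
    """Simulate a mitogenome/plastome pair with planted MTPTs and repeats.

    ``n_unique_sources`` plastid source regions are drawn; the first
    ``n_mtpt - n_unique_sources`` of them are inserted twice into the
    mitogenome (duplicated transfers), the rest once, for ``n_mtpt``
    insertions total.  Each insertion is substituted at ``mtpt_divergence``
    and placed on a random strand.  Gene annotations are laid out so that
    exactly ``n_full_gene_transfers`` plastid genes lie fully inside source
    regions and ``n_partial_gene_transfers`` straddle source boundaries.
    Defaults emulate a grass organelle pair: a ~424 kb mitogenome at 44%
    GC against a ~135 kb plastome, 30 transfers collapsing to 20 unique
    regions.
    """
    if not (0 <= mtpt_divergence <= 0.2):
        raise ConfigurationError("mtpt_divergence must lie in [0, 0.2]")
    if n_unique_sources > n_mtpt:
        raise ConfigurationError("n_unique_sources cannot exceed n_mtpt")
    if n_full_gene_transfers + n_partial_gene_transfers > n_unique_sources:
        raise ConfigurationError(
            "full+partial gene transfers cannot exceed n_unique_sources"
        )
    rng = np.random.default_rng(seed)

    lo, hi = mtpt_len_range
    # skewed log-spaced lengths: many short transfers, few long ones, as in
    # real organellar transfer landscapes; the smallest sources are the ones
    # inserted twice.  With the defaults the planted total is ~19.3 kb,
    # about 4.55% of the mitogenome.
    skew = 1.3425
    frac = (np.arange(n_unique_sources) / max(n_unique_sources - 1, 1)) ** skew
    src_lengths = [
        int(round(x)) for x in lo * np.exp(np.log(hi / lo) * frac)
    ]
    total_insert = sum(src_lengths) + sum(src_lengths[: n_mtpt - n_unique_sources])
    if total_insert >= 0.5 * mito_len:
        raise ConfigurationError("planted MTPT length exceeds half the mitogenome")

    plastid_seq = _random_seq(rng, plastid_len, gc)
    mito_seq = _random_seq(rng, mito_len, gc)

    src_intervals = _place_disjoint(rng, n_unique_sources, src_lengths, plastid_len)

    # plastid gene annotations: full genes inside the largest sources,
    # partial genes straddling source boundaries
    order = sorted(range(n_unique_sources), key=lambda i: -src_lengths[i])
    features: list[Feature] = []
    complete_genes, partial_genes = [], []
    margin = 30
    for gi in range(n_full_gene_transfers):
        s, e = src_intervals[order[gi]]
        if e - s < 2 * margin + 60:
            raise ConfigurationError("source region too short for a full gene")
        glen = min(int(rng.integers(60, max(61, (e - s) - 2 * margin))), e - s - 2 * margin)
        gs = int(rng.integers(s + margin, e - margin - glen + 1))
        name = f"fullgene{gi + 1}"
        features.append(Feature(name, gs, gs + glen, "+", "gene"))
        complete_genes.append(name)
    for gi in range(n_partial_gene_transfers):
        s, e = src_intervals[order[gi + n_full_gene_transfers]]
        # gene starts inside the source and runs past its end
        glen = 300
        gs = max(0, e - 100)
        ge = min(plastid_len, gs + glen)
        name = f"partgene{gi + 1}"
        features.append(Feature(name, gs, ge, "+", "gene"))
        partial_genes.append(name)

    # insertion schedule: duplicated sources first
    schedule = list(range(n_mtpt - n_unique_sources)) + list(range(n_unique_sources))
    ins_lengths = [src_lengths[i] for i in schedule]
    mito_slots = _place_disjoint(
        rng, len(schedule), ins_lengths + [repeat_len] * (2 * n_repeats), mito_len
    )
    ins_slots = mito_slots[: len(schedule)]
    repeat_slots = mito_slots[len(schedule):]

    truth = GenomeTruth()
    for slot, src_idx in zip(ins_slots, schedule):
        s, e = src_intervals[src_idx]
        segment = plastid_seq[s:e].copy()
        n_sub = int(rng.poisson(mtpt_divergence * (e - s)))
        _mutate(rng, segment, n_sub)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seg_str = revcomp(segment.tobytes().decode())
            segment = np.frombuffer(seg_str.encode(), dtype=np.uint8).copy()
        ms, me = slot
        mito_seq[ms:me] = segment
        truth.mtpt.append(
            {
                "source_id": src_idx,
                "mito_interval": (ms, me),
                "plastid_interval": (s, e),
                "strand": strand,
                "divergence": mtpt_divergence,
            }
        )

    for r in range(n_repeats):
        a = repeat_slots[2 * r]
        b = repeat_slots[2 * r + 1]
        mito_seq[b[0] : b[1]] = mito_seq[a[0] : a[1]]
        truth.repeats.append((a, b))

    truth.complete_genes = complete_genes
    truth.partial_genes = partial_genes

    plastid = GenomeRecord(
        "plastome_sim", plastid_seq.tobytes().decode(), circular=True,
        features=features,
    )
    mito = GenomeRecord("mitogenome_sim", mito_seq.tobytes().decode(), circular=True)
    return mito, plastid, truth


# ---------------------------------------------------------------------------
# coding sequences

def sim_cds(
    n_genes: int,
    len_range_aa: tuple[int, int] = (80, 500),
    codon_bias_profile: dict[str, float] | str = "uniform",
    table_id: int = 1,
    seed: int = 0,
) -> dict[str, str]:
    """Draw coding sequences codon-by-codon from a usage profile.

    ``codon_bias_profile`` maps sense codons to sampling weights (need not
    be normalized) or ``"uniform"``.  Each gene ends with a random stop
    codon.  The profile is recoverable from pooled counts at large n.
    """
    from Bio.Data import CodonTable

    if n_genes < 1 or len_range_aa[0] < 1:
        raise ConfigurationError("need at least one gene of >= 1 codon")
    tbl = CodonTable.unambiguous_dna_by_id[table_id]
    sense = sorted(tbl.forward_table)
    stops = sorted(tbl.stop_codons)
    if codon_bias_profile == "uniform":
        weights = np.ones(len(sense))
    else:
        weights = np.array([float(codon_bias_profile.get(c, 0.0)) for c in sense])
        if weights.sum() <= 0:
            raise ConfigurationError("profile has no mass on sense codons")
    p = weights / weights.sum()
    rng = np.random.default_rng(seed)
    genes = {}
    lo, hi = len_range_aa
    for g in range(1, n_genes + 1):
        n_aa = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(sense), size=n_aa, p=p)
        seq = "".join(sense[i] for i in idx) + stops[int(rng.integers(len(stops)))]
        genes[f"gene{g}"] = seq
    return genes
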