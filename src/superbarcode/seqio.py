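"""Input/output for the formats the pipeline touches, and coordinate discipline.

All internal coordinates are 0-based half-open.  GFF3 (1-based inclusive) and
BED (0-based half-open) are converted at the boundary.  Circular sequences are
linearized at position 0; features that span the origin are stored split into
two intervals sharing a name.

Ambiguity codes are kept in memory as-is; downstream policies decide their
semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    ConfigurationError,
    CoordinateError,
    TreeError,
)

IUPAC_GAP = b"ACGTRYSWKMBDHVN-"
_ALLOWED = np.zeros(256, dtype=bool)
_ALLOWED[np.frombuffer(IUPAC_GAP, dtype=np.uint8)] = True

#: expansion of each IUPAC nucleotide code into the set of ACGT bases it covers
AMBIGUITY = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

FEATURE_KINDS = {"gene", "CDS", "tRNA", "rRNA", "orf"}


def encode(seq: str) -> np.ndarray:
    """Uppercase a nucleotide string and encode as an ASCII uint8 array."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    bad = ~_ALLOWED[arr]
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise AlphabetError(
            f"illegal character {chr(arr[pos])!r} at position {pos}"
        )
    return arr


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass
class Alignment:
    """A multi-species alignment: uniform-length rows over IUPAC+gap."""

    fragment_id: str
    sample_ids: list[str]
    matrix: np.ndarray  # (n_samples, length) uint8, uppercase ASCII

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise AlignmentShapeError("matrix must be 2-dimensional")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise AlignmentShapeError("sample_ids do not match matrix rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            raise AlignmentShapeError(f"duplicate sample ids: {sorted(dupes)}")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def row(self, sample_id: str) -> np.ndarray:
        return self.matrix[self.sample_ids.index(sample_id)]

    def subset(self, sample_ids: Sequence[str]) -> "Alignment":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return Alignment(self.fragment_id, list(sample_ids), self.matrix[idx])


@dataclass
class Feature:
    name: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    kind: str   # gene, CDS, tRNA, rRNA, orf, other


@dataclass
class GenomeRecord:
    """A single (possibly circular) organellar genome with annotations."""

    seq_id: str
    sequence: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        encode(self.sequence)  # validates alphabet
        n = len(self.sequence)
        for f in self.features:
            if not (0 <= f.start < f.end <= n):
                raise CoordinateError(
                    f"feature {f.name!r} [{f.start},{f.end}) outside sequence "
                    f"of length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


class SpeciesPanel:
    """Sample -> species -> genus mapping defining query/reference partitions."""

    def __init__(self, table: pd.DataFrame):
        required = {"sample_id", "species", "genus"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigurationError(f"panel missing columns: {sorted(missing)}")
        if table["sample_id"].duplicated().any():
            d = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ConfigurationError(f"duplicate sample ids in panel: {d}")
        # species -> genus must be a function
        g = table.groupby("species")["genus"].nunique()
        conflicted = g[g > 1].index.tolist()
        if conflicted:
            raise ConfigurationError(
                f"species mapped to multiple genera: {conflicted}"
            )
        if "subspecies" not in table.columns:
            table = table.assign(subspecies="")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesPanel":
        return cls(pd.read_csv(path, sep="\t", dtype=str).fillna(""))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def species_of(self, sample_id: str) -> str:
        hit = self.table.loc[self.table["sample_id"] == sample_id, "species"]
        if hit.empty:
            raise KeyError(sample_id)
        return hit.iloc[0]

    def genus_of(self, species: str) -> str:
        hit = self.table.loc[self.table["species"] == species, "genus"]
        if hit.empty:
            raise KeyError(species)
        return hit.iloc[0]

    def samples_of(self, species: str) -> list[str]:
        return self.table.loc[
            self.table["species"] == species, "sample_id"
        ].tolist()

    def species_in_genus(self, genus: str) -> list[str]:
        return sorted(
            self.table.loc[self.table["genus"] == genus, "species"].unique()
        )


# ---------------------------------------------------------------------------
# alignments

def read_alignment(path: str | Path, fragment_id: str | None = None) -> Alignment:
    """Read an aligned multi-FASTA; rows are case-folded to uppercase."""
    path = Path(path)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    length: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            arr = encode(str(rec.seq))
        except AlphabetError as e:
            raise AlphabetError(f"record {rec.id!r}: {e}") from None
        if length is None:
            length = arr.size
        elif arr.size != length:
            raise AlignmentShapeError(
                f"record {rec.id!r} has length {arr.size}, expected {length}"
            )
        ids.append(rec.id)
        rows.append(arr)
    if not rows:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    return Alignment(fragment_id or path.stem, ids, np.vstack(rows))


def write_alignment(aln: Alignment, path: str | Path, wrap: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.sample_ids, aln.matrix):
            fh.write(f">{sid}\n")
            s = decode(row)
            for i in range(0, len(s), wrap):
                fh.write(s[i : i + wrap] + "\n")


def concat_alignments(
    alignments: Sequence[Alignment],
    panel: SpeciesPanel | None = None,
    missing_policy: str = "fill_gaps",
) -> tuple[Alignment, dict[str, tuple[int, int]]]:
    """Concatenate per-fragment alignments over a shared sample universe.

    Returns the concatenated alignment and a partition map of half-open
    column intervals per fragment_id.  Under ``fill_gaps`` a sample absent
    from a fragment gets an all-gap block; under ``drop_sample`` only samples
    present in every fragment are kept.
    """
    if not alignments:
        raise ConfigurationError("concat_alignments: empty input list")
    if missing_policy not in ("fill_gaps", "drop_sample"):
        raise ConfigurationError(f"unknown missing_policy {missing_policy!r}")
    universe: list[str] = []
    seen: set[str] = set()
    if panel is not None:
        universe = [s for s in panel.sample_ids]
        seen = set(universe)
        for a in alignments:
            for s in a.sample_ids:
                if s not in seen:
                    raise ConfigurationError(
                        f"sample {s!r} not in panel"
                    )
    else:
        for a in alignments:
            for s in a.sample_ids:
                if s not in seen:
                    universe.append(s)
                    seen.add(s)
    if missing_policy == "drop_sample":
        universe = [
            s
            for s in universe
            if all(s in a.sample_ids for a in alignments)
        ]
        if not universe:
            raise ConfigurationError("no sample present in every fragment")

    total = sum(a.length for a in alignments)
    out = np.full((len(universe), total), ord("-"), dtype=np.uint8)
    partition: dict[str, tuple[int, int]] = {}
    offset = 0
    for a in alignments:
        partition[a.fragment_id] = (offset, offset + a.length)
        index = {s: i for i, s in enumerate(a.sample_ids)}
        for r, s in enumerate(universe):
            if s in index:
                out[r, offset : offset + a.length] = a.matrix[index[s]]
        offset += a.length
    return Alignment("concat", universe, out), partition


# ---------------------------------------------------------------------------
# genomes

def _parse_gff3_line(line: str, lineno: int):
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 9:
        raise CoordinateError(f"GFF3 line {lineno}: expected 9 columns")
    seqid, _src, kind, start, end, _score, strand, _phase, attrs = parts
    attr = {}
    for kv in attrs.split(";"):
        if "=" in kv:
            k, v = kv.split("=", 1)
            attr[k.strip()] = v.strip()
    name = attr.get("Name") or attr.get("ID") or attr.get("gene") or kind
    return seqid, kind, int(start), int(end), strand, name


def read_genome(
    fasta_path: str | Path,
    gff3_path: str | Path | None = None,
    circular: bool | None = None,
) -> GenomeRecord:
    """Read a genome FASTA plus optional GFF3 annotations.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Circularity is taken from ``circular=true`` in the FASTA description or
    the explicit argument.  On a circular genome a feature whose GFF3 start
    exceeds its end is interpreted as spanning the origin and stored split
    into two intervals sharing a name.
    """
    recs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(recs) != 1:
        raise ConfigurationError(
            f"{fasta_path}: expected exactly one record, found {len(recs)}"
        )
    rec = recs[0]
    if circular is None:
        circular = "circular=true" in rec.description.lower()
    n = len(rec.seq)
    features: list[Feature] = []
    if gff3_path is not None:
        with open(gff3_path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                seqid, kind, start1, end1, strand, name = _parse_gff3_line(
                    line, lineno
                )
                if seqid != rec.id:
                    raise CoordinateError(
                        f"GFF3 line {lineno}: seqid {seqid!r} does not match "
                        f"FASTA header {rec.id!r}"
                    )
                if kind not in FEATURE_KINDS:
                    warnings.warn(
                        f"GFF3 line {lineno}: unknown feature kind {kind!r}, "
                        "kept as 'other'"
                    )
                    kind = "other"
                if circular and start1 > end1:
                    # spans the origin: split at position 0
                    features.append(Feature(name, start1 - 1, n, strand, kind))
                    features.append(Feature(name, 0, end1, strand, kind))
                    continue
                start, end = start1 - 1, end1
                if not (0 <= start < end <= n):
                    raise CoordinateError(
                        f"GFF3 line {lineno}: feature {name!r} "
                        f"[{start1},{end1}] outside sequence of length {n}"
                    )
                features.append(Feature(name, start, end, strand, kind))
    return GenomeRecord(rec.id, str(rec.seq).upper(), circular, features)


def write_bed(intervals: Iterable[tuple[int, int]], path: str | Path,
              name: str = "region") -> None:
    """Write half-open intervals as BED3+name rows."""
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(intervals, 1):
            fh.write(f"{name}\t{s}\t{e}\t{name}_{i}\n")


def read_bed(path: str | Path) -> list[tuple[int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((int(parts[1]), int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# trees

def read_tree(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree; internal-node labels are read as supports.

    Numeric internal labels become ``node.support`` (percent).  Duplicate
    leaf labels raise :class:`TreeError`.
    """
    src = str(source)
    if "(" in src and ";" in src:
        data, kwargs = src, {"data": src}
    else:
        kwargs = {"path": src}
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            suppress_internal_node_taxa=True,
            **kwargs,
        )
    except Exception as e:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick: {e}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate leaf labels: {dupes}")
    for node in tree.preorder_internal_node_iter():
        node.support = None
        if node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
        if node.support is not None and not (0 <= node.support <= 100):
            raise TreeError(f"support {node.support} outside [0,100]")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick with supports as internal-node labels."""
    clone = tree.clone(depth=1)
    for node in clone.preorder_internal_node_iter():
        sup = getattr(node, "support", None)
        if sup is not None:
            node.label = format(sup, "g")
    s = clone.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(s)
    return s
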