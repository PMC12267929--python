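"""Selection of candidate barcode fragments from a reference mitogenome.

Formalizes the criteria for a usable mitochondrial barcode fragment:
no overlap with plastid-transfer (MTPT) or repeat masks, a minimum length,
and presence across (most of) the species panel.  Surviving intervals are
numbered c1, c2, ... in genome order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import divstats, mdc as mdc_mod
from .errors import ConfigurationError, CoordinateError
from .homology import merge_intervals
from .seqio import Alignment, GenomeRecord, SpeciesPanel

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Fragment:
    fragment_id: str          # c1 ... cN in genome order
    start: int                # half-open on the reference mitogenome
    end: int
    presence_frac: float = 1.0
    notes: str = ""

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


def complement_intervals(
    masks: Sequence[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Complement of the union of masks within [0, length)."""
    merged = merge_intervals(list(masks))
    out = []
    prev = 0
    for s, e in merged:
        if not (0 <= s < e <= length):
            raise CoordinateError(f"mask [{s},{e}) outside [0,{length})")
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


def select_fragments(
    genome: GenomeRecord,
    masks: Sequence[tuple[int, int]] = (),
    presence: Callable[[str, tuple[int, int]], bool] | pd.DataFrame | None = None,
    species: Sequence[str] | None = None,
    min_len: int = 1000,
    min_presence_frac: float = 0.9,
) -> list[Fragment]:
    """Unmasked intervals >= min_len present in enough species.

    ``presence`` may be a callable (species, interval) -> bool, a DataFrame
    indexed by species with interval tuples as columns, or None (presence
    filtering skipped).  Presence is assessed per species, not per sample.
    """
    if not (0 < min_presence_frac <= 1):
        raise ConfigurationError("min_presence_frac must be in (0, 1]")
    candidates = [
        iv
        for iv in complement_intervals(masks, len(genome))
        if iv[1] - iv[0] >= min_len
    ]
    if not candidates:
        warnings.warn("mask complement leaves no interval >= min_len")
        return []

    lookup = presence
    if isinstance(presence, pd.DataFrame):
        if species is None:
            species = list(presence.index)
        table = {
            (sp, tuple(col)): bool(presence.loc[sp][col])
            for sp in presence.index
            for col in presence.columns
        }
        lookup = lambda sp, iv: table[(sp, tuple(iv))]  # noqa: E731
    elif presence is not None and species is None:
        raise ConfigurationError("species list required with a presence callable")

    fragments = []
    for iv in candidates:
        frac = 1.0
        if lookup is not None:
            hits = sum(bool(lookup(sp, iv)) for sp in species)
            frac = hits / len(species)
            if frac < min_presence_frac:
                continue
        fragments.append(Fragment("", iv[0], iv[1], presence_frac=frac))
    for i, f in enumerate(fragments, 1):
        f.fragment_id = f"c{i}"
    return fragments


def presence_from_alignments(
    fragments: Sequence[Fragment],
    alignments: dict[str, Alignment],
    panel: SpeciesPanel,
    min_cover_frac: float = 0.5,
) -> pd.DataFrame:
    """Presence of each fragment in each species from its alignment.

    A species is present in a fragment when at least one of its samples
    covers >= ``min_cover_frac`` of the fragment's reference length with
    non-gap characters.
    """
    species = panel.species
    data = {}
    for f in fragments:
        col = []
        aln = alignments.get(f.fragment_id)
        for sp in species:
            present = False
            if aln is not None:
                for smp in panel.samples_of(sp):
                    if smp not in aln.sample_ids:
                        continue
                    row = aln.row(smp)
                    nongap = int((row != ord("-")).sum())
                    if nongap >= min_cover_frac * len(f):
                        present = True
                        break
            col.append(present)
        data[f.fragment_id] = col
    return pd.DataFrame(data, index=species)


def fragment_report(
    fragments: Sequence[Fragment],
    alignments: dict[str, Alignment],
    panel: SpeciesPanel | None = None,
    policy: str = "conservative",
) -> pd.DataFrame:
    """Per-fragment summary: lengths, GC, identity, variable sites and the
    number of species the fragment alone discriminates (if a panel is given).
    Fragments without an alignment get NA columns with a warning.
    """
    rows = []
    for f in fragments:
        aln = alignments.get(f.fragment_id)
        row: dict = {
            "fragment_id": f.fragment_id,
            "ref_start": f.start,
            "ref_end": f.end,
            "ref_length": len(f),
            "presence_frac": round(f.presence_frac, 4),
        }
        if aln is None:
            warnings.warn(f"fragment {f.fragment_id} has no alignment")
            row.update(
                aligned_length=pd.NA, gc_pct=pd.NA, pairwise_identity_pct=pd.NA,
                variable_sites=pd.NA, mdc_species=pd.NA,
            )
        else:
            row["aligned_length"] = aln.length
            row["gc_pct"] = round(divstats.gc_content(aln), 2)
            row["pairwise_identity_pct"] = round(
                divstats.pairwise_identity(aln), 3
            )
            row["variable_sites"] = divstats.variable_sites(aln)
            if panel is not None:
                rep = mdc_mod.discrimination([aln], panel, policy=policy)
                row["mdc_species"] = int(rep.identified.sum())
            else:
                row["mdc_species"] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows)
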