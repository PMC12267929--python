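"""Detection of plastid-derived (MTPT) and repeated regions by local alignment.

The scanner is a classic seed-and-extend design: every exact shared k-mer
between the two genomes seeds an ungapped X-drop extension along its
diagonal; candidate segments are then re-aligned gapped (affine scoring,
Smith-Waterman on a padded window) to their maximal-scoring segment pair.
Both strands of the subject are searched.  Expectation values follow the
Karlin-Altschul formula E = K*m*n*exp(-lambda*S); the ungapped lambda for
the scoring scheme is solved exactly at construction and used as an
approximation for gapped scores, so the e-value cutoff is best treated as
configurable rather than exact.

Hits with identity below a configurable review threshold (default 80%) are
flagged ``low_identity`` in the report but never filtered automatically:
sequence similarity between analogous genes (e.g. ribosomal RNAs) can
produce qualifying hits that are not evidence of transfer, and that call is
editorial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy.optimize import brentq

from .errors import ConfigurationError
from .seqio import Feature, GenomeRecord, encode

# Karlin-Altschul K for ungapped uniform-composition schemes, keyed by
# (match, mismatch-penalty).  Values follow the standard blastn tables.
_K_TABLE = {(2, 3): 0.41, (1, 2): 0.46, (1, 1): 0.35}

_COMP = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass
class ScoringScheme:
    """blastn-like scoring: match reward, mismatch penalty, affine gaps.

    ``mismatch``, ``gap_open`` and ``gap_extend`` are stored as non-negative
    penalties.  ``karlin_lambda`` is solved from
    sum_ij p_i p_j exp(lambda*s_ij) = 1 at uniform base composition;
    ``karlin_k`` comes from a precomputed table for known schemes or must be
    supplied by the user.
    """

    match: int = 2
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    karlin_k: float | None = None
    karlin_lambda: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch < 0:
            raise ConfigurationError("reward must be > 0, penalty >= 0")
        expected = (self.match - 3 * self.mismatch) / 4.0
        if expected >= 0:
            raise ConfigurationError(
                "degenerate scoring: expected score per pair is non-negative, "
                "Karlin-Altschul lambda is undefined"
            )

        def f(lam: float) -> float:
            return (
                0.25 * math.exp(lam * self.match)
                + 0.75 * math.exp(-lam * self.mismatch)
                - 1.0
            )

        self.karlin_lambda = float(brentq(f, 1e-6, 10.0))
        if self.karlin_k is None:
            key = (self.match, self.mismatch)
            if key not in _K_TABLE:
                raise ConfigurationError(
                    f"no precomputed Karlin-Altschul K for scheme {key}; "
                    "pass karlin_k explicitly"
                )
            self.karlin_k = _K_TABLE[key]

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = self.match
        al.mismatch_score = -self.mismatch
        # affine: a gap of length L costs gap_open + L*gap_extend
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al


@dataclass
class HomologyHit:
    """A scored local-alignment interval pair (half-open, forward coords)."""

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    raw_score: float
    bit_score: float
    evalue: float
    pct_identity: float
    aln_len: int

    @property
    def query_interval(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def subject_interval(self) -> tuple[int, int]:
        return (self.subject_start, self.subject_end)


@dataclass
class RegionPair:
    """A deduplicated cluster of mutually overlapping hits."""

    query_region: tuple[int, int]
    subject_region: tuple[int, int]
    members: list[int]
    genes: list[tuple[str, str]] = field(default_factory=list)


def evalue(raw_score: float, m: int, n: int, scoring: ScoringScheme) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)."""
    if m <= 0 or n <= 0:
        raise ConfigurationError("search-space sizes m, n must be positive")
    return scoring.karlin_k * m * n * math.exp(-scoring.karlin_lambda * raw_score)


def bit_score(raw_score: float, scoring: ScoringScheme) -> float:
    return (scoring.karlin_lambda * raw_score - math.log(scoring.karlin_k)) / math.log(2)


def _extend_dir(a, b, qi, si, step, scoring, xdrop):
    """Ungapped X-drop extension from (qi, si) exclusive, in direction step.

    Returns (best_offset, best_delta): number of columns of the best-scoring
    extension and its score contribution.
    """
    best = 0.0
    cur = 0.0
    best_off = 0
    off = 0
    la, lb = len(a), len(b)
    q, s = qi, si
    while 0 <= q < la and 0 <= s < lb:
        cur += scoring.match if a[q] == b[s] else -scoring.mismatch
        off += 1
        if cur > best:
            best, best_off = cur, off
        elif best - cur > xdrop:
            break
        q += step
        s += step
    return best_off, best


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code of each k-mer; -1 where a non-ACGT base intrudes."""
    L = arr.size
    if L < k:
        return np.empty(0, dtype=np.int64)
    vals = np.full(L, -1, dtype=np.int64)
    for v, b in enumerate(b"ACGT"):
        vals[arr == b] = v
    codes = np.zeros(L - k + 1, dtype=np.int64)
    valid = np.ones(L - k + 1, dtype=bool)
    for t in range(k):
        window = vals[t : L - k + 1 + t]
        codes = codes * 4 + np.maximum(window, 0)
        valid &= window >= 0
    codes[~valid] = -1
    return codes


def _code_index(codes: np.ndarray) -> dict[int, np.ndarray]:
    """Map k-mer code -> sorted array of positions."""
    pos = np.flatnonzero(codes >= 0)
    if pos.size == 0:
        return {}
    order = pos[np.argsort(codes[pos], kind="stable")]
    sorted_codes = codes[order]
    uniq, starts = np.unique(sorted_codes, return_index=True)
    bounds = np.append(starts[1:], order.size)
    return {
        int(c): order[s:e] for c, s, e in zip(uniq, starts, bounds)
    }


def _identity_and_len(alignment) -> tuple[float, int]:
    """Percent identity and column count (incl. gaps) of a Bio.Align result."""
    qa, sa = alignment.aligned
    matches = 0
    block_cols = 0
    tseq, qseq = alignment.target, alignment.query
    for (ts, te), (qs, qe) in zip(qa, sa):
        t_block = np.frombuffer(tseq[ts:te].encode(), dtype=np.uint8)
        q_block = np.frombuffer(qseq[qs:qe].encode(), dtype=np.uint8)
        matches += int((t_block == q_block).sum())
        block_cols += te - ts
    # columns include internal gaps: span on each sequence minus shared blocks
    t_span = qa[-1][1] - qa[0][0]
    q_span = sa[-1][1] - sa[0][0]
    cols = block_cols + (t_span - block_cols) + (q_span - block_cols)
    return 100.0 * matches / cols if cols else 0.0, cols


def find_hits(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    scoring: ScoringScheme | None = None,
    seed_len: int = 12,
    min_raw_score: float = 100.0,
    max_evalue: float = 1e-5,
    xdrop: float = 100.0,
    gapped: bool = True,
    pad: int = 50,
    _skip_forward_self_diagonal: bool = False,
) -> list[HomologyHit]:
    """Scan genome A (query) against both strands of genome B (subject).

    Every exact shared substring of length >= ``seed_len`` seeds an ungapped
    X-drop extension; extended segments are optionally refined by gapped
    local alignment on a padded window.  Hits scoring below
    ``min_raw_score`` or above ``max_evalue`` are discarded; overlapping
    hits on identical diagonals collapse to the best-scoring.
    """
    if scoring is None:
        scoring = ScoringScheme()
    if seed_len < 8:
        raise ConfigurationError("seed_len must be >= 8")
    if not genome_a.sequence or not genome_b.sequence:
        raise ConfigurationError("genomes must be non-empty")

    a = encode(genome_a.sequence)
    m, n = len(a), len(genome_b.sequence)
    aligner = scoring.aligner() if gapped else None
    a_codes = _kmer_codes(a, seed_len)

    raw_hits: list[HomologyHit] = []
    for strand in ("+", "-"):
        b_str = genome_b.sequence if strand == "+" else revcomp(genome_b.sequence)
        b = encode(b_str)
        b_codes = _kmer_codes(b, seed_len)
        index = _code_index(b_codes)
        if not index:
            continue
        uniq = np.fromiter(index.keys(), dtype=np.int64)
        candidates = np.flatnonzero((a_codes >= 0) & np.isin(a_codes, uniq))
        covered: dict[int, int] = {}
        for i in candidates:
            i = int(i)
            for j in index[int(a_codes[i])]:
                j = int(j)
                d = i - j
                if _skip_forward_self_diagonal and strand == "+" and d == 0:
                    continue
                if covered.get(d, -1) >= i:
                    continue
                seed_score = seed_len * scoring.match
                r_off, r_sc = _extend_dir(
                    a, b, i + seed_len, j + seed_len, +1, scoring, xdrop
                )
                l_off, l_sc = _extend_dir(a, b, i - 1, j - 1, -1, scoring, xdrop)
                qs, qe = i - l_off, i + seed_len + r_off
                ss, se = j - l_off, j + seed_len + r_off
                covered[d] = qe
                score = seed_score + r_sc + l_sc
                seg_len = qe - qs
                ident = 100.0 * int((a[qs:qe] == b[ss:se]).sum()) / seg_len
                if gapped:
                    wq0, wq1 = max(0, qs - pad), min(m, qe + pad)
                    ws0, ws1 = max(0, ss - pad), min(n, se + pad)
                    aln = aligner.align(
                        a[wq0:wq1].tobytes().decode(),
                        b[ws0:ws1].tobytes().decode(),
                    )[0]
                    g_score = float(aln.score)
                    if g_score >= score:
                        score = g_score
                        qa_blocks, sa_blocks = aln.aligned
                        qs = wq0 + int(qa_blocks[0][0])
                        qe = wq0 + int(qa_blocks[-1][1])
                        ss = ws0 + int(sa_blocks[0][0])
                        se = ws0 + int(sa_blocks[-1][1])
                        ident, seg_len = _identity_and_len(aln)
                        covered[d] = max(covered[d], qe)
                e = evalue(score, m, n, scoring)
                if score < min_raw_score or e > max_evalue:
                    continue
                if strand == "-":
                    f_ss, f_se = n - se, n - ss
                else:
                    f_ss, f_se = ss, se
                raw_hits.append(
                    HomologyHit(
                        qs, qe, f_ss, f_se, strand,
                        score, bit_score(score, scoring), e, ident, seg_len,
                    )
                )

    # collapse overlapping hits on identical diagonals to the best-scoring
    best: dict[tuple, HomologyHit] = {}
    for h in raw_hits:
        d = h.query_start - (
            h.subject_start if h.strand == "+" else -h.subject_end
        )
        key = None
        for (kd, ks), other in best.items():
            if kd == (h.strand, d) and not (
                h.query_end <= other.query_start or other.query_end <= h.query_start
            ):
                key = (kd, ks)
                break
        if key is None:
            best[((h.strand, d), (h.query_start, h.query_end))] = h
        elif h.raw_score > best[key].raw_score:
            del best[key]
            best[((h.strand, d), (h.query_start, h.query_end))] = h
    hits = sorted(
        best.values(), key=lambda h: (h.query_start, h.query_end, h.subject_start)
    )
    # drop exact duplicates (two seeds converging on one refined alignment)
    seen: set[tuple] = set()
    out = []
    for h in hits:
        k = (h.query_start, h.query_end, h.subject_start, h.subject_end, h.strand)
        if k not in seen:
            seen.add(k)
            out.append(h)
    return out


def _reciprocal_overlap(i1: tuple[int, int], i2: tuple[int, int], frac: float) -> bool:
    ov = min(i1[1], i2[1]) - max(i1[0], i2[0])
    if ov <= 0:
        return False
    return ov >= frac * (i1[1] - i1[0]) and ov >= frac * (i2[1] - i2[0])


def dedupe_hits(hits: list[HomologyHit], overlap_frac: float = 0.5) -> list[RegionPair]:
    """Cluster hits whose query OR subject intervals reciprocally overlap.

    Clustering is the transitive closure of the pairwise relation; one
    :class:`RegionPair` with merged spans is emitted per cluster.
    """
    if not (0 < overlap_frac <= 1):
        raise ConfigurationError("overlap_frac must be in (0, 1]")
    n = len(hits)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _reciprocal_overlap(
                hits[i].query_interval, hits[j].query_interval, overlap_frac
            ) or _reciprocal_overlap(
                hits[i].subject_interval, hits[j].subject_interval, overlap_frac
            ):
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    pairs = []
    for members in clusters.values():
        qs = min(hits[i].query_start for i in members)
        qe = max(hits[i].query_end for i in members)
        ss = min(hits[i].subject_start for i in members)
        se = max(hits[i].subject_end for i in members)
        pairs.append(RegionPair((qs, qe), (ss, se), sorted(members)))
    pairs.sort(key=lambda p: p.query_region)
    return pairs


def classify_gene_content(
    pairs: list[RegionPair],
    annotation: GenomeRecord | list[Feature],
    kinds: tuple[str, ...] = ("gene",),
) -> pd.DataFrame:
    """Tabulate genes contained in (complete) or overlapping (fragment) the
    merged subject region of each pair.  Annotation is in subject coordinates.
    """
    features = annotation.features if isinstance(annotation, GenomeRecord) else annotation
    rows = []
    for ridx, pair in enumerate(pairs):
        rs, re_ = pair.subject_region
        for f in features:
            if kinds and f.kind not in kinds:
                continue
            ov = min(re_, f.end) - max(rs, f.start)
            if ov <= 0:
                continue
            complete = rs <= f.start and f.end <= re_
            status = "complete" if complete else "fragment"
            rows.append({"region": ridx, "gene": f.name, "completeness": status})
            pair.genes.append((f.name, status))
    return pd.DataFrame(rows, columns=["region", "gene", "completeness"])


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def self_repeats(
    genome: GenomeRecord,
    min_len: int = 100,
    min_identity: float = 90.0,
    scoring: ScoringScheme | None = None,
    seed_len: int = 12,
    min_raw_score: float = 100.0,
    max_evalue: float = 1e-5,
) -> list[tuple[int, int]]:
    """Mask of repeated regions: genome vs itself, trivial diagonal excluded.

    Returns the union of query and subject intervals of qualifying hits as a
    sorted, merged list of half-open intervals.
    """
    hits = find_hits(
        genome,
        genome,
        scoring=scoring,
        seed_len=seed_len,
        min_raw_score=min_raw_score,
        max_evalue=max_evalue,
        _skip_forward_self_diagonal=True,
    )
    intervals = []
    for h in hits:
        if h.aln_len >= min_len and h.pct_identity >= min_identity:
            intervals.append(h.query_interval)
            intervals.append(h.subject_interval)
    return merge_intervals(intervals)


def hits_table(hits: list[HomologyHit], low_identity_threshold: float = 80.0) -> pd.DataFrame:
    """Hits as a DataFrame, flagging low-identity matches for manual review."""
    rows = [
        {
            "query_start": h.query_start,
            "query_end": h.query_end,
            "subject_start": h.subject_start,
            "subject_end": h.subject_end,
            "strand": h.strand,
            "raw_score": h.raw_score,
            "bit_score": round(h.bit_score, 2),
            "evalue": h.evalue,
            "pct_identity": round(h.pct_identity, 2),
            "aln_len": h.aln_len,
            "low_identity": h.pct_identity < low_identity_threshold,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "query_start", "query_end", "subject_start", "subject_end",
            "strand", "raw_score", "bit_score", "evalue", "pct_identity",
            "aln_len", "low_identity",
        ],
    )


def mtpt_share(mask: list[tuple[int, int]], genome_len: int) -> float:
    """Percent of a genome covered by (merged) transfer regions."""
    if genome_len <= 0:
        raise ConfigurationError("genome_len must be positive")
    merged = merge_intervals(mask)
    return 100.0 * sum(e - s for s, e in merged) / genome_len


def genome_size_difference(size_a: int, size_b: int) -> float:
    """Percent by which genome A exceeds genome B: 100*(A-B)/B."""
    if size_b <= 0:
        raise ConfigurationError("reference size must be positive")
    return 100.0 * (size_a - size_b) / size_b
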