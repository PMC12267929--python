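"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: the Smith-Waterman
scorer is a direct Gotoh recurrence, the MDC oracle is a per-column set
scan, and the clustering oracle enumerates pairs.
"""

AMBIG = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def sw_score(a: str, b: str, match=2, mismatch=3, gap_open=5, gap_extend=2):
    """Optimal local alignment score, affine gaps costing open + L*extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    best = 0.0
    H_prev = [0.0] * (m + 1)
    F_prev = [NEG] * (m + 1)
    for i in range(1, n + 1):
        H_cur = [0.0] * (m + 1)
        F_cur = [NEG] * (m + 1)
        run = NEG  # max over k<j of H_cur[k] + gap_extend*k
        for j in range(1, m + 1):
            k = j - 1
            cand = H_cur[k] + gap_extend * k
            if cand > run:
                run = cand
            E = run - gap_open - gap_extend * j
            F_cur[j] = max(
                F_prev[j] - gap_extend,
                H_prev[j] - gap_open - gap_extend,
            )
            s = match if a[i - 1] == b[j - 1] else -mismatch
            H_cur[j] = max(0.0, H_prev[j - 1] + s, E, F_cur[j])
            if H_cur[j] > best:
                best = H_cur[j]
        H_prev, F_prev = H_cur, F_cur
    return best


def mdc_columns(rows_query, rows_ref, policy="conservative"):
    """0-based columns that are diagnostic for the query taxon."""
    L = len(rows_query[0])
    out = []
    for c in range(L):
        q_states = {r[c] for r in rows_query}
        if len(q_states) != 1:
            continue
        (qb,) = q_states
        if qb not in "ACGT":
            continue
        ok = True
        for r in rows_ref:
            ch = r[c]
            if policy == "conservative":
                if ch == "-" or qb in AMBIG.get(ch, set()):
                    ok = False
                    break
            else:  # strict_acgt
                if ch in "ACGT" and ch == qb:
                    ok = False
                    break
        if ok:
            out.append(c)
    return out


def cluster_pairs(intervals_q, intervals_s, frac):
    """Brute-force transitive-closure clustering of hits by reciprocal
    query-or-subject overlap; returns sorted member-index clusters."""
    n = len(intervals_q)

    def recip(i1, i2):
        ov = min(i1[1], i2[1]) - max(i1[0], i2[0])
        return ov > 0 and ov >= frac * (i1[1] - i1[0]) and ov >= frac * (i2[1] - i2[0])

    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if recip(intervals_q[i], intervals_q[j]) or recip(
                intervals_s[i], intervals_s[j]
            ):
                adj[i].add(j)
                adj[j].add(i)
    seen = set()
    clusters = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            stack.extend(adj[x] - seen)
        clusters.append(sorted(comp))
    return sorted(clusters)


def pi_by_columns(rows):
    """Mean per-column pairwise heterozygosity for gap-free alignments."""
    n = len(rows)
    L = len(rows[0])
    total = 0.0
    npairs = n * (n - 1) / 2
    for c in range(L):
        col = [r[c] for r in rows]
        diff = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if col[i] != col[j]
        )
        total += diff / npairs
    return total / L
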