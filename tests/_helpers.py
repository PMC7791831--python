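"""Independent oracle implementations shared by the test modules.

Everything here is deliberately naive (plain Python loops, exhaustive pair
counting, per-base coordinate tables) so it cannot share a code path with
the implementations it checks.
"""

import statistics

import pysam

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
)


def naive_base_features(segment):
    """Plain-Python mean / median / population std / dwell."""
    n = len(segment)
    mean = sum(segment) / n
    median = statistics.median(segment)
    std = (sum((x - mean) ** 2 for x in segment) / n) ** 0.5
    return mean, median, std, n


BRUTE_MOTIFS = {a + b + "AC" + c for a in "AG" for b in "AG" for c in "ACT"}


def brute_force_rrach(seq):
    """Scan every 5-window against the explicit 12-motif set."""
    seq = seq.upper().replace("U", "T")
    return [
        (i + 2, seq[i : i + 5])
        for i in range(len(seq) - 4)
        if seq[i : i + 5] in BRUTE_MOTIFS
    ]


def mann_whitney_auc(scores, labels):
    """Pair-counting oracle: P(s+ > s-) + P(s+ = s-)/2 over all pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_alignment(name, start0, cigar, reverse=False, qlen=None):
    aln = pysam.AlignedSegment(HEADER)
    aln.query_name = name
    aln.flag = 16 if reverse else 0
    aln.reference_id = 0
    aln.reference_start = start0
    aln.cigarstring = cigar
    if qlen is not None:
        aln.query_sequence = "A" * qlen
    aln.mapping_quality = 60
    return aln


def walk_cigar(start0, cigar_ops, reverse, qlen, tpos):
    """Exhaustive per-base coordinate table built from the CIGAR operations."""
    table = {}  # query pos -> 0-based reference pos
    q = r = 0
    for op, length in cigar_ops:
        if op in "M=X":
            for _ in range(length):
                table[q] = start0 + r
                q += 1
                r += 1
        elif op in "IS":
            q += length
        elif op in "DN":
            r += length
    qpos = qlen - 1 - tpos if reverse else tpos
    return table.get(qpos)


def random_cigar(rng):
    """A random alignment layout mixing M/I/D/N operations."""
    ops = [("M", int(rng.integers(1, 20)))]
    for _ in range(int(rng.integers(0, 4))):
        kind = str(rng.choice(["I", "D", "N", "M"]))
        ops.append((kind, int(rng.integers(1, 30))))
        ops.append(("M", int(rng.integers(1, 20))))
    qlen = sum(l for op, l in ops if op in "MI")
    cigar = "".join(f"{l}{op}" for op, l in ops)
    return ops, cigar, qlen


def connected_components_clusters(positions, window=24):
    """Oracle: components of the graph linking positions within the window."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= window:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(g) for g in groups.values())
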