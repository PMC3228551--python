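"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: candidate
enumeration is re-done as a naive scan over all index pairs, and alignment
scores are recomputed by explicit enumeration of alignment paths.
"""

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = -10
GAP_EXTEND = -2


def brute_force_enumerate(
    residues,
    region_start,
    region_end,
    acc_targets,
    don_targets,
    query_len,
    allowed_length_difference,
    min_new_intron_length,
    start_anchor="splice",
    end_anchor="splice",
):
    """Naive double scan over all index pairs applying the printed constraints."""
    starts = []
    if start_anchor == "splice":
        for p in range(region_start, region_end - 1):
            if residues[p : p + 2] in acc_targets:
                s = p + 2
                if s - region_start >= min_new_intron_length:
                    starts.append(s)
    else:  # atg
        for p in range(region_start, region_end - 2):
            if residues[p : p + 3] == "ATG":
                starts.append(p)
    ends = []
    if end_anchor == "splice":
        for p in range(region_start, region_end - 1):
            if residues[p : p + 2] in don_targets:
                if region_end - p >= min_new_intron_length:
                    ends.append(p)
    else:  # stop
        for p in range(region_start, region_end - 2):
            if residues[p : p + 3] in ("TAA", "TAG", "TGA"):
                ends.append(p)
    out = set()
    for s in starts:
        for e in ends:
            if e <= s:
                continue
            diff = (e - s) - query_len
            if diff % 3 != 0:
                continue
            if abs(diff) > 3 * allowed_length_difference:
                continue
            if e - s < 3:
                continue
            if "N" in residues[s:e]:
                continue
            out.add((s, e))
    return out


@lru_cache(maxsize=None)
def _paths(m, n):
    """All monotone alignment paths as move strings over M (match),
    A (gap in b, consumes a), B (gap in a, consumes b)."""
    if m == 0 and n == 0:
        return ("",)
    paths = []
    if m > 0 and n > 0:
        paths += ["M" + p for p in _paths(m - 1, n - 1)]
    if m > 0:
        paths += ["A" + p for p in _paths(m - 1, n)]
    if n > 0:
        paths += ["B" + p for p in _paths(m, n - 1)]
    return tuple(paths)


def path_score(path, a, b):
    """Score one alignment path under the affine gap-run cost model:
    a run of L gap positions costs GAP_OPEN + (L-1)*GAP_EXTEND."""
    i = j = 0
    score = 0
    prev = None
    for move in path:
        if move == "M":
            score += BLOSUM62[a[i], b[j]]
            i += 1
            j += 1
        else:
            score += GAP_EXTEND if prev == move else GAP_OPEN
            if move == "A":
                i += 1
            else:
                j += 1
        prev = move
    return int(score)


def exhaustive_align_score(a, b):
    """Optimal global score by explicit enumeration of every alignment."""
    return max(path_score(p, a, b) for p in _paths(len(a), len(b)))


def all_pairs_scores(alphabet, max_len):
    """Vectorized exhaustive oracle: optimal score for every sequence pair
    with lengths up to max_len over the alphabet.

    Returns a dict (seq_a, seq_b) -> score, computed by enumerating all
    alignment paths per length pair and taking the max over paths, with the
    substitution sums evaluated with numpy across all pairs at once.
    """
    import itertools

    idx = {c: i for i, c in enumerate(alphabet)}
    sub = np.array(
        [[BLOSUM62[x, y] for y in alphabet] for x in alphabet], dtype=np.int64
    )
    seqs_by_len = {
        L: ["".join(t) for t in itertools.product(alphabet, repeat=L)]
        for L in range(max_len + 1)
    }
    result = {}
    for m in range(max_len + 1):
        for n in range(max_len + 1):
            seqs_a = seqs_by_len[m]
            seqs_b = seqs_by_len[n]
            a_idx = np.array(
                [[idx[c] for c in s] for s in seqs_a], dtype=np.intp
            ).reshape(len(seqs_a), m)
            b_idx = np.array(
                [[idx[c] for c in s] for s in seqs_b], dtype=np.intp
            ).reshape(len(seqs_b), n)
            na, nb = len(seqs_a), len(seqs_b)
            best = np.full((na, nb), -(10 ** 9), dtype=np.int64)
            for path in _paths(m, n):
                gap_cost = 0
                prev = None
                pairs = []
                i = j = 0
                for move in path:
                    if move == "M":
                        pairs.append((i, j))
                        i += 1
                        j += 1
                    else:
                        gap_cost += GAP_EXTEND if prev == move else GAP_OPEN
                        if move == "A":
                            i += 1
                        else:
                            j += 1
                    prev = move
                total = np.full((na, nb), gap_cost, dtype=np.int64)
                for (pi, pj) in pairs:
                    total += sub[a_idx[:, pi][:, None], b_idx[:, pj][None, :]]
                np.maximum(best, total, out=best)
            for ia, sa in enumerate(seqs_a):
                for ib, sb in enumerate(seqs_b):
                    result[(sa, sb)] = int(best[ia, ib])
    return result
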