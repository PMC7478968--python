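"""Independent brute-force oracles used only by the test suite."""

from functools import lru_cache
from itertools import product


def brute_force_alignment_score(
    a: str,
    b: str,
    match: float = 2,
    mismatch: float = -3,
    gap_open: float = -6,
    gap_extend: float = -1,
) -> float:
    """Best global alignment score by exhaustive recursion over all
    alignment paths (first gap base scores gap_open, later bases
    gap_extend; end gaps penalized).  Independent of the production
    aligner."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):
            g = gap_extend if prev == "D" else gap_open
            best = max(best, g + rec(i + 1, j, "D"))
        if j < len(b):
            g = gap_extend if prev == "I" else gap_open
            best = max(best, g + rec(i, j + 1, "I"))
        return best

    return rec(0, 0, "")


def multinomial_deficit_tail(k: int, x: int, f_exp: float) -> float:
    """P(frameshift count <= x) by enumerating all 3^k assignments of k
    events to the classes (3n, 3n+1, 3n+2) with probabilities
    (1 - f_exp, f_exp/2, f_exp/2)."""
    total = 0.0
    for combo in product((0, 1, 2), repeat=k):
        p = 1.0
        n_fs = 0
        for c in combo:
            p *= (1.0 - f_exp) if c == 0 else f_exp / 2.0
            n_fs += c != 0
        if n_fs <= x:
            total += p
    return total


def enumerate_left_shifts(ref: str, position: int, deleted: str) -> int:
    """5'-most equivalent placement of a deletion by brute force: try
    every start and keep those yielding the same edited sequence."""
    L = len(deleted)
    target = ref[:position] + ref[position + L :]
    best = position
    for p in range(position + 1):
        if ref[:p] + ref[p + L :] == target:
            best = p
            break
    return best
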