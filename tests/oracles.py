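"""Independent brute-force oracles used by the tests.

Deliberately naive implementations, written against the definitions rather
than the library code paths they check.
"""

from __future__ import annotations

import itertools

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def maximal_g_runs(residues: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal all-G runs found by a direct position walk (no regex)."""
    runs = []
    i = 0
    n = len(residues)
    while i < n:
        if residues[i] == "G":
            j = i
            while j < n and residues[j] == "G":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def brute_force_g4(
    residues: str,
    min_tract: int = 2,
    loop_bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = ((1, 7), (1, 7), (1, 7)),
) -> list[tuple[tuple[int, int], ...]]:
    """Every placement of four maximal G-tracts whose three inter-tract gaps
    fall inside the per-loop bounds; returns sorted tract-span 4-tuples."""
    runs = maximal_g_runs(residues, min_tract)
    out = []
    for combo in itertools.combinations(runs, 4):
        ok = True
        for k in range(3):
            gap = combo[k + 1][0] - combo[k][1]
            lo, hi = loop_bounds[k]
            if not (lo <= gap <= hi):
                ok = False
                break
        if ok:
            out.append(combo)
    return sorted(out)


def brute_force_homodimer_alignments(oligo: str, min_seed: int = 4):
    """All (i, j) pairings of two antiparallel copies, grouped by alignment
    constant c = i + j, as lists of contiguous complementary runs."""
    n = len(oligo)
    for c in range(2 * n - 1):
        run = []
        runs = []
        for i in range(max(0, c - n + 1), min(n, c + 1)):
            j = c - i
            if (oligo[i], oligo[j]) in _WC:
                run.append(i)
            else:
                if len(run) >= min_seed:
                    runs.append(list(run))
                run = []
        if len(run) >= min_seed:
            runs.append(list(run))
        if runs:
            yield c, runs
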