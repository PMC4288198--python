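"""Nearest-neighbor thermodynamics for ASO:target duplexes.

Free energies are ΔG°37 in kcal/mol built from the Watson-Crick RNA/RNA
stacking parameters of the standard unified nearest-neighbor set (shipped as
``data/rna_nn_stacks.tsv``; keys are the 5'->3' dinucleotide of the top
strand) plus a duplex-initiation term. 2'-O-methyl positions reuse unmodified
RNA parameters; LNA positions receive a uniform stabilization increment per
paired position. Internal mismatches carry a flat penalty and interrupt
stacking; terminal mismatches are free. These simplifications give correct
*orderings* (longer duplex more stable, LNA more stable than 2'-O-Me, any
mismatch destabilizing), which is all the oligo screen relies on; absolute
values are implementation-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .sequences import complement

DUPLEX_INIT = 4.09  # kcal/mol, duplex initiation
MISMATCH_PENALTY = 1.0  # kcal/mol per internal mismatch
LNA_INCREMENT = -1.0  # kcal/mol per Watson-Crick-paired LNA position
HAIRPIN_LOOP_PENALTY = 5.0  # kcal/mol, flat hairpin-loop closure cost

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def _load_stacks() -> dict[str, float]:
    table = {}
    text = resources.files("g4switch.data").joinpath("rna_nn_stacks.tsv").read_text()
    for line in text.strip().splitlines()[1:]:
        key, val = line.split("\t")
        table[key] = float(val)
    return table


STACKS = _load_stacks()


def is_watson_crick(a: str, b: str) -> bool:
    return (a, b) in _WC


@dataclass(frozen=True)
class DuplexResult:
    """ΔG°37 of an antiparallel duplex plus its per-position pairing map."""

    delta_g37: float
    pair_map: tuple[bool, ...]  # True where Watson-Crick paired (probe 5'->3')
    n_mismatches: int


def _probe_flags(probe) -> tuple[str, Sequence[str]]:
    """Accept a plain string or an AsoDesign-like object with .oligo/.chemistry."""
    oligo = getattr(probe, "oligo", probe)
    chem = getattr(probe, "chemistry", None)
    flags = chem.per_position_flags if chem is not None else ["OMe"] * len(oligo)
    return oligo, flags


def duplex_delta_g(
    probe,
    target: str,
    mismatch_penalty: float = MISMATCH_PENALTY,
    lna_increment: float = LNA_INCREMENT,
) -> DuplexResult:
    """ΔG°37 of probe (5'->3') bound antiparallel to a target segment (5'->3').

    Position i of the probe faces position L-1-i of the target. Stacking is
    summed over steps where both faced pairs are Watson-Crick; each internal
    mismatch adds ``mismatch_penalty``; each paired LNA position adds
    ``lna_increment``.
    """
    oligo, flags = _probe_flags(probe)
    oligo = oligo.replace("T", "U").upper()
    target = target.replace("T", "U").upper()
    n = len(oligo)
    if n != len(target):
        raise ValueError(
            f"probe length {n} != target segment length {len(target)}"
        )
    paired = tuple(
        is_watson_crick(oligo[i], target[n - 1 - i]) for i in range(n)
    )
    dg = DUPLEX_INIT
    for i in range(n - 1):
        if paired[i] and paired[i + 1]:
            dg += STACKS[oligo[i : i + 2]]
    n_mm = 0
    for i in range(n):
        if not paired[i]:
            n_mm += 1
            if 0 < i < n - 1:  # terminal mismatches are free
                dg += mismatch_penalty
        elif flags[i] == "LNA":
            dg += lna_increment
    return DuplexResult(round(dg, 6), paired, n_mm)


def self_structure_delta_g(
    probe,
    min_helix: int = 3,
    min_loop: int = 3,
) -> float:
    """Best (most negative) intramolecular hairpin ΔG, 0 if none possible.

    Exhaustive enumeration of contiguous Watson-Crick helices of >= min_helix
    base pairs closing a loop of >= min_loop nt; helix ΔG is the stack sum
    plus a flat hairpin-loop closure penalty.
    """
    oligo, _ = _probe_flags(probe)
    n = len(oligo)
    best = 0.0
    for i in range(n):
        for j in range(i + 2 * min_helix + min_loop - 1, n):
            # extend a helix inward from the (i, j) closing pair
            h = 0
            while (
                i + h < j - h
                and (j - h) - (i + h) - 1 >= min_loop
                and is_watson_crick(oligo[i + h], oligo[j - h])
            ):
                h += 1
            if h >= min_helix:
                dg = HAIRPIN_LOOP_PENALTY
                for t in range(h - 1):
                    dg += STACKS[oligo[i + t : i + t + 2]]
                best = min(best, dg)
    return round(best, 6)


def homodimer_delta_g(probe, min_seed: int = 4) -> float:
    """Best ΔG over all antiparallel self-alignments, 0 if no alignment has a
    complementary run of >= min_seed contiguous positions.

    For each alignment (position i of one copy facing position c - i of the
    other), every contiguous complementary run of length >= min_seed scores
    initiation + stack sum (+ LNA increments for paired modified positions of
    both strands); the minimum over runs and alignments is returned.
    """
    oligo, flags = _probe_flags(probe)
    n = len(oligo)
    best = 0.0
    for c in range(n):  # c = i + j; c >= min_seed-1 needed, scan all
        lo, hi = max(0, c - n + 1), min(n - 1, c)
        run: list[int] = []
        for i in range(lo, hi + 1):
            if is_watson_crick(oligo[i], oligo[c - i]):
                run.append(i)
            else:
                best = min(best, _run_dg(oligo, flags, run, c, min_seed))
                run = []
        best = min(best, _run_dg(oligo, flags, run, c, min_seed))
    # alignments with c > n-1 mirror c' = 2(n-1) - c by symmetry of self-dimers
    for c in range(n, 2 * n - 1):
        lo, hi = c - n + 1, n - 1
        run = []
        for i in range(lo, hi + 1):
            if is_watson_crick(oligo[i], oligo[c - i]):
                run.append(i)
            else:
                best = min(best, _run_dg(oligo, flags, run, c, min_seed))
                run = []
        best = min(best, _run_dg(oligo, flags, run, c, min_seed))
    return round(best, 6)


def _run_dg(oligo: str, flags: Sequence[str], run: list[int], c: int, min_seed: int) -> float:
    if len(run) < min_seed:
        return 0.0
    dg = DUPLEX_INIT
    for i in run[:-1]:
        dg += STACKS[oligo[i : i + 2]]
    for i in run:
        if flags[i] == "LNA":
            dg += LNA_INCREMENT
        if flags[c - i] == "LNA":
            dg += LNA_INCREMENT
    return dg
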