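"""Watson-Crick stems around a G4 motif.

A G4 motif lives inside a larger RNA whose canonical secondary structure can
sequester tract guanines in stems and so compete with quadruplex folding.
The pro-G4 design strategy targets the partner strand of such a stem. The
builtin finder is a helix enumerator (contiguous complementary runs, G·U
wobble allowed), not a minimum-free-energy folder; dot-bracket output from a
real predictor can be loaded instead via :func:`load_dotbracket`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .duplex_thermo import STACKS, is_watson_crick
from .g4scan import G4Motif, Span
from .sequences import NucleotideSequence

_WOBBLE = {("G", "U"), ("U", "G")}
WOBBLE_STACK_DG = -0.5  # rough per-stack value for wobble-containing steps


def pairs(a: str, b: str, wobble: bool = True) -> bool:
    return is_watson_crick(a, b) or (wobble and (a, b) in _WOBBLE)


@dataclass(frozen=True)
class Stem:
    """One helix: arm5 pairs antiparallel with arm3, contiguous over `length` bp."""

    arm5: Span
    arm3: Span
    length: int
    delta_g: float

    def __post_init__(self):
        if self.arm5[1] - self.arm5[0] != self.length or self.arm3[1] - self.arm3[0] != self.length:
            raise ValueError("arm spans must match paired length")
        if self.arm5[1] > self.arm3[0]:
            raise ValueError("arms must be disjoint with arm5 upstream")

    def base_pairs(self) -> list[tuple[int, int]]:
        s5, _ = self.arm5
        _, e3 = self.arm3
        return [(s5 + t, e3 - 1 - t) for t in range(self.length)]

    def positions(self) -> set[int]:
        return set(range(*self.arm5)) | set(range(*self.arm3))


@dataclass(frozen=True)
class StemReport:
    seq_id: str
    stems: tuple[Stem, ...]
    source: str = "builtin"  # builtin | external_dotbracket

    def paired_positions(self) -> set[int]:
        out: set[int] = set()
        for s in self.stems:
            out |= s.positions()
        return out


def _helix_dg(residues: str, bp: list[tuple[int, int]]) -> float:
    """Stack-sum estimate; wobble-containing steps get a flat value."""
    dg = 0.0
    for t in range(len(bp) - 1):
        (i1, j1), (i2, j2) = bp[t], bp[t + 1]
        wc = is_watson_crick(residues[i1], residues[j1]) and is_watson_crick(
            residues[i2], residues[j2]
        )
        dg += STACKS[residues[i1] + residues[i2]] if wc else WOBBLE_STACK_DG
    return round(dg, 6)


def _crossing(a: Stem, b: Stem) -> bool:
    for (p1, q1) in a.base_pairs():
        for (p2, q2) in b.base_pairs():
            if p1 < p2 < q1 < q2 or p2 < p1 < q2 < q1:
                return True
    return False


def find_stems(
    seq: NucleotideSequence,
    window: Span | None = None,
    min_helix: int = 3,
    max_internal_loop: int = 3,
    wobble: bool = True,
) -> StemReport:
    """Enumerate maximal helices in `window` and greedily retain a mutually
    compatible (non-overlapping, pseudoknot-free) set by descending length.

    `max_internal_loop` is accepted for signature compatibility with external
    predictors but the builtin enumerator reports contiguous helices only.
    """
    if min_helix < 3:
        raise ValueError("min_helix must be >= 3")
    lo, hi = window if window is not None else (0, len(seq))
    if not (0 <= lo <= hi <= len(seq)):
        raise ValueError(f"window [{lo}, {hi}) outside sequence of length {len(seq)}")
    res = seq.residues
    if hi - lo < 2 * min_helix + 3:
        return StemReport(seq.id, ())

    helices: list[Stem] = []
    for i in range(lo, hi):
        for j in range(hi - 1, i, -1):
            if not pairs(res[i], res[j], wobble):
                continue
            # outermost pair only: skip if extendable outward within window
            if i - 1 >= lo and j + 1 < hi and pairs(res[i - 1], res[j + 1], wobble):
                continue
            h = 0
            while i + h < j - h and (j - h) - (i + h) - 1 >= 3 and pairs(
                res[i + h], res[j - h], wobble
            ):
                h += 1
            if h >= min_helix:
                bp = [(i + t, j - t) for t in range(h)]
                helices.append(
                    Stem((i, i + h), (j - h + 1, j + 1), h, _helix_dg(res, bp))
                )
    # deduplicate (same helix can be reached from several (i, j) seeds)
    helices = list({(s.arm5, s.arm3): s for s in helices}.values())
    helices.sort(key=lambda s: (-s.length, s.arm5[0], s.arm3[0]))
    kept: list[Stem] = []
    for s in helices:
        if any(s.positions() & k.positions() for k in kept):
            continue
        if any(_crossing(s, k) for k in kept):
            continue
        kept.append(s)
    kept.sort(key=lambda s: (s.arm5[0], s.arm3[0]))
    return StemReport(seq.id, tuple(kept))


def load_dotbracket(seq: NucleotideSequence, structure: str) -> StemReport:
    """Convert a dot-bracket string (the interchange format of secondary
    structure predictors) into a StemReport. Helices are maximal runs of
    stacked adjacent pairs."""
    if len(structure) != len(seq):
        raise ValueError(
            f"structure length {len(structure)} != sequence length {len(seq)}"
        )
    stack: list[int] = []
    partner: dict[int, int] = {}
    for k, ch in enumerate(structure):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {k}")
            i = stack.pop()
            partner[i] = k
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r} at position {k}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")

    opens = sorted(partner)
    stems: list[Stem] = []
    run: list[tuple[int, int]] = []
    for i in opens:
        j = partner[i]
        if run and (i == run[-1][0] + 1 and j == run[-1][1] - 1):
            run.append((i, j))
        else:
            if run:
                stems.append(_stem_from_run(seq.residues, run))
            run = [(i, j)]
    if run:
        stems.append(_stem_from_run(seq.residues, run))
    stems.sort(key=lambda s: (s.arm5[0], s.arm3[0]))
    return StemReport(seq.id, tuple(stems), source="external_dotbracket")


def _stem_from_run(residues: str, run: list[tuple[int, int]]) -> Stem:
    i0, j0 = run[0]
    h = len(run)
    return Stem((i0, i0 + h), (j0 - h + 1, j0 + 1), h, _helix_dg(residues, run))


def tract_sequestration(motif: G4Motif, report: StemReport) -> tuple[int, int, int, int]:
    """Per-tract count of tract-guanine positions engaged in any stem arm."""
    if motif.seq_id != report.seq_id:
        raise ValueError(
            f"motif on {motif.seq_id!r} but stems on {report.seq_id!r}"
        )
    paired = report.paired_positions()
    return tuple(
        sum(1 for p in range(s, e) if p in paired) for s, e in motif.tract_spans
    )  # type: ignore[return-value]


def stems_to_tsv(report: StemReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tarm5_start\tarm5_end\tarm3_start\tarm3_end\tlength\tdelta_g\tsource\n")
        for s in report.stems:
            fh.write(
                f"{report.seq_id}\t{s.arm5[0] + 1}\t{s.arm5[1]}\t{s.arm3[0] + 1}"
                f"\t{s.arm3[1]}\t{s.length}\t{s.delta_g}\t{report.source}\n"
            )
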