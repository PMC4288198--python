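"""G-quadruplex motif scanning.

Two motif classes are recognized on the sense (mRNA) strand only:

* ``canonical`` — four G-tracts of >= 2 guanines interspaced by three loops of
  1-7 nt, the textbook intramolecular G4 signature.
* ``long_central_loop`` — the extended-loop-2 class: short flanking loops
  (<= 7 nt) around a central loop of 8-30 nt. Such motifs still fold in K+ and
  provide enough single-stranded loop for an antisense oligo to land on.

G-tracts are taken as *maximal* runs of G. A candidate motif is any ordered
choice of four such runs; the loops are exactly the gaps between consecutive
chosen runs (gaps may themselves contain shorter or skipped G-runs). All
placements satisfying the class constraints are reported; use
:func:`select_nonoverlapping` to reduce to a disjoint subset.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .sequences import NucleotideSequence

Span = tuple[int, int]

CANONICAL = "canonical"
LONG_CENTRAL_LOOP = "long_central_loop"


@dataclass(frozen=True)
class ScanParams:
    """Scanner thresholds; defaults encode the standard G4 definition plus the
    long-central-loop extension (central loop up to 30 nt)."""

    min_tract_g: int = 2
    canonical_loop_min: int = 1
    canonical_loop_max: int = 7
    long_central_min: int = 8
    long_central_max: int = 30
    long_flank_loop_max: int = 7

    def __post_init__(self):
        if self.min_tract_g < 2:
            raise ValueError("min_tract_g must be >= 2")
        if not (1 <= self.canonical_loop_min <= self.canonical_loop_max):
            raise ValueError("need 1 <= canonical_loop_min <= canonical_loop_max")
        if self.long_central_min <= self.canonical_loop_max:
            raise ValueError("long_central_min must exceed canonical_loop_max")
        if self.long_central_max < self.long_central_min:
            raise ValueError("long_central_max must be >= long_central_min")


@dataclass(frozen=True)
class G4Motif:
    """Anatomy of one G4 placement: four tract spans, three loop spans, class.

    All coordinates are 0-based half-open on the parent sequence.
    """

    seq_id: str
    tract_spans: tuple[Span, Span, Span, Span]
    loop_spans: tuple[Span, Span, Span]
    motif_class: str

    def __post_init__(self):
        for (s, e) in self.tract_spans:
            if e <= s:
                raise ValueError("empty tract span")
        for i in range(3):
            if self.tract_spans[i][1] != self.loop_spans[i][0] or (
                self.loop_spans[i][1] != self.tract_spans[i + 1][0]
            ):
                raise ValueError("loops must be exactly the gaps between tracts")

    @property
    def span(self) -> Span:
        return (self.tract_spans[0][0], self.tract_spans[3][1])

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    @property
    def loop_lengths(self) -> tuple[int, int, int]:
        return tuple(e - s for s, e in self.loop_spans)  # type: ignore[return-value]

    @property
    def tract_lengths(self) -> tuple[int, int, int, int]:
        return tuple(e - s for s, e in self.tract_spans)  # type: ignore[return-value]

    @property
    def total_tract_g(self) -> int:
        return sum(self.tract_lengths)

    def tract_positions(self) -> set[int]:
        """All guanine positions belonging to the four tracts."""
        return {p for s, e in self.tract_spans for p in range(s, e)}

    def loop_positions(self) -> set[int]:
        return {p for s, e in self.loop_spans for p in range(s, e)}

    def positions(self) -> set[int]:
        return set(range(self.start, self.end))

    def overlaps(self, other: "G4Motif") -> bool:
        return self.seq_id == other.seq_id and not (
            self.end <= other.start or other.end <= self.start
        )


def _g_runs(residues: str, min_len: int) -> list[Span]:
    """Maximal runs of G with length >= min_len, left to right."""
    return [
        (m.start(), m.end())
        for m in re.finditer(r"G+", residues)
        if m.end() - m.start() >= min_len
    ]


def _placements(seq: NucleotideSequence, params: ScanParams) -> Iterable[tuple[tuple[Span, ...], tuple[int, int, int]]]:
    runs = _g_runs(seq.residues, params.min_tract_g)
    for combo in itertools.combinations(runs, 4):
        gaps = tuple(combo[i + 1][0] - combo[i][1] for i in range(3))
        yield combo, gaps  # type: ignore[misc]


def _motif(seq_id: str, tracts: Sequence[Span], cls: str) -> G4Motif:
    loops = tuple((tracts[i][1], tracts[i + 1][0]) for i in range(3))
    return G4Motif(seq_id, tuple(tracts), loops, cls)  # type: ignore[arg-type]


def scan_canonical(seq: NucleotideSequence, params: ScanParams | None = None) -> list[G4Motif]:
    """All placements of four maximal G-tracts with every loop in the
    canonical 1-7 nt range (or the configured bounds). Overlapping placements
    are all reported, sorted by start coordinate."""
    params = params or ScanParams()
    out = []
    for tracts, gaps in _placements(seq, params):
        if all(params.canonical_loop_min <= g <= params.canonical_loop_max for g in gaps):
            out.append(_motif(seq.id, tracts, CANONICAL))
    out.sort(key=lambda m: (m.start, m.end))
    return out


def scan_long_loop(seq: NucleotideSequence, params: ScanParams | None = None) -> list[G4Motif]:
    """Placements with short flanking loops (loops 1 and 3 <= long_flank_loop_max)
    and a single long central loop in [long_central_min, long_central_max].

    Disjoint from :func:`scan_canonical` by construction, since
    long_central_min > canonical_loop_max.
    """
    params = params or ScanParams()
    out = []
    for tracts, gaps in _placements(seq, params):
        l1, l2, l3 = gaps
        if (
            params.canonical_loop_min <= l1 <= params.long_flank_loop_max
            and params.canonical_loop_min <= l3 <= params.long_flank_loop_max
            and params.long_central_min <= l2 <= params.long_central_max
        ):
            out.append(_motif(seq.id, tracts, LONG_CENTRAL_LOOP))
    out.sort(key=lambda m: (m.start, m.end))
    return out


def scan_all(seq: NucleotideSequence, params: ScanParams | None = None) -> list[G4Motif]:
    """Union of both motif classes, sorted by start."""
    motifs = scan_canonical(seq, params) + scan_long_loop(seq, params)
    motifs.sort(key=lambda m: (m.start, m.end))
    return motifs


def select_nonoverlapping(motifs: Sequence[G4Motif]) -> list[G4Motif]:
    """Greedy mutually non-overlapping subset: longer total G-tract content
    wins, ties broken by leftmost start. Deterministic."""
    if not motifs:
        return []
    ids = {m.seq_id for m in motifs}
    if len(ids) != 1:
        raise ValueError(f"motifs span multiple sequences: {sorted(ids)}")
    ranked = sorted(motifs, key=lambda m: (-m.total_tract_g, m.start, m.end))
    kept: list[G4Motif] = []
    for m in ranked:
        if not any(m.overlaps(k) for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: (m.start, m.end))
    return kept


# ---------------------------------------------------------------------------
# Reporting


def motifs_to_bed(motifs: Iterable[G4Motif], path: str | Path) -> None:
    """BED6; score = total tract G count x 100 capped at 1000, strand '+'. """
    with open(path, "w") as fh:
        for i, m in enumerate(motifs):
            score = min(m.total_tract_g * 100, 1000)
            fh.write(
                f"{m.seq_id}\t{m.start}\t{m.end}\t{m.motif_class}\t{score}\t+\n"
            )


def motifs_to_tsv(motifs: Iterable[G4Motif], path: str | Path) -> None:
    """Human-readable TSV with 1-based inclusive spans."""
    cols = [
        "seq_id", "class", "start", "end",
        "tract1", "tract2", "tract3", "tract4",
        "loop1_len", "loop2_len", "loop3_len",
    ]

    def fmt(span: Span) -> str:
        return f"{span[0] + 1}-{span[1]}"

    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for m in motifs:
            l1, l2, l3 = m.loop_lengths
            fields = [
                m.seq_id, m.motif_class, str(m.start + 1), str(m.end),
                *(fmt(t) for t in m.tract_spans), str(l1), str(l2), str(l3),
            ]
            fh.write("\t".join(fields) + "\n")
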