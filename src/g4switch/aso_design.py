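"""Antisense-oligonucleotide design against (or for) G4 motifs.

Four roles are produced:

* ``anti`` — reverse complement of a window spanning the central loop (loop 2)
  plus ``anchor_n`` loop-proximal guanines of each adjacent tract. Binding
  sequesters those guanines from quartet formation; oligo length is
  |loop2| + 2*anchor_n.
* ``mismatch_control`` — the anti oligo with k substitutions confined to the
  positions that pair with loop 2, used to establish sequence specificity.
* ``pro`` — reverse complement of the partner strand of a Watson-Crick stem
  that sequesters tract guanines; binding releases the tracts so the G4 can
  fold.
* ``random_control`` — composition-shuffled oligo with bounded
  complementarity to the target.

A G/A-mutant *target* (guanine-to-adenine substitutions abolishing G4
competence while preserving length) is also generated here, as it is the
standard negative-control construct of the reporter assay.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from . import duplex_thermo
from .g4scan import G4Motif, Span, scan_canonical, scan_long_loop
from .sequences import NucleotideSequence, reverse_complement
from .structure_context import StemReport, tract_sequestration

ROLE_ANTI = "anti"
ROLE_PRO = "pro"
ROLE_MISMATCH = "mismatch_control"
ROLE_RANDOM = "random_control"

# complementary base -> Watson-Crick-incompatible transversion partner
_MISMATCH_SUB = {"A": "C", "C": "A", "G": "U", "U": "G"}


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class Chemistry:
    """Sugar/backbone annotation of an oligo.

    ``two_prime_ome``: all-2'-O-methyl ribose on a phosphodiester backbone.
    ``lna_dna_ps``: LNA/DNA hybrid on a full phosphorothioate backbone; the
    default pattern alternates LNA with DNA from the 5' end until the stated
    LNA count is placed (the clinically used patterns vary; this one is
    configurable per position).
    """

    scheme: str
    per_position_flags: tuple[str, ...]
    backbone: str

    def __post_init__(self):
        if self.scheme not in ("two_prime_ome", "lna_dna_ps"):
            raise ValueError(f"unknown chemistry scheme {self.scheme!r}")
        if any(f not in ("OMe", "LNA", "DNA") for f in self.per_position_flags):
            raise ValueError("per-position flags must be OMe/LNA/DNA")
        if self.scheme == "lna_dna_ps":
            if self.backbone != "phosphorothioate":
                raise ValueError("lna_dna_ps requires a phosphorothioate backbone")
            if self.n_lna == 0:
                raise ValueError("lna_dna_ps requires at least one LNA position")

    @property
    def n_lna(self) -> int:
        return sum(1 for f in self.per_position_flags if f == "LNA")

    @classmethod
    def two_prime_ome(cls, length: int) -> "Chemistry":
        return cls("two_prime_ome", ("OMe",) * length, "phosphodiester")

    @classmethod
    def lna_dna_ps(cls, length: int, n_lna: int = 8) -> "Chemistry":
        """Alternating LNA/DNA pattern from the 5' end totaling `n_lna` LNA
        residues (8 on a 19-mer by default), full phosphorothioate."""
        n_lna = min(n_lna, (length + 1) // 2)
        flags = ["DNA"] * length
        placed = 0
        for i in range(0, length, 2):
            if placed == n_lna:
                break
            flags[i] = "LNA"
            placed += 1
        return cls("lna_dna_ps", tuple(flags), "phosphorothioate")


@dataclass(frozen=True)
class AsoDesign:
    """An oligo (5'->3') with its role, target span and chemistry."""

    oligo: str
    role: str
    target_span: Span
    seq_id: str
    anchor_n: Optional[int] = None
    mismatch_positions: tuple[int, ...] = ()
    chemistry: Optional[Chemistry] = None

    def __post_init__(self):
        if len(self.oligo) != self.target_span[1] - self.target_span[0]:
            raise ValueError("oligo length must equal target span length")
        if self.chemistry is not None and len(self.chemistry.per_position_flags) != len(
            self.oligo
        ):
            raise ValueError("chemistry flags length must equal oligo length")

    def __len__(self) -> int:
        return len(self.oligo)

    def target_positions(self) -> set[int]:
        return set(range(*self.target_span))


def design_anti_g4(
    seq: NucleotideSequence,
    motif: G4Motif,
    anchor_n: int = 3,
    chemistry: Chemistry | None = None,
) -> AsoDesign:
    """Anti-G4 oligo: reverse complement of loop 2 plus `anchor_n`
    loop-proximal guanines of tracts 2 and 3 (equal counts on both sides).

    anchor_n=0 covers the central loop and no tract guanines (the 13-mer of a
    13-nt loop); anchor_n=1/2/3 give the 15/17/19-mer series.
    """
    if anchor_n < 0:
        raise DesignError("anchor_n must be >= 0")
    t2, t3 = motif.tract_spans[1], motif.tract_spans[2]
    if t2[1] - t2[0] < anchor_n:
        raise DesignError(
            f"tract 2 has {t2[1] - t2[0]} guanines, fewer than anchor_n={anchor_n}"
        )
    if t3[1] - t3[0] < anchor_n:
        raise DesignError(
            f"tract 3 has {t3[1] - t3[0]} guanines, fewer than anchor_n={anchor_n}"
        )
    span = (t2[1] - anchor_n, t3[0] + anchor_n)
    oligo = reverse_complement(seq.segment(*span))
    chem = chemistry or Chemistry.two_prime_ome(len(oligo))
    return AsoDesign(oligo, ROLE_ANTI, span, seq.id, anchor_n=anchor_n, chemistry=chem)


def _loop2_window(aso: AsoDesign, motif: G4Motif) -> list[int]:
    """Oligo indices whose faced target position lies in loop 2."""
    s, e = aso.target_span
    l2s, l2e = motif.loop_spans[1]
    return [i for i in range(len(aso.oligo)) if l2s <= e - 1 - i < l2e]


def _spread_indices(window: Sequence[int], k: int) -> list[int]:
    """k indices of `window` spread to maximize minimum pairwise distance
    (even spacing over the sorted window); deterministic."""
    w = sorted(window)
    if k == 1:
        return [w[len(w) // 2]]
    picks = np.unique(np.round(np.linspace(0, len(w) - 1, k)).astype(int))
    i = 0
    while len(picks) < k:  # fill rounding collisions with unused slots
        if i not in picks:
            picks = np.sort(np.append(picks, i))
        i += 1
    return [w[i] for i in picks]


def design_mismatch_control(
    aso: AsoDesign,
    motif: G4Motif,
    k: int = 3,
    seed: int = 0,
) -> AsoDesign:
    """Mismatch control: k substitutions within the loop-2-pairing window of
    an anti design, each a transversion that cannot pair the original target
    base (A<->C, G<->U). Hamming distance to the parent is exactly k."""
    if aso.role != ROLE_ANTI:
        raise DesignError("mismatch controls derive from anti designs only")
    window = _loop2_window(aso, motif)
    if k > len(window):
        raise DesignError(
            f"k={k} exceeds the {len(window)} oligo positions pairing with loop 2"
        )
    if k == 0:
        return replace(aso, role=ROLE_MISMATCH)
    positions = tuple(sorted(_spread_indices(window, k)))
    oligo = list(aso.oligo)
    for i in positions:
        oligo[i] = _MISMATCH_SUB[oligo[i]]
    return replace(
        aso, oligo="".join(oligo), role=ROLE_MISMATCH, mismatch_positions=positions
    )


def alternative_target(seq: NucleotideSequence, control: AsoDesign) -> NucleotideSequence:
    """Compensatory target: mutate the sequence so the mismatch control pairs
    perfectly again (the specificity-rescue construct)."""
    s, e = control.target_span
    residues = list(seq.residues)
    for i in control.mismatch_positions:
        p = e - 1 - i
        residues[p] = reverse_complement(control.oligo[i])
    return NucleotideSequence(f"{seq.id}|alt", "".join(residues))


def design_pro_g4(
    seq: NucleotideSequence,
    motif: G4Motif,
    stems: StemReport,
    length: int = 19,
    chemistry: Chemistry | None = None,
) -> AsoDesign:
    """Pro-G4 oligo: targets the competing arm of the stem that sequesters the
    most tract guanines, never overlapping tract-guanine positions, so that
    binding releases the tracts for quadruplex folding."""
    if length < 10:
        raise DesignError("pro-G4 oligos must be >= 10 nt")
    counts = tract_sequestration(motif, stems)
    if sum(counts) == 0:
        raise DesignError("no competing structure; pro-G4 design not applicable")
    tract_pos = motif.tract_positions()

    def stem_score(s):
        return sum(1 for p in s.positions() if p in tract_pos)

    stem = max(stems.stems, key=lambda s: (stem_score(s), s.length, -s.arm5[0]))
    # the competing partner strand: the arm free of tract guanines
    arms = sorted(
        (stem.arm5, stem.arm3),
        key=lambda a: sum(1 for p in range(*a) if p in tract_pos),
    )
    arm = arms[0]
    if any(p in tract_pos for p in range(*arm)):
        raise DesignError("both arms of the competing stem contain tract guanines")

    best: tuple[int, int] | None = None
    best_overlap = -1
    for start in range(0, len(seq) - length + 1):
        window = (start, start + length)
        if any(p in tract_pos for p in range(*window)):
            continue
        overlap = max(0, min(window[1], arm[1]) - max(window[0], arm[0]))
        if overlap > best_overlap:
            best, best_overlap = window, overlap
    if best is None or best_overlap == 0:
        raise DesignError(
            "no tract-free window of the requested length overlaps the competing arm"
        )
    oligo = reverse_complement(seq.segment(*best))
    chem = chemistry or Chemistry.two_prime_ome(length)
    return AsoDesign(oligo, ROLE_PRO, best, seq.id, chemistry=chem)


def design_ga_mutant(
    seq: NucleotideSequence,
    motif: G4Motif,
    n_subs: int = 2,
    seed: int = 0,
    max_candidates: int = 5000,
) -> NucleotideSequence:
    """G/A-mutant target: `n_subs` G->A substitutions in tract guanines,
    preferring distinct tracts and loop-2-distal positions, such that
    rescanning the mutant reports no motif overlapping the original locus.

    Raises with the minimum sufficient count if `n_subs` cannot abolish the
    motif.
    """
    if n_subs < 1:
        raise DesignError("n_subs must be >= 1")
    # candidate positions ordered: outer tracts first, loop-2-distal ends first
    tract_order = [0, 3, 1, 2]
    per_tract: list[list[int]] = []
    for ti in tract_order:
        s, e = motif.tract_spans[ti]
        positions = list(range(s, e))
        if ti in (2, 3):  # loop-2 downstream tracts: distal end is 3'
            positions = positions[::-1]
        per_tract.append(positions)

    def combos(size: int):
        # distinct tracts first
        for tracts in itertools.combinations(range(4), min(size, 4)):
            if len(tracts) == size:
                for choice in itertools.product(*(per_tract[t] for t in tracts)):
                    yield choice
        if size > 4:
            flat = [p for t in per_tract for p in t]
            for choice in itertools.combinations(flat, size):
                yield choice

    def abolished(mutant: NucleotideSequence) -> bool:
        for m in scan_canonical(mutant) + scan_long_loop(mutant):
            if not (m.end <= motif.start or motif.end <= m.start):
                return False
        return True

    def attempt(size: int) -> NucleotideSequence | None:
        for n_tried, choice in enumerate(combos(size)):
            if n_tried >= max_candidates:
                break
            residues = list(seq.residues)
            for p in choice:
                residues[p] = "A"
            mutant = NucleotideSequence(f"{seq.id}|ga_mutant", "".join(residues))
            if abolished(mutant):
                return mutant
        return None

    result = attempt(n_subs)
    if result is not None:
        return result
    for size in range(n_subs + 1, n_subs + 5):
        if attempt(size) is not None:
            raise DesignError(
                f"{n_subs} G/A substitution(s) cannot abolish the motif; "
                f"minimum required is {size}"
            )
    raise DesignError(f"{n_subs} G/A substitution(s) cannot abolish the motif")


def design_random_control(
    aso: AsoDesign,
    seq: NucleotideSequence,
    seed: int = 0,
    max_complementarity: float = 0.6,
    max_draws: int = 1000,
) -> AsoDesign:
    """Random negative control: composition-shuffled oligo of equal length
    whose complementarity to every window of the target stays below
    `max_complementarity`."""
    rng = np.random.default_rng(seed)
    letters = list(aso.oligo)
    n = len(letters)
    for _ in range(max_draws):
        shuffled = "".join(rng.permutation(letters))
        if _max_window_complementarity(shuffled, seq.residues) < max_complementarity:
            return AsoDesign(
                shuffled,
                ROLE_RANDOM,
                aso.target_span,
                seq.id,
                chemistry=aso.chemistry,
            )
    raise DesignError(
        f"could not draw a random control below {max_complementarity:.0%} "
        f"complementarity in {max_draws} shuffles"
    )


def _max_window_complementarity(oligo: str, target: str) -> float:
    n = len(oligo)
    best = 0.0
    for start in range(0, len(target) - n + 1):
        window = target[start : start + n]
        frac = (
            sum(
                duplex_thermo.is_watson_crick(oligo[i], window[n - 1 - i])
                for i in range(n)
            )
            / n
        )
        best = max(best, frac)
    return best


# ---------------------------------------------------------------------------
# Thermodynamic screen


@dataclass(frozen=True)
class ScreenThresholds:
    """Pass/fail bounds for the oligo screen (kcal/mol)."""

    self_structure_min: float = -2.0
    homodimer_min: float = -6.0
    concordance_ddg: float = 1.0


@dataclass(frozen=True)
class ScreenReport:
    self_delta_g: float
    homodimer_delta_g: float
    self_ok: bool
    homodimer_ok: bool
    passed: bool
    concordant_with_parent: Optional[bool] = None


def screen_candidate(
    aso: AsoDesign,
    thresholds: ScreenThresholds | None = None,
    parent: ScreenReport | None = None,
) -> ScreenReport:
    """Self-structure and homodimer screen. A mismatch control is concordant
    with its parent when the pass/fail verdict matches and the self-structure
    ΔΔG stays within the concordance threshold."""
    if len(aso.oligo) < 6:
        raise DesignError("screen requires oligos of >= 6 nt")
    th = thresholds or ScreenThresholds()
    self_dg = duplex_thermo.self_structure_delta_g(aso)
    dimer_dg = duplex_thermo.homodimer_delta_g(aso)
    self_ok = self_dg >= th.self_structure_min
    dimer_ok = dimer_dg >= th.homodimer_min
    passed = self_ok and dimer_ok
    concordant = None
    if parent is not None:
        concordant = (
            passed == parent.passed
            and abs(self_dg - parent.self_delta_g) <= th.concordance_ddg
        )
    return ScreenReport(self_dg, dimer_dg, self_ok, dimer_ok, passed, concordant)


# ---------------------------------------------------------------------------
# Oligo sheet


def designs_to_tsv(
    rows: Iterable[tuple[str, AsoDesign, ScreenReport | None]],
    path: str | Path,
) -> None:
    """Oligo sheet: id, role, sequence, chemistry, 1-based target span,
    anchor count, screen ΔGs and verdict."""
    with open(path, "w") as fh:
        fh.write(
            "id\trole\tsequence_5to3\tchemistry\ttarget_start\ttarget_end"
            "\tanchor_n\tself_dg\thomodimer_dg\tscreen\n"
        )
        for oid, d, rep in rows:
            chem = d.chemistry.scheme if d.chemistry else "."
            anchor = "." if d.anchor_n is None else str(d.anchor_n)
            if rep is None:
                sdg = hdg = verdict = "."
            else:
                sdg, hdg = f"{rep.self_delta_g:.2f}", f"{rep.homodimer_delta_g:.2f}"
                verdict = "pass" if rep.passed else "fail"
            fh.write(
                f"{oid}\t{d.role}\t{d.oligo}\t{chem}\t{d.target_span[0] + 1}"
                f"\t{d.target_span[1]}\t{anchor}\t{sdg}\t{hdg}\t{verdict}\n"
            )
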