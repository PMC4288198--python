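"""Synthetic sequences and assay datasets with known ground truth.

Every generator is seed-deterministic (identical spec + seed give identical
output) and forms a round-trip pair with an analysis operation: the scanner
recovers the planted motif, the stem finder recovers the planted duplex, the
ratio/Tm/qPCR estimators recover the generating parameters.

Sequence fixtures emulate the experimental constructs: an artificial G4 with
single-uridine loops 1/3, an unstructured 13-nt central loop and ~15-nt
flanks; and its "double-stranded" variant whose upstream region pairs with
loop 2 plus five loop-proximal tract guanines, sequestering them in a
stem-loop. Loop/flank residues are drawn from {A, C} with no CC run (and no
AAA run for the double-stranded variant), which guarantees no spurious
helix of >= 3 bp can form anywhere else; candidates are still
rejection-sampled against the stem finder and the scanners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .assay_stats import CqTable, LuciferasePlate, MeltingCurve, ProbingTable
from .g4scan import (
    CANONICAL,
    LONG_CENTRAL_LOOP,
    G4Motif,
    ScanParams,
    scan_all,
)
from .sequences import NucleotideSequence, reverse_complement
from .structure_context import Stem, StemReport, find_stems, tract_sequestration


class FixtureError(RuntimeError):
    pass


_KINDS = (
    "artificial_g4",
    "ds_g4",
    "probing_table",
    "melting_curve",
    "luciferase_plate",
    "cq_table",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request; identical spec + seed give identical output."""

    kind: str
    seed: int
    parameters: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")

    def build(self):
        maker = {
            "artificial_g4": make_artificial_g4,
            "ds_g4": make_ds_g4,
            "probing_table": make_probing_table,
            "melting_curve": make_melting_curve,
            "luciferase_plate": make_luciferase_plate,
            "cq_table": make_cq_table,
        }[self.kind]
        return maker(seed=self.seed, **dict(self.parameters))


def _loop_like(rng: np.random.Generator, n: int, forbid_aaa: bool = False) -> str:
    """Random {A,C} string with no CC run (optionally no AAA run): cannot seed
    a Watson-Crick or wobble helix of 3 bp against any part of the construct."""
    out: list[str] = []
    for _ in range(n):
        allow_c = not (out and out[-1] == "C")
        allow_a = not (forbid_aaa and len(out) >= 2 and out[-1] == out[-2] == "A")
        if allow_c and allow_a:
            ch = "C" if rng.random() < 0.35 else "A"
        elif allow_c:
            ch = "C"
        else:
            ch = "A"
        out.append(ch)
    return "".join(out)


def _build_artg4(
    tract_len: int,
    loop2_len: int,
    flank_len: int,
    rng: np.random.Generator,
    forbid_aaa: bool,
    upstream: str = "",
) -> tuple[NucleotideSequence, G4Motif]:
    flank5 = _loop_like(rng, flank_len, forbid_aaa)
    flank3 = _loop_like(rng, flank_len, forbid_aaa)
    loop2 = _loop_like(rng, loop2_len, forbid_aaa)
    g = "G" * tract_len
    core = g + "U" + g + loop2 + g + "U" + g
    residues = upstream + flank5 + core + flank3
    off = len(upstream) + flank_len
    t = tract_len
    tracts = (
        (off, off + t),
        (off + t + 1, off + 2 * t + 1),
        (off + 2 * t + 1 + loop2_len, off + 3 * t + 1 + loop2_len),
        (off + 3 * t + 2 + loop2_len, off + 4 * t + 2 + loop2_len),
    )
    loops = tuple((tracts[i][1], tracts[i + 1][0]) for i in range(3))
    params = ScanParams()
    cls = (
        LONG_CENTRAL_LOOP
        if loop2_len >= params.long_central_min
        else CANONICAL
    )
    seq = NucleotideSequence("ArtG4", residues)
    return seq, G4Motif(seq.id, tracts, loops, cls)


def make_artificial_g4(
    tract_len: int = 3,
    loop2_len: int = 13,
    flank_len: int = 15,
    seed: int = 0,
    max_draws: int = 1000,
) -> tuple[NucleotideSequence, G4Motif]:
    """Artificial G4 construct: four G-tracts, single-U loops 1/3, an
    unstructured central loop and mRNA-like flanks. The scanners recover
    exactly the planted motif and the stem finder reports no stems."""
    if tract_len < 2:
        raise ValueError("tract_len must be >= 2")
    if loop2_len < 1:
        raise ValueError("loop2_len must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_draws):
        seq, motif = _build_artg4(tract_len, loop2_len, flank_len, rng, False)
        if scan_all(seq) != [motif]:
            continue
        if find_stems(seq).stems:
            continue
        return seq, motif
    raise FixtureError(
        f"could not build a structure-free artificial G4 in {max_draws} draws"
    )


def make_ds_g4(
    tract_len: int = 3,
    loop2_len: int = 13,
    flank_len: int = 15,
    sequestered_g: int = 5,
    seed: int = 0,
    max_draws: int = 1000,
) -> tuple[NucleotideSequence, G4Motif, StemReport]:
    """Double-stranded G4 construct: an upstream region complementary to
    loop 2 plus `sequestered_g` loop-proximal tract guanines, so those
    guanines sit in a stem-loop competing with G4 folding."""
    a = (sequestered_g + 1) // 2  # guanines taken from the 3' end of tract 2
    b = sequestered_g - a  # guanines taken from the 5' end of tract 3
    if a > tract_len or b > tract_len:
        raise ValueError(
            f"sequestered_g={sequestered_g} exceeds available loop-proximal "
            f"tract guanines for tract_len={tract_len}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_draws):
        # shift placeholder: build without upstream first to locate the span
        seq0, motif0 = _build_artg4(tract_len, loop2_len, flank_len, rng, True)
        t2, t3 = motif0.tract_spans[1], motif0.tract_spans[2]
        pair_span = (t2[1] - a, t3[0] + b)
        arm_seq = reverse_complement(seq0.segment(*pair_span))
        spacer = _loop_like(rng, 4, True)
        upstream = arm_seq + spacer
        residues = upstream + seq0.residues
        shift = len(upstream)
        tracts = tuple((s + shift, e + shift) for s, e in motif0.tract_spans)
        loops = tuple((s + shift, e + shift) for s, e in motif0.loop_spans)
        seq = NucleotideSequence("DsG4", residues)
        motif = G4Motif(seq.id, tracts, loops, motif0.motif_class)
        if scan_all(seq) != [motif]:
            continue
        report = find_stems(seq)
        counts = tract_sequestration(motif, report)
        if sequestered_g == 0:
            if sum(counts) == 0:
                return seq, motif, report
            continue
        if counts != (0, a, b, 0):
            continue
        # ground truth stem must be the planted duplex
        planted_arm3 = (pair_span[0] + shift, pair_span[1] + shift)
        if not any(
            s.arm5 == (0, len(arm_seq)) and s.arm3 == planted_arm3
            for s in report.stems
        ):
            continue
        return seq, motif, report
    raise FixtureError(
        f"could not build a double-stranded G4 fixture in {max_draws} draws"
    )


def make_probing_table(
    motif: G4Motif,
    folded_fraction: float = 0.8,
    noise_sd: float = 0.05,
    seed: int = 0,
    seq_len: int | None = None,
    aso_conc: float = 0.0,
) -> ProbingTable:
    """In-line probing table over the whole construct (1-based positions).

    Baseline intensity 1 everywhere; the K+ lane scales loop positions by
    (1 + folded_fraction) and tract positions by (1 - 0.5 * folded_fraction);
    both lanes carry multiplicative log-normal noise of sd `noise_sd` (the Li+
    lane is noise only)."""
    if not (0.0 <= folded_fraction <= 1.0):
        raise ValueError("folded_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = seq_len if seq_len is not None else motif.end + 5
    loop_pos = motif.loop_positions()
    tract_pos = motif.tract_positions()
    base = np.ones(n)
    k = base.copy()
    for p in loop_pos:
        k[p] *= 1.0 + folded_fraction
    for p in tract_pos:
        k[p] *= 1.0 - 0.5 * folded_fraction
    li = base.copy()
    if noise_sd > 0:
        k = k * rng.lognormal(0.0, noise_sd, n)
        li = li * rng.lognormal(0.0, noise_sd, n)
    positions = tuple(range(1, n + 1))
    lanes = {
        ProbingTable.lane_label("K", aso_conc): tuple(float(x) for x in k),
        ProbingTable.lane_label("Li", aso_conc): tuple(float(x) for x in li),
    }
    return ProbingTable(positions, lanes)


def make_luciferase_plate(
    true_R: float = 1.5,
    cv: float = 0.10,
    n_replicates: int = 9,
    seed: int = 0,
    aso: str = "control",
) -> LuciferasePlate:
    """Dual-luciferase plate: wildtype arm at Rluc/Fluc = 1, mutant arm at
    `true_R`, mean-one log-normal multiplicative noise of the given CV on
    every well signal. n_replicates mirrors three experiments in triplicate."""
    if true_R <= 0:
        raise ValueError("true_R must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_replicates < 3:
        raise ValueError("need n_replicates >= 3 (three experiments in triplicate)")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0

    def noisy(mean: float, size: int) -> np.ndarray:
        if sigma == 0:
            return np.full(size, mean)
        return mean * rng.lognormal(-0.5 * sigma**2, sigma, size)

    rows = []
    for construct, level in (("wt", 1.0), ("ga_mutant", true_R)):
        rluc = noisy(level, n_replicates)
        fluc = noisy(1.0, n_replicates)
        for i in range(n_replicates):
            rows.append(
                {
                    "construct": construct,
                    "aso": aso,
                    "replicate": i + 1,
                    "rluc": float(rluc[i]),
                    "fluc": float(fluc[i]),
                }
            )
    return LuciferasePlate(pd.DataFrame(rows))


def make_melting_curve(
    tm: float = 60.0,
    slope: float = 2.5,
    folded_baseline: tuple[float, float] = (10.0, -0.02),
    unfolded_baseline: tuple[float, float] = (2.0, -0.01),
    noise: float = 0.0,
    seed: int = 0,
    t_min: float = 25.0,
    t_max: float = 90.0,
    step: float = 0.2,
) -> MeltingCurve:
    """Two-state CD melt: signal = unfolded(T) + [folded(T) - unfolded(T)] *
    θ(T) with θ = 1/(1 + exp((T - tm)/slope)) and linear (intercept, slope)
    baselines; Gaussian noise of sd `noise` x amplitude."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(t_min, t_max + step / 2, step)
    theta = 1.0 / (1.0 + np.exp((t - tm) / slope))
    fb = folded_baseline[0] + folded_baseline[1] * t
    ub = unfolded_baseline[0] + unfolded_baseline[1] * t
    y = ub + (fb - ub) * theta
    if noise > 0:
        amplitude = abs(
            (folded_baseline[0] + folded_baseline[1] * tm)
            - (unfolded_baseline[0] + unfolded_baseline[1] * tm)
        )
        y = y + rng.normal(0.0, noise * amplitude, len(t))
    return MeltingCurve(tuple(float(x) for x in t), tuple(float(x) for x in y))


def make_cq_table(
    levels: Mapping[str, Mapping[str, float]] | None = None,
    reference_genes: tuple[str, ...] = ("MRPL19", "SDHA", "YWHAZ"),
    efficiencies: Mapping[str, float] | None = None,
    noise: float = 0.0,
    seed: int = 0,
    cq0: float = 22.0,
) -> CqTable:
    """Cq table from true expression levels: Cq = cq0 - log_E(level) +
    Gaussian noise. Reference genes default to level 1 in every sample."""
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    if levels is None:
        levels = {"H2AFY": {"control": 1.0, "treated": 2.0}}
    efficiencies = dict(efficiencies or {})
    samples = sorted({s for gene_levels in levels.values() for s in gene_levels})
    rows = []
    all_genes = list(levels) + [g for g in reference_genes if g not in levels]
    for gene in all_genes:
        e = float(efficiencies.get(gene, 2.0))
        for sample in samples:
            level = float(levels.get(gene, {}).get(sample, 1.0))
            if level <= 0:
                raise ValueError("expression levels must be positive")
            cq = cq0 - math.log(level, e)
            if noise > 0:
                cq += float(rng.normal(0.0, noise))
            rows.append({"gene": gene, "sample": sample, "cq": cq})
    return CqTable(pd.DataFrame(rows), tuple(reference_genes), efficiencies)
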