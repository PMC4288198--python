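"""Quantification of G4 folding from the three assay read-outs, plus qPCR.

* In-line probing: unpaired (loop) nucleotides self-cleave faster; the
  per-nucleotide ratio of band intensity in K+ (G4-permissive) over Li+
  (non-permissive) reports accessibility. Elevated loop ratios together with
  depressed tract ratios call a folded G4.
* Dual-luciferase: Rluc carries the G4-containing 5'UTR, Fluc is the
  co-transfected normalizer. The relative G4-formation scale S rescales the
  mutant-to-wildtype ratio R of Rluc/Fluc means linearly so that the control
  oligo sits at 100 and R = 1 (no G4 effect) at 0:
  S = 100 * (R - 1) / (R_ctrl - 1).
* CD melting: fraction folded θ(T) from baseline-corrected 264-nm ellipticity;
  Tm is the θ = 0.5 crossing.
* qPCR: qBASE-style relative quantities normalized by the geometric mean of
  multiple reference genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .g4scan import G4Motif


class AssayError(ValueError):
    pass


# ---------------------------------------------------------------------------
# In-line probing


@dataclass(frozen=True)
class ProbingTable:
    """Per-nucleotide band intensities, one lane per (condition, ASO µM).

    `positions` are 1-based nucleotide indices (gel convention); lanes are
    keyed "K_0", "Li_0", "K_0.5", ... Intensities are arbitrary densitometry
    units, non-negative.
    """

    positions: tuple[int, ...]
    lanes: Mapping[str, tuple[float, ...]]

    def __post_init__(self):
        for label, values in self.lanes.items():
            if len(values) != len(self.positions):
                raise ValueError(f"lane {label!r} length differs from positions")
            if any(v < 0 for v in values):
                raise ValueError(f"lane {label!r} contains negative intensities")

    @staticmethod
    def lane_label(condition: str, aso_conc: float) -> str:
        conc = f"{aso_conc:g}"
        return f"{condition}_{conc}"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"position": self.positions})
        for label, values in self.lanes.items():
            df[label] = values
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbingTable":
        df = pd.read_csv(path, sep="\t")
        lanes = {
            c: tuple(float(x) for x in df[c]) for c in df.columns if c != "position"
        }
        return cls(tuple(int(p) for p in df["position"]), lanes)


@dataclass(frozen=True)
class AccessibilityProfile:
    """Per-position K+/Li+ intensity ratio ρ; NaN where undefined (flagged,
    never dropped)."""

    positions: tuple[int, ...]
    rho: tuple[float, ...]
    undefined: tuple[int, ...]  # positions with zero Li intensity
    condition: str = ""

    def rho_at(self, position: int) -> float:
        return self.rho[self.positions.index(position)]


def accessibility_profile(
    table: ProbingTable,
    aso_conc: float = 0.0,
    normalize: bool = True,
) -> AccessibilityProfile:
    """ρ_i = I_K(i) / I_Li(i) at the requested ASO concentration.

    With `normalize` (default), each lane is first divided by its total, which
    makes ρ invariant to whole-lane scaling (loading differences); set False
    to consume cpm-equalized densitometry output as-is.
    """
    k_label = ProbingTable.lane_label("K", aso_conc)
    li_label = ProbingTable.lane_label("Li", aso_conc)
    for label in (k_label, li_label):
        if label not in table.lanes:
            raise AssayError(f"missing lane {label!r} in probing table")
    k = np.asarray(table.lanes[k_label], dtype=float)
    li = np.asarray(table.lanes[li_label], dtype=float)
    if normalize:
        if k.sum() <= 0 or li.sum() <= 0:
            raise AssayError("cannot normalize a lane with zero total intensity")
        k = k / k.sum()
        li = li / li.sum()
    undefined = tuple(
        int(p) for p, v in zip(table.positions, li) if v == 0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(li > 0, k / li, np.nan)
    return AccessibilityProfile(
        table.positions,
        tuple(float(r) for r in rho),
        undefined,
        condition=f"aso={aso_conc:g}uM",
    )


@dataclass(frozen=True)
class FoldCallThresholds:
    loop_up: float = 1.5
    tract_down: float = 0.8
    min_loop_positions: int = 3


@dataclass(frozen=True)
class FoldCall:
    call: str  # folded | unfolded | ambiguous
    loop_median: float
    tract_median: float
    reason: str = ""


def g4_fold_call(
    profile: AccessibilityProfile,
    motif: G4Motif,
    thresholds: FoldCallThresholds | None = None,
) -> FoldCall:
    """Call folding from loop vs tract accessibility medians.

    folded: loop median >= loop_up AND tract median <= tract_down;
    unfolded: neither elevated loops nor depressed tracts;
    ambiguous: exactly one signature present, or too few loop positions.
    """
    th = thresholds or FoldCallThresholds()
    pos_to_rho = dict(zip(profile.positions, profile.rho))

    def medians(indices: set[int]) -> tuple[float, int]:
        vals = [
            pos_to_rho[p + 1]
            for p in indices
            if p + 1 in pos_to_rho and not math.isnan(pos_to_rho[p + 1])
        ]
        return (float(np.median(vals)) if vals else float("nan"), len(vals))

    missing = [p + 1 for p in motif.positions() if p + 1 not in pos_to_rho]
    if missing:
        raise AssayError(
            f"profile does not cover the motif span (missing positions {missing[:5]}...)"
        )
    loop_med, n_loop = medians(motif.loop_positions())
    tract_med, _ = medians(motif.tract_positions())
    if n_loop < th.min_loop_positions:
        return FoldCall(
            "ambiguous", loop_med, tract_med,
            f"only {n_loop} loop positions available (need {th.min_loop_positions})",
        )
    loops_up = loop_med >= th.loop_up
    tracts_down = tract_med <= th.tract_down
    if loops_up and tracts_down:
        return FoldCall("folded", loop_med, tract_med)
    if not loops_up and not tracts_down:
        return FoldCall("unfolded", loop_med, tract_med)
    return FoldCall(
        "ambiguous", loop_med, tract_med,
        "loop and tract signatures disagree",
    )


# ---------------------------------------------------------------------------
# Dual-luciferase


@dataclass(frozen=True)
class LuciferasePlate:
    """Well records: (construct, aso, replicate, Rluc, Fluc)."""

    wells: pd.DataFrame  # columns construct, aso, replicate, rluc, fluc

    REQUIRED = ("construct", "aso", "replicate", "rluc", "fluc")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.wells.columns:
                raise ValueError(f"plate missing column {col!r}")

    def to_tsv(self, path: str | Path) -> None:
        self.wells.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LuciferasePlate":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class RatioResult:
    """Mutant-to-wildtype ratio of Rluc/Fluc arm means with dispersion and a
    two-sided Welch t-test between arms."""

    R: float
    sd: float
    p_value: float
    mean_wt: float
    mean_mut: float
    n_wt: int
    n_mut: int


def construct_ratio(
    plate: LuciferasePlate,
    construct_pair: tuple[str, str] = ("wt", "ga_mutant"),
    aso: str = "control",
) -> RatioResult:
    """R = mean(mutant Rluc/Fluc) / mean(wildtype Rluc/Fluc) for one ASO.

    The standard deviation is propagated from the per-arm CVs; the p-value is
    a two-sided unequal-variance (Welch) t-test on per-well ratios.
    """
    wt_name, mut_name = construct_pair
    df = plate.wells[plate.wells["aso"] == aso]
    bad = df[df["fluc"] <= 0]
    if not bad.empty:
        row = bad.iloc[0]
        raise AssayError(
            f"non-positive Fluc in well (construct={row['construct']}, "
            f"aso={row['aso']}, replicate={row['replicate']})"
        )
    arms = {}
    for name in (wt_name, mut_name):
        sub = df[df["construct"] == name]
        if len(sub) < 2:
            raise AssayError(f"need >= 2 replicates for construct {name!r}, got {len(sub)}")
        arms[name] = (sub["rluc"] / sub["fluc"]).to_numpy()
    wt, mut = arms[wt_name], arms[mut_name]
    mean_wt, mean_mut = float(wt.mean()), float(mut.mean())
    r = mean_mut / mean_wt
    cv_wt = wt.std(ddof=1) / mean_wt
    cv_mut = mut.std(ddof=1) / mean_mut
    sd = abs(r) * math.sqrt(cv_wt**2 + cv_mut**2)
    if wt.std(ddof=1) == 0 and mut.std(ddof=1) == 0:
        p = 1.0 if np.allclose(wt.mean(), mut.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(mut, wt, equal_var=False).pvalue)
    return RatioResult(r, float(sd), p, mean_wt, mean_mut, len(wt), len(mut))


@dataclass(frozen=True)
class RelativeG4Score:
    """S = 100 (R - 1) / (R_ctrl - 1): control ASO pinned at 100, no-effect
    ratio R = 1 pinned at 0, linear in between."""

    R: float
    R_ctrl: float
    S: float


def relative_g4_formation(R: float, R_ctrl: float) -> RelativeG4Score:
    if abs(R_ctrl - 1.0) < 1e-12:
        raise AssayError("control shows no G4 effect; scale undefined")
    s = 100.0 * (R - 1.0) / (R_ctrl - 1.0)
    return RelativeG4Score(R, R_ctrl, s)


# ---------------------------------------------------------------------------
# CD melting


@dataclass(frozen=True)
class MeltingCurve:
    """264-nm ellipticity vs temperature; θ populated by fraction_folded."""

    temperature: tuple[float, ...]  # °C, strictly increasing
    signal: tuple[float, ...]  # mdeg
    theta: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        t = np.asarray(self.temperature)
        if len(t) != len(self.signal):
            raise ValueError("temperature and signal lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"temperature": self.temperature, "signal": self.signal})
        if self.theta is not None:
            df["theta"] = self.theta
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MeltingCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(df["temperature"]), tuple(df["signal"]))


def fraction_folded(
    curve: MeltingCurve,
    baseline_fraction: float = 0.10,
) -> MeltingCurve:
    """Two-state baseline correction: linear folded/unfolded baselines fitted
    on the terminal `baseline_fraction` of the temperature range; θ(T) is the
    signal position between them, clipped to [0, 1].

    Rejects when the two baselines explain the whole curve (no transition).
    """
    t = np.asarray(curve.temperature, dtype=float)
    y = np.asarray(curve.signal, dtype=float)
    if len(t) < 10:
        raise AssayError("need >= 10 temperature points")
    span = t[-1] - t[0]
    low = t <= t[0] + baseline_fraction * span
    high = t >= t[-1] - baseline_fraction * span
    if low.sum() < 2 or high.sum() < 2:
        raise AssayError("too few points in baseline windows")
    folded_fit = np.polyfit(t[low], y[low], 1)  # low-T: folded state
    unfolded_fit = np.polyfit(t[high], y[high], 1)  # high-T: unfolded state
    folded_bl = np.polyval(folded_fit, t)
    unfolded_bl = np.polyval(unfolded_fit, t)
    resid = max(
        float(np.std(y[low] - np.polyval(folded_fit, t[low]))),
        float(np.std(y[high] - np.polyval(unfolded_fit, t[high]))),
    )
    gap = float(np.median(np.abs(folded_bl - unfolded_bl)))
    if gap <= max(5.0 * resid, 1e-9):
        raise AssayError("no melting transition detected")
    theta = np.clip((y - unfolded_bl) / (folded_bl - unfolded_bl), 0.0, 1.0)
    # second pass: extend the baseline windows to every point the first pass
    # classifies as fully folded/unfolded, shrinking extrapolation error
    low2 = low | ((theta >= 0.99) & (t < t[np.argmin(np.abs(theta - 0.5))]))
    high2 = high | ((theta <= 0.01) & (t > t[np.argmin(np.abs(theta - 0.5))]))
    folded_bl = np.polyval(np.polyfit(t[low2], y[low2], 1), t)
    unfolded_bl = np.polyval(np.polyfit(t[high2], y[high2], 1), t)
    theta = np.clip((y - unfolded_bl) / (folded_bl - unfolded_bl), 0.0, 1.0)
    return replace(curve, theta=tuple(float(x) for x in theta))


def melting_tm(curve: MeltingCurve) -> float:
    """Tm: temperature of the θ = 0.5 crossing, linearly interpolated between
    bracketing grid points.

    Noise can create spurious crossings away from the transition; the crossing
    nearest the steepest descent of a lightly smoothed θ(T) is returned
    (deterministic)."""
    if curve.theta is None:
        curve = fraction_folded(curve)
    t = np.asarray(curve.temperature, dtype=float)
    th = np.asarray(curve.theta, dtype=float)
    d = th - 0.5
    crossings = []
    for i in range(len(t) - 1):
        if d[i] == 0.0:
            crossings.append(float(t[i]))
        elif d[i] * d[i + 1] < 0:
            frac = d[i] / (d[i] - d[i + 1])
            crossings.append(float(t[i] + frac * (t[i + 1] - t[i])))
    if d[-1] == 0.0:
        crossings.append(float(t[-1]))
    if not crossings:
        raise AssayError("fraction folded never crosses 0.5; Tm undefined")
    if len(crossings) == 1:
        return crossings[0]
    # locate the transition on the raw signal: its descent dominates any
    # baseline slope, and is immune to baseline-fit artifacts in θ
    y = np.asarray(curve.signal, dtype=float)
    span = t[-1] - t[0]
    w = max(1, int(round(2 * len(t) / span)))  # ~2 °C moving average
    kernel = np.ones(w) / w
    smooth = np.convolve(y, kernel, mode="same")
    slopes = np.gradient(smooth, t)
    interior = slice(w, len(t) - w)  # drop smoothing edge artifacts
    steep = int(np.argmin(slopes[interior])) + w
    t_steepest = float(t[steep])
    near = [c for c in crossings if abs(c - t_steepest) <= 5.0]
    if near:
        return float(np.median(near))
    return min(crossings, key=lambda c: abs(c - t_steepest))


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class CqTable:
    """Quantification-cycle records with reference genes and efficiencies.

    `efficiencies` maps gene -> amplification efficiency E (2.0 = perfect
    doubling per cycle); genes absent from the map default to 2.0.
    """

    records: pd.DataFrame  # columns gene, sample, cq
    reference_genes: tuple[str, ...]
    efficiencies: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for col in ("gene", "sample", "cq"):
            if col not in self.records.columns:
                raise ValueError(f"Cq table missing column {col!r}")
        if not self.reference_genes:
            raise ValueError("need at least one reference gene")
        if not np.isfinite(self.records["cq"]).all():
            raise ValueError("Cq values must be finite")

    def efficiency(self, gene: str) -> float:
        return float(self.efficiencies.get(gene, 2.0))

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        reference_genes: Sequence[str],
        efficiencies: Mapping[str, float] | None = None,
    ) -> "CqTable":
        return cls(
            pd.read_csv(path, sep="\t"),
            tuple(reference_genes),
            efficiencies or {},
        )


def qpcr_relative_levels(
    table: CqTable,
    calibrator: str | None = None,
) -> pd.DataFrame:
    """qBASE-style normalized relative expression.

    Per gene g and sample s: RQ = E_g^(min_s Cq - Cq); the per-sample
    normalization factor is the geometric mean of reference-gene RQs; the
    normalized level RQ/NF is rescaled so the calibrator sample (default:
    first sample in table order) equals 1 for every gene.
    """
    df = table.records.copy()
    samples = list(dict.fromkeys(df["sample"]))
    if calibrator is None:
        calibrator = samples[0]
    if calibrator not in samples:
        raise AssayError(f"calibrator sample {calibrator!r} not in table")
    for ref in table.reference_genes:
        for s in samples:
            if df[(df["gene"] == ref) & (df["sample"] == s)].empty:
                raise AssayError(f"missing reference Cq for gene {ref!r}, sample {s!r}")

    df["rq"] = [
        table.efficiency(g) ** (df[df["gene"] == g]["cq"].min() - cq)
        for g, cq in zip(df["gene"], df["cq"])
    ]
    nf = {}
    for s in samples:
        refs = df[(df["sample"] == s) & (df["gene"].isin(table.reference_genes))]
        nf[s] = float(stats.gmean(refs["rq"]))
    df["normalized"] = [rq / nf[s] for rq, s in zip(df["rq"], df["sample"])]
    out = df.pivot_table(index="gene", columns="sample", values="normalized")
    out = out.div(out[calibrator], axis=0)
    return out.reset_index().melt(
        id_vars="gene", var_name="sample", value_name="level"
    )
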