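# Methods

This note records the models, parameter choices and numerical decisions
behind `g4switch`, and what the synthetic fixtures do and do not emulate.

## Motif model and scanning

A G4 motif is four *maximal* runs of guanine (each ≥ `min_tract_g`,
default 2) with the three inter-tract gaps as loops. Two disjoint
classes are reported: `canonical` (all loops within 1–7 nt) and
`long_central_loop` (flanking loops ≤ 7 nt, central loop 8–30 nt). The
8-nt lower and 30-nt upper central-loop bounds follow the in vitro
folding evidence for extended-loop quadruplexes; both are parameters
(`ScanParams`). Scanning is an exhaustive enumeration over ordered
4-subsets of maximal G-runs, so overlapping placements are all
reported and the scanner is trivially equivalent to brute force; a
greedy post-filter (`select_nonoverlapping`, most tract guanines wins,
leftmost breaks ties) reduces to a disjoint subset when one motif per
locus is wanted. Gaps may contain further G-runs: a skipped run simply
becomes loop sequence, which is the permissive reading of the loop
definition. Scanning is sense-strand only — an RNA G4 has no
complementary-strand equivalent, and the reverse complement of a
G-rich motif is C-rich and reports nothing.

Coordinates are 0-based half-open internally, BED convention in BED
output, 1-based inclusive in report TSVs. T is accepted on input and
mapped to U; outputs emit U.

## Design rules

* **Anti-G4**: target span `[end(tract2) − n, start(tract3) + n)`,
  oligo = reverse complement. Anchoring is symmetric and uses the
  loop-2-proximal guanines of tracts 2 and 3, matching the geometry in
  which the oligo lies across the central loop with equal guanine
  doublets/triplets gripped on each side. Default `anchor_n = 3`
  (19-mer on a 13-nt loop): the longest member of the series, and the
  one carried forward experimentally because inhibition grows with
  anchored guanines.
* **Mismatch control**: k (default 3) substitutions confined to
  oligo positions that pair with loop 2, spread to maximize the
  minimum pairwise distance (even spacing over the window; the seed
  only breaks exact ties). Substitution rule: the complementary base
  is replaced by its transversion partner under the swap A↔C, G↔U,
  which can never pair (not even wobble) with the original target
  base. The compensatory "alternative target" that restores perfect
  pairing is derivable via `alternative_target`.
* **Pro-G4**: among stems that sequester tract guanines, the one
  sequestering most is selected; the oligo (default 19-mer) targets a
  window maximizing overlap with the stem arm that is free of tract
  guanines and never covers a tract-guanine position. Absence of any
  sequestering stem is a hard error: promotion is meaningless without
  competition.
* **G/A-mutant**: candidate guanine positions are searched in a fixed
  preference order (outer tracts first, loop-2-distal positions
  first, distinct tracts before repeats) and the first substitution
  set whose rescan shows no motif overlapping the original locus is
  returned. If `n_subs` cannot abolish the motif the error names the
  minimum count that can.
* **Random control**: a composition shuffle with < 60% complementarity
  to every target window, rejection-sampled, seed-deterministic.

## Thermodynamics

The duplex evaluator uses the unified Watson–Crick RNA/RNA
nearest-neighbor ΔG°37 stack table (shipped as
`data/rna_nn_stacks.tsv`) with +4.09 kcal/mol duplex initiation.
Deliberate simplifications, all configurable:

* internal mismatches cost a flat +1.0 kcal/mol and interrupt
  stacking; terminal mismatches are free;
* 2′-O-Me positions reuse unmodified RNA parameters; each paired LNA
  position contributes −1.0 kcal/mol, reproducing the qualitative
  LNA > 2′-O-Me affinity ordering;
* no terminal-AU penalty, so a homodimer of a palindromic oligo
  equals the duplex of the oligo against itself exactly;
* hairpin evaluation is an exhaustive stem enumeration (min helix 3 bp,
  min loop 3 nt, flat 5.0 kcal/mol loop closure), not a full folding
  partition function.

Absolute ΔG values are therefore implementation-defined; the screen
thresholds (self-structure fail < −2.0, homodimer fail < −6.0,
mismatch-control concordance |ΔΔG| ≤ 1.0 kcal/mol) are calibrated to
these conventions and exposed in `ScreenThresholds`.

## Structural context

`find_stems` enumerates maximal contiguous helices (G·U wobble
counted; ≥ 3 bp; hairpin gap ≥ 3 nt) and greedily retains a
non-overlapping, non-crossing set by descending length. It is a helix
enumerator, not an MFE folder; ΔG per stem is a stack-sum estimate
with a flat −0.5 kcal/mol for wobble-containing steps. Output from a
real predictor can be substituted through `load_dotbracket`, which
produces the same report type, and the recommended window is the motif
span ± 50 nt.

## Assay quantification

* **Probing**: ρᵢ = I_K/I_Li per position, after optional per-lane
  total normalization (default on, making ρ invariant to whole-lane
  scaling; turn off to consume cpm-equalized densitometry tables
  as-is). Zero-denominator positions are flagged, never dropped. The
  fold call compares the loop-position median (≥ 1.5 ⇒ elevated) and
  tract-position median (≤ 0.8 ⇒ depressed); both signatures ⇒
  `folded`, neither ⇒ `unfolded`, disagreement or < 3 usable loop
  positions ⇒ `ambiguous`. The thresholds are this package's
  quantitative rendering of calls that are made qualitatively from
  histograms in practice.
* **Luciferase**: R is the ratio of arm means of per-well Rluc/Fluc
  (not the mean of well ratios), with SD propagated from the arm CVs
  and a two-sided Welch t-test between arms ("Student's t-test"
  without a variance statement is implemented as unequal-variance).
  S = 100(R−1)/(R_ctrl−1) is exact arithmetic; R_ctrl = 1 is rejected
  as the scale is then undefined.
* **Melting**: linear baselines are fitted on the terminal 10% of the
  temperature range, then refitted on all points the first pass
  classifies as fully folded/unfolded — the second pass shrinks the
  extrapolation error of short terminal windows, which otherwise
  dominates the Tm error budget. θ is clipped to [0,1];
  "no transition" is declared when the baseline gap does not exceed
  5× the baseline residual. Tm interpolates the θ = 0.5 crossing; if
  noise creates several crossings, the median of those within 5 °C of
  the steepest descent of the (2 °C-smoothed) raw signal is used —
  the raw signal locates the transition robustly even when a baseline
  window clips the transition edge.
* **qPCR** (qBASE form): RQ = E^(Cq_min − Cq) per gene, per-sample
  normalization factor = geometric mean of reference-gene RQs
  (defaults MRPL19, SDHA, YWHAZ, E = 2.0), rescaled so the calibrator
  sample (default: first in table order) equals 1.

## Synthetic fixtures: what they emulate, and what not

Generators mirror the experimental constructs and read-outs at their
published conditions: tract length 3, single-U loops 1/3, 13-nt
central loop, ~15-nt flanks; five sequestered guanines (3 from tract
2, 2 from tract 3) for the double-stranded construct; probing lanes at
0/0.5/5 µM oligo labels; ≥ 3 replicates per reporter arm (three
experiments in triplicate); melts on a 25–90 °C grid at 0.2 °C steps.
Noise models are invented but conservative: mean-one log-normal
multiplicative noise on intensities and luminescence, Gaussian noise
on Cq. Loop/flank residues are drawn from {A, C} with no CC run (and
no AAA run for the double-stranded variant), which structurally
guarantees no spurious ≥ 3 bp helix; candidates are still
rejection-sampled against the stem finder and the scanners (≤ 1000
draws). Real 5′UTRs are G/U-rich, fold, and carry flanking structure
— passing round-trips on these fixtures demonstrates the correctness
of the geometry, arithmetic and estimators, not scanner specificity or
design efficacy on natural transcripts. Cellular biology (transfection
efficiency, position effects, mRNA stability) is out of scope
entirely.

## Problem sizes

The default test run uses 1000 random sequences (≤ 200 nt) for the
scanner/oracle equivalence, 100 synthetic melts for Tm recovery, 300
plates (1000 in the unit suite) for ratio recovery, and 100 probing
tables for fold-call sensitivity — sizes at which every estimate in
this note is reproduced comfortably on a laptop.

## Known limitations

* No G4 propensity scoring (G4Hunter/cGcC) and no quartet-count
  stability model: detection is purely geometric.
* The thermodynamic module gives orderings, not calibrated free
  energies; no salt or temperature extrapolation, no
  phosphorothioate-specific corrections.
* The builtin stem finder reports helices, not a folded ensemble;
  pseudoknots are excluded.
* The LNA placement pattern is a configurable stand-in (alternating
  from the 5′ end, 8 residues on a 19-mer); vendor patterns vary.
* The fold-call thresholds (1.5/0.8) are package conventions, not
  community standards; report ρ profiles alongside calls.
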