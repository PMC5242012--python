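# Methods

`venombank` models the desk-side half of a high-throughput pipeline that
expresses disulphide-rich venom peptides in the *E. coli* periplasm: gene
design, assembly-oligo tiling, construct bookkeeping, mass-spectrometric QC,
bank triage, and a stochastic model of gene-synthesis errors and colony
screening. This note records the models, defaults and design choices, and
what the synthetic data can and cannot show.

## Peptide records and cysteine frameworks

A peptide is a string over the 20 canonical residues; ambiguity codes are
rejected outright because every downstream stage (codon choice, elemental
composition, extinction coefficients) needs a concrete residue. The cysteine
framework projects the sequence onto its cysteines: cysteines at consecutive
positions concatenate (`CC`), others join with `-`. Runs of three or more
cysteines are rendered as that many concatenated `C`s — published framework
notation only shows pairs, so this is a documented generalization. The
maximum bridge count is `floor(n_cys / 2)`; an odd cysteine count sets a flag
rather than an error, since a small minority of natural venom peptides do
carry unpaired cysteines.

## The synthetic library generator

Real production-campaign sequences are confidential, so tests and the
acceptance run use a generator that emulates the campaign's composition:

| parameter | default | rationale |
|---|---|---|
| length | uniform 35–120 aa | the recombinant-production size window |
| bridges | uniform 1–9 | observed bridge-count range |
| taxon mix | spider .43, scorpion .31, snake .10, centipede .07, cone snail .06, other .03 | observed species composition |
| odd-cysteine fraction | 0.02 | ≈99/4992 in the real bank |
| named-framework probability | 0.6 | the common folds (ICK, three-finger, Csα/β, Csα/α, C–C) dominate real banks |

Frameworks are realized by partitioning cysteines into blocks of 1–2
(adjacent-pair probability 0.15 for random frameworks), placing blocks with
at least one spacer residue, and drawing the remaining residues uniformly
from the 19 non-Cys letters (a user-supplied residue distribution is
accepted). Everything is driven by one `numpy` generator, so libraries are
bit-for-bit reproducible under a seed.

What the generator does *not* emulate: real residue composition (venom
peptides are biased toward certain residues), propeptides, the correlation
between taxon and length/framework, and of course wet-lab producibility.
Passing tests therefore validate the algorithms, not biological yield
predictions.

## Codon design

Genes are `TEV-prefix (GAGAACCTGTACTTCCAA, encoding ENLYFQ) + one codon per
residue + TAATAA`. The CAI of a gene is the geometric mean of the relative
adaptiveness `w = f/f_max` of its codons under a reference usage table; Met,
Trp and stop codons are excluded from scoring (Sharp & Li convention — the
exclusion set is an argument, so the convention is switchable). The packaged
default table is standard *E. coli* K-12 usage (per-1000); any delimited
`codon, aa, frequency` table can be supplied.

Initialization uses the `w = 1` codon everywhere except cysteine, which
alternates TGC/TGT starting from the more frequent codon so the two cysteine
codons appear in equal proportion (|ΔTGC−TGT| ≤ 1). Repair then runs a
steepest-descent loop over single-codon synonymous swaps against the rule
set: GC 40–60 % (global, whole gene — a windowed variant was considered and
rejected because reported per-gene GC is global), homopolymer ≤ 5 nt, G/C
runs ≤ 6 nt, no forbidden motif on either strand (default list: σ70 −10 box
TATAAT and Shine–Dalgarno AGGAGG — deliberately minimal configuration), no
codon with `w <` 0.1, cysteine-codon balance, CAI ≥ 0.8.

Acceptance of a repair is governed by a two-level severity: the count of
violated *hard* sequence rules (runs, motifs, rare codons, Cys balance),
then a continuous badness summing run excesses, motif hits, GC distance from
the window, CAI shortfall and Cys imbalance. Accepted swaps must strictly
decrease this pair lexicographically, so hard violations never regress,
while the graded score rules (GC, CAI) may trade transiently — necessary
because e.g. breaking a poly-A homopolymer in a lysine run costs CAI, and
for degenerate peptides (short poly-K, poly-F) GC or CAI targets are
provably unreachable. Such designs come back with explicit failed flags,
never exceptions. The seeded RNG is used only for the violation visit order
and for breaking exact ties between candidate swaps (tie order: higher `w`,
higher frequency, alphabetical codon); optimization is deterministic under a
fixed seed. The iteration cap is `10 × peptide length`; in practice designs
converge in under ten repairs.

## Oligo tiling ("scheme A")

Tiling is anchored at top-strand position 0 with period `P = max_len + gap`
(80 nt by default): top oligos at `[80i, 80i+60)`, internal bottom oligos at
`[80j+40, 80j+100)` (clipped to the gene end), and a terminal bottom oligo
from `80(n_top−1)+40` to `L` when non-empty. Every junction is an exact
20-nt reverse-complement duplex; terminal truncations down to 15 nt are
allowed, and any shorter oligo is extended leftward into the duplex to
15 nt. The two outermost oligos double as the amplification primers. The
anchoring reproduces the published primer statistics (220 nt → 6 oligos,
137 nt → 4); the closed-form count `n_top + (n_top−1) + [L > 80(n_top−1)+40]`
is verified against the full tiling across the length range. The scheme
yields 11 oligos at the 413-nt maximum where the published table prints a
maximum of 10; the commercial designer's anchoring is unknown and may be
length-balanced, so this single extreme is a known, documented divergence.
In-silico reassembly checks junction duplexes, stitches the top-strand
consensus, and flags junction 20-mers that recur elsewhere in the gene
(mispriming risk). No melting-temperature balancing is attempted: the
geometry, not thermodynamics, is the specification here.

## Constructs and masses

The fusion is `carrier + ENLYFQ + peptide` at protein level; TEV cleavage
after Q releases the native peptide with no added residue. The real
DsbC-His6 carrier sequence is not redistributable, so the default carrier is
mass-only: 27,787 Da, reverse-derived from the published relation that a
5935-Da average peptide is 17.6 % of its fusion. The mass-only constant is
defined to cover everything upstream of the peptide *including* the TEV
site and junction water, so `fusion = carrier_constant + peptide_mass`
exactly matches the residue-level sum (`carrier_mass_from_sequence` derives
such a constant from any carrier sequence). When a carrier sequence is
given, its His6 tag is located as the last `HHHHHH` occurrence for
annotation; carrier DNA for GenBank output is a `w = 1` back-translation
(synthetic — the real vector DNA is not public).

Mass conventions: monoisotopic and average masses from standard residue
tables (via `pyteomics`); each disulphide bridge subtracts 2 × 1.007825 Da
(mono) or 2 × 1.00794 Da (average). Oxidation-state calling uses average
masses with a 1.0 Da tolerance by default (quadrupole-class deconvolution);
ties between adjacent ladder species break toward the more oxidized species,
mirroring the observation that reduced forms do not survive the acidified
purification. Isotope patterns are aggregated by nominal offset: per-element
isotopologue distributions are raised to the atom count by binary
exponentiation of the convolution and multiplied across elements; the test
oracle is an independent atom-by-atom dictionary convolution, and the two
agree to < 1e-6 relative abundance for CHNOS compositions. Extinction
coefficients follow Gill–von Hippel (5500·W + 1490·Y + 125·cystine, with
cystines = max bridges when oxidation is assumed); peptides without W/Y/C
get ε = 0 plus a low-confidence flag because A280 quantification is then
meaningless.

## Triage and banking

Bins partition [0, ∞): > 20 µM → dilute to 10 µM (C₁V₁ = C₂V₂ at 250 µL,
mole-exact); 5–20 µM → bank as-is ("10 µM bank"); 1–5 µM → "1 µM bank";
< 1 µM → discard (counted as non-producing). The published ranges overlap at
their endpoints; the half-open convention here (20 → as-is, 5 → as-is,
1 → kept) makes them disjoint and is configurable. Plates hold 80 peptides
plus 16 controls; controls sit in columns 1 and 12 (the source protocol
says only "2×8 empty wells" — a fixed choice here), peptides fill
column-major across columns 2–11, and each 250-µL stock feeds five 50-µL
copies. Report percentages round half-away-from-zero to integers; note that
562/2736 renders as 21 % although it is usually quoted as ~20 %.

## Synthesis-error and screening simulator

Errors are single-base events — the dominant failure mode of chemical oligo
synthesis; multi-base deletions are not modelled. Per clone the error count
is Poisson(rate·L/1000) with default 1.06 errors/kb, positions uniform,
types drawn from the spectrum (deletion .76 / insertion .07 / substitution
.17), with an optional per-base bias table. Screening is sequential: one
colony per cloning reaction, a second and at most a third only on failure
(policy configurable). The Poisson closed form `exp(−rate·L/1000)` is the
calibration oracle; the simulator matches it within 3 Monte-Carlo standard
errors in the test suite. Because the published error-rate estimator is not
fully specified, two are reported: naive (incorrect clones per kb sequenced,
one error per incorrect clone — a deliberate undercount) and maximum
likelihood (−ln p̂₁ over mean gene kb, which recovers the simulation input).

## Problem sizes and numerical notes

The default test/acceptance runs use a 200-peptide design batch, 400-length
tiling sweeps, ~10⁴-gene tiling statistics, and screening simulations of
1–4 × 10³ genes — sizes at which every Monte-Carlo assertion has comfortable
margin while the whole suite runs in seconds. Mass assertions use absolute
tolerances (1e-6 Da for additivity, 1e-3 Da against tabulated values);
percentage renderings use round-half-away-from-zero throughout.

## Known limitations

* The optimizer's repair neighbourhood is single-codon swaps; pathological
  constraint sets that require coordinated multi-codon moves end with
  honest failure flags instead of solutions.
* Scheme A is one admissible reading of the published oligo geometry; only
  its aggregate statistics, not the vendor tool's exact coordinates, are
  reproducible.
* The isotope engine aggregates by nominal mass; fine structure within an
  isotopologue peak is out of scope for quadrupole-resolution QC.
* Wet-lab outcomes (expression success, folding, cleavage efficiency) are
  inputs, never predictions: `production_report` summarises observed
  outcome tables and the simulator models sequence fidelity only.
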