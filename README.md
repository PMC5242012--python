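# venombank

Design and QC toolkit for building large *E. coli* expression libraries of
disulphide-rich venom peptides.

Animal venoms are rich in short (35–120 aa), cysteine-reticulated peptides —
highly selective, stable receptor ligands and prime drug-discovery starting
material. Producing thousands of them recombinantly means, before any wet
lab work: back-translating each peptide into a codon-optimized synthetic
gene, tiling that gene into PCR-assembly oligonucleotides, tracking the
periplasmic DsbC–His6–TEV fusion construct, predicting the masses and
isotope patterns that confirm full oxidation on the mass spectrometer,
normalizing purified peptides into screening bank plates, and budgeting for
the sequence errors that chemical oligo synthesis injects into cloned genes.
`venombank` implements that desk-side pipeline for bench scientists and
pipeline engineers running (or simulating) such campaigns.

## The models at the core

* **Codon optimization.** Genes are `TEV site (ENLYFQ) + peptide codons +
  duplicated TAA stop`. Starting from the most-adapted codon per residue
  (cysteines alternate TGC/TGT so both codons are used equally), a
  deterministic repair loop enforces: GC ∈ [40, 60] %, homopolymers ≤ 5 nt,
  G/C runs ≤ 6 nt, no regulatory motifs on either strand, no codon with
  relative adaptiveness *w* < 0.1, and CAI ≥ 0.8, where
  CAI = (∏ᵢ wᵢ)^(1/L) is the geometric mean of wᵢ = f(codonᵢ)/f(best
  synonym) over a highly-expressed-gene usage table.
* **Oligo tiling.** With period P = 80 nt, top-strand oligos cover
  [80i, 80i+60) and bottom-strand oligos [80j+40, 80j+100), giving exact
  20-nt junction duplexes and 20-nt same-strand gaps; a 220-nt gene takes 6
  oligos, a 137-nt gene 4. Reassembly is verified in silico.
* **Disulphide mass ladders.** mass(n bridges) = mass(reduced) − 2n·m_H;
  an observed deconvoluted mass is matched against the ladder to call the
  oxidation state (fully oxidized = ⌊n_cys/2⌋ bridges). Isotope patterns
  come from convolving per-element isotopologue distributions.
* **Bank triage.** > 20 µM → dilute to 10 µM; 5–20 µM → bank as-is;
  1–5 µM → 1 µM bank; < 1 µM → discard. 80 peptides + 16 controls per
  96-well plate, five 50-µL copies each.
* **Synthesis-error model.** Errors per clone ~ Poisson(rate·L/1000) with
  rate 1.06/kb, spectrum 76 % deletions / 7 % insertions / 17 %
  substitutions; sequential screening of up to 3 colonies per gene, with
  the closed form P(correct) = e^(−rate·L/1000) as oracle.

A confidential-sequence-free synthetic library generator reproduces the
composition of a real campaign (taxon mix, lengths, bridge counts, cysteine
frameworks) for testing and benchmarking.

## Worked example

```python
from venombank import (generate_synthetic_library, CodonTable, optimize,
                       design_oligos, simulate_assembly, MassProfile,
                       match_observed, assign_bin, screening_statistics)

lib = generate_synthetic_library(n=96, seed=7)
pep = lib[0]
print(f"{pep.id}: {pep.length} aa, taxon={pep.taxon_group}, "
      f"framework {pep.pattern} ({pep.n_bridges_max} bridges)")

gene = optimize(pep, CodonTable.default(), seed=1)
print(f"gene: {len(gene.cds)} nt, CAI {gene.cai:.3f}, GC {gene.gc_percent:.1f}%, "
      f"all constraints pass: {gene.passes_all}")

plan = design_oligos(gene.cds, pep.id)
print(f"assembly: {plan.n_oligos} oligos, reassembly ok: "
      f"{simulate_assembly(plan, gene.cds).ok}")

profile = MassProfile.from_sequence(pep.sequence, pep.id)
qc = match_observed(profile, profile.species[-1].average)
print(f"QC: oxidized average mass {profile.species[-1].average:.2f} Da -> {qc.status}")

decision = assign_bin(25.0, pep.id)
print(f"triage at 25.0 uM: {decision.bin}, {decision.stock_volume_ul:.0f} uL stock "
      f"+ {decision.water_ul:.0f} uL water")

stats = screening_statistics((3818, 809, 365), 4992)
print(f"colony cascade: {stats.fractions_pct} %, "
      f"mean {stats.mean_colonies} colonies per gene")
```

which prints:

```text
VP00001: 93 aa, taxon=scorpion, framework C-C-C-CC-C-C-C-C-C-C-C-C-C-C-C-C-C (9 bridges)
gene: 303 nt, CAI 0.956, GC 47.9%, all constraints pass: True
assembly: 8 oligos, reassembly ok: True
QC: oxidized average mass 10773.57 Da -> fully_oxidized
triage at 25.0 uM: adjust_to_10, 100 uL stock + 150 uL water
colony cascade: (76.5, 16.2, 7.3) %, mean 1.3 colonies per gene
```

Reading this: the generator produced a 93-residue scorpion-like peptide with
9 disulphide bridges; its 303-nt gene passes every design constraint at
CAI 0.956 and 47.9 % GC; the gene tiles into 8 assembly oligos that
reassemble exactly; the fully oxidized species (18 H lighter than reduced)
is what QC should observe; a 25 µM purification is diluted 100 µL + 150 µL
water to 250 µL at 10 µM; and sequencing counts of 3818/809/365 correct
genes at colonies 1/2/3 of 4992 mean 1.3 colonies screened per recovered
gene.

A `venombank` console script exposes the same steps
(`synth-library`, `design`, `oligos`, `construct`, `qc`, `triage`,
`report`, `simulate`); run `venombank --help`.

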