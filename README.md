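# openrds

Scoring and synonymous-codon design of the **ribosome docking site (RDS)**
for prokaryotic (cell-free) expression constructs.

## The problem

Cell-free expression with a prokaryotic machinery is exquisitely sensitive
to mRNA secondary structure around the start codon: the lysate has no
helicase-driven scanning to clear structured 5′ ends, so the ~30-nt segment
that the 30S subunit must dock on — Shine–Dalgarno (SD) motif, spacer,
start codon and the proximal coding region — has to be single-stranded at
equilibrium. Constructs that bury this segment in a hairpin transcribe
normally but translate poorly or not at all. Because the genetic code is
redundant, the proximal coding region can usually be *re-encoded
synonymously* to melt such structure without touching the protein.

`openrds` quantifies and exploits this:

* it scores a construct by the **translation-initiation potential**

  δ = exp( −(ΔE_SD + ΔE_tRNA + ΔE_open) / RT )

  where ΔE_SD is the SD/anti-SD hybridization free energy, ΔE_tRNA the
  start-codon/initiator-tRNA stabilization (−1.19 kcal/mol for AUG,
  −0.075 kcal/mol for GUG), and ΔE_open the **opening energy** of the
  30-nt RDS window — the difference between the constrained (window forced
  single-stranded) and unconstrained ensemble free energies;
* it scans ΔE_open(i) over SD placements i (i = 0 at the first nucleotide
  of the start codon; the canonical placement is i = −11, scans default to
  i ∈ [−13, −5]);
* it minimizes ΔE_open at the canonical placement by **simulated
  annealing** over single-nucleotide synonymous mutations in the first
  coding codons, preserving 5′UTR, SD, start codon and protein exactly.

Folding thermodynamics come from an exact McCaskill-style partition
function over a simplified nearest-neighbor model (see
`docs/methods.md`), backed by an exhaustive structure-enumeration oracle
for short sequences; ViennaRNA can be swapped in as an alternative engine
(`--set energy.backend=reference-engine`).

## Worked example

Generate the bundled toy gene — a construct whose first six codons pair
with a complementary 5′UTR segment, occluding the RDS — then scan and
optimize it:

```sh
openrds fixtures --kind toy-gene --out-prefix toy
openrds scan --construct toy.toy-gene.construct --out toy.profile.tsv
openrds optimize --construct toy.toy-gene.construct --region 1:6 --seed 1 \
        --out toy.optimized.json
```

The scan shows a strongly occluded docking site (ΔE_open ≈ 17 kcal/mol
across all SD placements):

```
construct  i    dE_open_kcal_mol
toy-gene   -13  17.353627677540363
toy-gene   -12  17.36616811021038
...
```

and the optimizer melts it with six silent third-position substitutions:

```
toy-gene: dE_open 17.134 -> 0.597 kcal/mol (6 mutation(s)); wrote toy.optimized.json
```

`toy.optimized.json` records the mutations in coding (c.) notation —
`c.6U>C, c.9U>C, c.12U>C, c.15U>C, c.18U>C, c.21U>C` — the optimized
coding sequence `AUGGACAACUACCACGACUUCAAAAAAAAA` (same protein,
MDNYHDFKKK), and the final δ. A 28-fold drop in ΔE_open at fixed ΔE_SD
and ΔE_tRNA raises δ by a factor exp(16.5/RT) ≈ 10¹¹: the redesigned
transcript is predicted to initiate, the wild type is not. On this
64-combination instance the annealed optimum coincides with the
brute-force global optimum.

Other commands: `openrds score` (δ report for one or more constructs),
`openrds profile-genome --fasta F --gff G` (mean ΔE_open(i) across all
annotated CDS starts of a genome, strand-aware).

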