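# Methods

## The initiation model

A prokaryotic 30S subunit initiates on an mRNA when (i) the Shine–Dalgarno
(SD) motif hybridizes with the anti-SD tail of 16S rRNA, (ii) the
initiator tRNA pairs with the start codon, and (iii) the ~30-nt ribosome
docking site (RDS) spanning SD, spacer, start codon and proximal coding
region is single-stranded. The package condenses this into the
translation-initiation potential

    δ = exp(−(ΔE_SD + ΔE_tRNA + ΔE_open) / RT)

with R the molar gas constant (1.987·10⁻³ kcal·mol⁻¹·K⁻¹ — all energies
are molar, so "Boltzmann constant" is read on the molar scale) and
T = 310.15 K by default. δ is a Boltzmann weight, not a rate: it orders
constructs by the equilibrium feasibility of assembling the initiation
complex. Within a set of constructs sharing SD and start codon, ΔE_SD and
ΔE_tRNA are constant and the ordering is carried entirely by ΔE_open.

Component conventions:

* **ΔE_SD** — minimum intermolecular hybridization free energy of the SD
  motif against the configured anti-SD (default `ACCUCCUUA`, the
  *E. coli* 16S 3′-tail read 5′→3′; configurable, and echoed in every
  report since different anti-SDs shift all scores). When no canonical
  pair is possible the component is *absent* (flagged, contributes 0) —
  distinct from a true 0.0 kcal/mol duplex.
* **ΔE_tRNA** — per-start-codon constant: −1.19 kcal/mol (AUG),
  −0.075 kcal/mol (GUG). Other annotated starts are scoreable for
  ΔE_open profiles but have no δ.
* **ΔE_open** — ensemble free energy with the RDS window constrained
  single-stranded minus the unconstrained ensemble free energy; ≥ 0 by
  construction (the constrained ensemble is a subset).

### Coordinates and the window anchor

Positions are 0-based half-open internally; offsets *i* are relative to
the start codon (i = 0 at its first nucleotide, negative upstream). The
SD anchor is the 5′-most nucleotide of the SD motif — the choice is a
convention, recorded and configurable, since "SD position" is ambiguous
between the motif's ends. The RDS window is [i, i + 30): anchored at the
SD anchor and running 30 nt downstream, covering SD, spacer, start codon
and roughly the first seven codons at the canonical i = −11. This is the
single most consequential convention in the package. Scans default to
i ∈ [−13, −5], the placement range of natural SD motifs. Windows that do
not fit the transcript are *errors*, never silent truncations — a
truncated window would measure a different quantity.

## Folding thermodynamics

### Energy model

The default backend uses a deliberately compact nearest-neighbor
parameterization (`openrds/nnparams.py`), at 37 °C:

* canonical pairs: Watson–Crick and G·U wobble;
* sequence-dependent helix stacking energies (Turner-like magnitudes,
  6×6 table over pair types);
* size-only hairpin, bulge and interior-loop penalties with
  Jacobson–Stockmayer log extrapolation; interior-loop asymmetry penalty
  0.6·|n1−n2| capped at 3.0; interior/bulge loops capped at 30 unpaired nt
  (the cap is part of the model, shared by every code path);
* affine multiloops (closing 3.4, per-branch 0.4, unpaired 0.0 kcal/mol);
* duplex initiation 4.09 kcal/mol for intermolecular hybridization;
* minimum hairpin loop 3 nt; no pseudoknots; **no lonely pairs** (every
  helix ≥ 2 pairs).

No terminal-mismatch, dangling-end or special-loop terms: omitting them
keeps the energy function *exactly* shared between the dynamic program
and the enumeration oracle, which is what makes the oracle-equivalence
guarantee meaningful. The temperature parameter enters only through RT in
Boltzmann weights; the tabulated energies are 37 °C free energies.

The no-lonely-pair convention (as in `RNAfold --noLP`) is a deliberate
design choice: isolated single pairs are both thermodynamically marginal
and an artifact magnet — any start codon carries a U, so with lonely
pairs admitted no construct could ever have an exactly zero opening
profile, and the package's "unstructured" baseline would be noise rather
than zero.

### Partition function

`openrds/fold.py` implements an exact McCaskill-style partition function
(numba-compiled) with the no-lonely-pair rule handled by a two-matrix
split: `qb[i,j]` assumes pair (i,j) is supported by an enclosing stack;
`qs[i,j]` requires (i,j) to stack inward. Exterior loop, interior loops
and multiloop branches all recurse through `qs`, so every helix has ≥ 2
pairs, exactly. Hard single-strandedness constraints remove a base from
the pairable set, giving constrained ensembles (the RNAup-style
accessibility quantity) without approximation. Windowed-average
("RNAplfold-style") genome profiling is replaced by exact constrained
folding on bounded start contexts — the identical quantity at desk scale.

The partition function is unscaled float64; sequences are bounded at
250 nt (overflow raises a clear error). All package use cases — construct
transcripts and genome start contexts of ~60–150 nt — sit well inside the
bound. Backends memoize folds per (sequence, constraint), which is what
makes 100-seed annealing runs cheap: the toy instance has only 64 distinct
states.

### The enumeration oracle

`openrds/enumeration.py` enumerates *every* secondary structure of a
≤ 25-nt sequence (independent interval recursion, lonely-pair filter
applied post hoc), scores each by explicit loop decomposition with the
shared parameters, and Boltzmann-sums the ensemble. It shares parameters
with the backend but no recursions; agreement within 1e-6 kcal/mol on
random sequences is the backend's correctness check, and in practice
agreement is at machine precision (~1e-15).

ViennaRNA (Python bindings) is wired in as the `reference-engine`
backend for users who want the full Turner model; it is cross-checked
qualitatively (orderings, signs) but is never the oracle — its dangles,
special loops and parameter smoothing make 1e-6 agreement with an
external enumeration unattainable and uninformative.

## Simulated annealing

The optimizer minimizes ΔE_open of the window at the construct's SD
offset over synonymous single-nucleotide substitutions in a codon region
(default codons 1–10: the canonical window reaches ~7 codons into the
coding region; 10 gives headroom; codon 0 is immutable). Moves are drawn
uniformly from the exhaustive single-swap synonymous neighborhood of the
*current* sequence, so multi-step wobble paths are reachable over the
walk. Acceptance is Metropolis (downhill always, uphill with
exp(−ΔE/t)); cooling is geometric with t: 1.0 → 10⁻³, factor 0.95, 20
proposals per temperature, capped at 2000 proposals. The schedule is a
package choice — small instances converge in seconds and reach the exact
brute-force optimum in ≥ 95/100 seeds (in practice 100/100 on the bundled
toy gene). The best-ever state is returned, making the result robust to
the schedule's tail; stop-codon creation and start-codon changes are
excluded at proposal time rather than penalized. Identical inputs and
seed give a bit-identical result.

`brute_force_optimum` enumerates all synonymous codon *combinations* in
the region (guarded at 10⁵ states; ties broken lexicographically) — a
superset of single-swap-reachable sequences for split codon families
(e.g. Ser UCN/AGY), which is the correct direction for an oracle: the
annealer can never beat it.

## Synthetic fixtures: what they do and do not show

All test data is generated programmatically (`openrds/fixtures.py`), each
fixture with a manifest of machine-checkable expectations:

* *unstructured* — purine-only filler (alphabet {A, G} plus the start
  codon's single U): no helix of length ≥ 2 exists, so the opening
  profile is identically zero. This is the exact-zero baseline.
* *hairpin-over-rds* — a strong stem looping over the start codon
  (opened by every scanned window) plus two 2-pair marker helices whose
  in-window arms end exactly at the canonical window's edges, so
  ΔE_open(i) peaks strictly at i = −11. The marker geometry exploits the
  no-lonely-pair collapse: touching either pair of a 2-pair helix opens
  all of it.
* *stem-ladder* (stems 0/4/8) — identical UTR filler and SD; ΔE_open
  strictly increases and δ strictly decreases with stem length.
* *toy-gene* — six two-fold (wobble U↔C) codons paired against a
  complementary UTR segment: 64 synonymous states, exhaustively
  enumerable, with the optimum reachable by single-nt toggles.
* *mini-genome* — FASTA + GFF3 text with the same start contexts
  embedded on both strands of two contigs (strand-extraction oracle:
  plus- and minus-strand records must be identical).

These fixtures demonstrate correctness of the machinery — window
accounting, constraint handling, optimizer convergence, strand handling —
under a controlled energy model. They do not demonstrate that the
simplified parameterization reproduces wet-lab expression rankings of
real constructs: real transcripts have dangles, tetraloops, tertiary
context and kinetics the model omits, and validating against expression
data requires the actual construct sequences and an experimental
readout. The qualitative claims carried by the fixtures (deeper RDS
occlusion ⇒ lower δ; synonymous redesign can melt the RDS) are
model-robust and also hold under the ViennaRNA backend.

## Numerical choices and degenerate inputs

* Opening energies are clamped to 0 within −1e-9 (float rounding); more
  negative values raise, since they would indicate a backend bug.
* Profile minima break exact ties toward the canonical offset, then
  upstream; brute-force ties break lexicographically; ranking ties keep
  input order (stable sort).
* Empty sequences, ambiguity codes, out-of-bounds windows, unknown start
  codons, unknown config keys are all hard errors at the boundary.
* Terminal stop codons are tolerated on coding sequences and stripped
  with a flag at translation (an 855-bp gene may or may not include its
  stop in the count; both readings work).
* Sequence-length guards: 25 nt (enumeration), 60 nt (duplex strands),
  250 nt (partition function).

## Problem sizes

Default verification sizes, chosen so the whole suite runs in well under
a minute of compute after JIT warm-up: 200 random sequences of 5–20 nt
for oracle equivalence; 100 annealing seeds on the 64-state toy gene;
10⁴ Metropolis trials; 9-offset scans on ~55–70-nt transcripts; a
4-gene mini-genome. Larger inputs (real genomes via
`profile-genome`, longer constructs up to the 250-nt fold bound) are
supported but not part of the default suite.

## Known limitations

* The simplified energy model ranks and localizes structure correctly
  but its absolute kcal/mol values are not Turner-2004 accurate; use the
  `reference-engine` backend when absolute comparability with ViennaRNA
  outputs matters.
* Equilibrium-only: no co-transcriptional folding, no kinetics, no
  RNA–protein interactions, no standby-site or spacing-penalty terms.
* One CDS start per feature group in genome profiling; programmed
  frameshifts and downstream segments of joined CDS are ignored.
* The partition function is unscaled (250-nt bound); whole-transcript
  folding of long mRNAs is out of scope by design — the quantity of
  interest lives in a bounded start context.
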