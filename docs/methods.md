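# Methods

This note documents the models behind `fyvescan`, the defaults that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices a maintainer would want explained.

## Scaffold model

The FYVE fold binds two Zn²⁺ ions through eight cysteines arranged in four
pairs (pairs 1+3 share one ion, 2+4 the other). On sequence alone we model
this as a spacing envelope (`ScaffoldConfig`):

| parameter | default | meaning |
|---|---|---|
| `intra_pair_gap` | 1–4 | residues strictly between the two cysteines of a pair |
| `inter_pair_gap` | 4–30 | residues strictly between adjacent pairs |
| `max_span` | 90 | first-to-last cysteine span |
| `anchor_cys_index` | 5 | which cysteine must carry the central motif's C |
| `anchor_pair_tolerance` | 0 | slack on that index, in pairs |

The envelope brackets the EEA1/Vps27p-like folds without hard-coding one
family member; every admissible eight-tuple is enumerated and overlapping
alternatives resolve leftmost-longest, which makes detection deterministic.
The central-motif anchor is the start of the four-residue HHCR/HNCY core,
placed so that the core's cysteine **is** the fifth scaffold cysteine in
linear order. Published descriptions number the motif-bearing cysteines
differently depending on the pairing convention; anchoring on the
linear-order fifth cysteine is this package's convention, and the tolerance
knob exists precisely because that convention is not universal.

Classification is deliberately anchored: a `(R/K)HHCR` or `(K/R)(R/K)HNCY`
core only counts when its cysteine coincides with an allowed scaffold
cysteine. That single constraint eliminates essentially all spurious core
matches on random sequence. The leading arginine of the classic central
motif is optional (recorded as the `missing-first-arg` flag) because one
family subgroup genuinely lacks it; requiring it would misclassify those
domains as atypical. `WxxD`/`WxxG` and the class-V accessory motif are
reported but never required — N-terminal anchors degenerate to a lone
glycine, or to nothing recognizable, in part of the family.

## Regions

* **Turret loop** — the `turret_window` (default 6) residues immediately
  N-terminal to the central motif, clipped at the domain start. Six covers
  the known single-residue insertions in the family without swallowing the
  preceding cysteine pair.
* **Dimerization interface** — 10 residues beginning 2 positions C-terminal
  of the `WxxD`/`WxxG` anchor's end. The offsets mirror the EEA1-defined
  dimer region and are configuration, not a structural claim; absence of an
  N-terminal anchor yields no interface and a `no-nterm-anchor` flag.
* Hydropathy uses the Kyte–Doolittle scale (pluggable); `X` placeholders
  are excluded from every mean and count.

## RCC1 blade detection

A blade is scored against a profile of seven anchors — four glycines, a
tyrosine, a leucine, a proline — placed at fractional offsets
(0.10 G, 0.25 Y, 0.35 G, 0.50 L, 0.60 G, 0.75 P, 0.85 G) of the blade
length, each matched within a ±2-residue window; the anchor score is the
fraction matched. Candidate windows over the canonical 51–68-residue period
are chained by dynamic programming (consecutive starts one period apart,
no overlap), maximizing total score, then blade count; remaining ties go to
the chain with the smallest total anchor displacement from the canonical
offsets (the best-registered reading) and then the leftmost chain. The ±5
`boundary_slack` is an input-validation allowance for ragged terminal
blades, not a proposal range.

The anchor offsets are a calibration of this package, not published
constants. The window width is the load-bearing choice: the glycine anchors
sit roughly a quarter blade (~14 residues) apart, so windows wider than
about ±3 overlap and a single stray glycine starts satisfying several
anchors at once. At ±2 an anchor matches uniform-random sequence with
probability ≈0.23 and the measured false-positive rate for ≥3-blade chains
on 400-residue uniform-random sequences is 4.4 % (44/1000 fixed seeds,
regression-tested); at ±6 the per-anchor probability rises to ≈0.49 and
the same measurement gives 79 %, i.e. no specificity at all. Defaults:
`min_score` 0.6 (≥5 of 7 anchors), `min_blades` 3 — recall-oriented, with
the false-positive rate measured rather than assumed.

`first_blade_check` examines the window one period upstream of a detected
array: no room → `canonical` (the array opens the chain, as in a complete
propeller); partial but sub-threshold blade character → `degenerate-first`;
no anchor signal at all → `open-ring-candidate`. This is a sequence-level
flag for the molecular-clasp/open-ring alternatives; no 3D inference is
made.

## Net charge

Charge is a sum of independent Henderson–Hasselbalch terms — basic groups
contribute +1/(1+10^(pH−pKa)), acidic groups −1/(1+10^(pKa−pH)) — with an
EMBOSS-like pKa set (D 3.65, E 4.25, H 6.0, C 8.3, Y 10.07, K 10.53,
R 12.48; termini 8.6/3.6, off by default since the modeled domains are
excised fragments). The two structural Zn²⁺ ions add +2 each. The eight
scaffold cysteines default to `coordinated_neutral` (contribute 0); the
`thiolate` (−1 each) and `free` (titrating) alternatives are one flag away
because the protonation state of zinc-bound thiols in continuum-
electrostatics models is genuinely ambiguous. Default pH is 6.5, the regime
where the EEA1 domain is predominantly binding-competent.

This proxy ignores site–site coupling and the dielectric environment, so it
does **not** reproduce Poisson–Boltzmann totals computed on structures;
only orderings and trends across domains should be compared, and no
acceptance value is pinned to structure-derived charges. Note one exact
consequence of the model worth remembering when testing limits: arginine
(pKa 12.48) still carries ≈+0.037 at pH 13.9.

## Contact consensus

A residue is a consensus interactor for a headgroup when it appears in at
least `ceil(threshold × n_runs)` of that headgroup's runs — with the
conventional 0.5 threshold over six runs, three or more times; the ceiling
keeps "50 % or more" literal for odd run counts. Headgroups aggregate
separately by default (rigid and flexible scenarios pooled; a flag splits
them). Coordinate mode calls a residue in contact when any heavy atom lies
within 4.0 Å of a ligand heavy atom — a contact definition, distinct from
any docking-grid energy cutoff, and itself a flag. Consensus is provably
sandwiched between run intersection and union and monotone in the
threshold; both properties are tested.

## Synthetic data: what it emulates, what it does not

The generator emits proteins whose FYVE domains instantiate the full motif
layout of their class (classic: WxxD … interface … C-pairs … turret …
R(R/K)HHCR … R(V/I)C; variant: WxxG … AxxAP interface … turret with the
conserved F/R … (K/R)(R/K)HNCY … accessory … (L/F/P)YR), embedded in the
five architecture layouts (I FYVE+Fab1_TCP+PIPKc, II FYVE+DUF500, III/IV
lone N-/C-terminal FYVE, V PH_PLC + blade array + FYVE, with DZC on seven
of nine class V proteins). Defaults encode the study conditions: census
2/2/1/1/9, six 57-residue blades per class V array, six docking runs per
headgroup.

Identifiability choices, all deliberate:

* Template filler avoids cysteine (scaffold arity is the controlled
  variable) and tryptophan (the N-terminal anchor stays unique); blade
  filler avoids the anchor residues so a clean blade scores exactly 1.0.
* Each zero-mutation skeleton is **verified** — scaffold, motif class,
  architecture and blade count must all recover the recorded truth — and
  deterministically resampled otherwise, so the zero-noise recovery theorem
  holds by construction.
* Mutations draw positions and target residues once per seed, independent
  of the rate, so mutation sets are nested across rates and recovery
  ladders are monotone by construction; substitutions never produce
  cysteine and never touch the eight cysteines or the central core (the
  separate `corrupt_core` mode builds the six-cysteine decoys).
* Contact noise drops each true contact with probability `contact_noise`
  and, with the same probability, adds one decoy residue per run.

Consequently, passing tests demonstrate the *logic* of the pipeline —
detection, classification, chaining, aggregation and their equivalence with
independent oracles — not its performance on real proteomes: real domains
have ragged motif spacing, real blades have shifted anchors (the ±2 window
is tight for them), real backgrounds are not uniform, and real contact
noise is not symmetric. The curated Arabidopsis architecture table ships
with placeholder coordinates (ids and domain order are curated; residue
numbers are plausible inventions), which is sufficient for architecture
rules and census work but not for sequence lookups.

## Degenerate inputs and numerical conventions

All external coordinates are 1-based inclusive; the two converters to
0-based half-open slices are the only crossing points and are tested in
both directions. Empty FASTA files parse to empty collections; empty
regions make hydropathy undefined (an error, not a 0). `X` is tolerated in
sequences but excluded from charge and hydropathy sums; B/Z/U are rejected
so titration stays well-defined. Scaffold alternatives under one leftmost-
longest winner are logged, not silently dropped. The architecture rules are
a pure function of the annotation multiset and N→C order; rule ties (which
the five rules cannot produce among themselves) would report UNCLASSIFIED
with a warning rather than guess. Which lone-FYVE class is the N-terminal
one is a package convention (midpoint in the N-terminal half → III),
exposed as `fyve_n_terminal_label`.

## Problem sizes

The shipped tests run the full property suite at desk scale by choice:
200 seeded proteins for the zero-noise recovery theorem, 1000 fixed seeds
for the blade false-positive regression, 500 seeds for the contact-noise
Jaccard regression (frozen estimate 0.986), 150 hypothesis cases for the
scan-vs-oracle equivalence. The whole suite completes in well under a
minute on one CPU.

## Known limitations

* No profile-HMM scoring, no multiple-sequence alignment, no homology
  modeling, no Poisson–Boltzmann electrostatics, no docking — the package
  post-processes sequences and contact lists only.
* The blade anchor offsets/windows are calibrated for discriminative power
  on synthetic arrays; applying the detector to real propeller proteins
  will likely need a wider window or recalibrated offsets (both are
  configuration).
* The misannotation filter is exactly as strong as the scaffold envelope:
  a real FYVE domain with unusual cysteine spacing would be rejected, and
  the envelope should be widened deliberately rather than the filter
  trusted blindly.
* Insertion codes in PDB residue numbering are unsupported; the first model
  of a multi-model structure is used.
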