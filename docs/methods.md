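# Methods

`crossbeta` implements the computational arm of a peptide design campaign
whose goal is short (7-mer) peptides that self-assemble into *parallel*
β-sheet nanofibrils — the Class-1 cross-β spine packing, in which strands
within each of the two stacked sheets run parallel while the two sheets face
each other antiparallel. The pipeline has four stages: scaffold
construction, Monte Carlo sequence design, coarse-grained aggregation
simulation, and structure analytics (simulation metrics plus FTIR β-index
classification of experimental-style spectra).

## Scaffolds

Scaffolds are idealized extended β-strands (φ ≈ −120°, ψ ≈ +120° territory,
realized as a 3.4 Å per-residue rise) laid out on a regular lattice: strand
axis x, in-sheet stacking y at `d_strand` = 5.5 Å, sheet normal z at
`d_sheet` = 12 Å. Backbone atoms N, Cα, C, O are represented; carbonyl
oxygens alternate ±y so that successive residues hydrogen-bond to the two
flanking strands, as in a real β-sheet ladder. The Cα pleat is zero-mean so
the mean Cα planes of the two sheets sit exactly `d_sheet` apart.
Antiparallel strands are built by a 180° rotation about the sheet normal
plus a 0.5 Å axial shift chosen so the reversed ladder still forms
H-bonds under the analytics criterion.

We deliberately use geometric construction rather than force-field-relaxed
coordinates: the design stage only needs a plausible *fixed* backbone, and a
deterministic builder doubles as an exact fixture generator for the
analytics tests. Replication of a scaffold unit applies a rigid transform
cumulatively and rejects any configuration with inter-atom distances below
1.0 Å (a floor that catches construction errors without forbidding tight
steric-zipper interfaces). Replicated copies are bookkept as fresh sheets.

## Scoring

The design objective is

```
Γ_score = ΔG_binding − λ · P_aggregation
```

* `ΔG_binding`: binding energy of a *test chain* (the chain with the most
  inter-chain contacts) with all neighbors. It sums a 20×20 residue-pair
  contact table over side-chain pseudo-centroid pairs within 6.5 Å, plus a
  constant −0.5 per backbone H-bond of the test chain (N–O distance ≤
  4.5 Å), plus terminal-charge interactions (+1 amine / −1 carboxylate,
  ±0.25 per unit charge product within the cutoff) that vanish when the
  termini are acetylated/amidated. Side-chain pseudo-centroids sit 2.0 Å
  from Cα along the local pleat normal (computed from backbone geometry, so
  the energy is rigid-motion invariant). With this geometry and cutoff,
  binding is dominated by in-sheet neighbor contacts and backbone H-bonds;
  the 12 Å cross-sheet interface does not contribute, which we accept for a
  residue-level model.
* `P_aggregation`: an additive per-residue scale, shipped as a data file —
  normalized Kyte–Doolittle hydropathy with an aromatic bonus, zero-centered
  (so λ·P can be negative for charge-rich sequences).
* `λ` (default 2.0; the campaign used 2.0 and 3.0) balances the two terms.

The shipped contact table uses geometric-mean mixing of a hydropathy-derived
hydrophobic strength, ±0.25 per unit side-chain charge product, and −0.10
for polar–polar pairs. All energies are dimensionless score units; the
published absolute ΔG/P values (which come from an atomistic force field
defined elsewhere) are *not* reproduced, by design — only the score-identity
Γ = ΔG − λP and the algorithmic contracts are.

## Monte Carlo design

Sequences evolve on a fixed scaffold under a composition constraint
("hydration case": counts of hydrophobic / polar / charged / other
residues; Case 1 = 5/0/2/0 and Case 2 = 5/2/0/0 for 7-mers). Two moves,
chosen 50/50 per step, act on all chains at once: within-class mutation of
one residue (the replacement is drawn uniformly over the class and may
redraw the incumbent — the simplest unbiased draw) and unconstrained
exchange of two positions. Both conserve the case by construction. Trial
moves are accepted with Metropolis probability min(1, exp(−ΔΓ/T_seq)); the
sequence temperature is not part of the published description, so we default
to T_seq = 1.0 score unit, which gives order-unity acceptance on the shipped
potential. The default run is 10,000 steps; top-k reporting takes the
lowest-Γ distinct sequences over the whole trace, ties broken by earlier
step.

## Coarse-grained event-driven dynamics

Each residue maps to four spheres — NH, CαH, CO united atoms and one
side-chain bead R (glycine keeps a small hydrogen-sized R bead so all chains
share the 4-beads-per-residue topology). Interactions are discontinuous:

* hard cores (additive diameters),
* infinite-well bonds: each bonded or pseudo-bonded pair reflects
  elastically at ±`bond_tolerance` (default 2.375%) of its nominal length,
* square wells: backbone H-bond wells between inter-chain NH–CO pairs
  (depth ε₀ = 1 by definition, outer radius 4.5 Å) and side-chain R–R wells
  (depth from a 20×20 table, outer radius 1.5× contact diameter).

The chain template is a colinear backbone (NH–CαH–CO along the strand axis)
with R beads alternating ± perpendicular; pseudo-bonds are generated
automatically between every intra-chain bead pair whose template distance is
within its contact diameter + 1 Å, which enforces backbone geometry and
keeps chains near-extended. Two simplifications follow and are intentional:
the dispersed starting state is an unassembled monomer gas of near-extended
chains rather than a true random coil, and intra-chain H-bonds are excluded
(7-mers in this model cannot hairpin). Side-chain wells use hydrophobic
geometric-mean mixing only; screened electrostatics are omitted from the
shipped set (high-ionic-strength limit). Geometric-mean mixing makes
in-register, like-above-like stacking — i.e. parallel β-sheets — the
energetically preferred arrangement for hydrophobically driven sequences,
which is the physics the campaign exploits.

Units are reduced: length Å, mass amu, energy ε₀, time τ = Å·√(amu/ε₀).
Laboratory temperature maps through `energy_scale_K` = ε₀/k_B = 1000 K, so
the 296–310 K window corresponds to kT = 0.296–0.310 ε₀, inside the
fibrillization regime of the shipped parameter set. The Andersen thermostat
redraws a random bead's velocity from the Maxwell–Boltzmann distribution at
rate 0.1 per bead per τ (default).

The engine is a standard event-driven loop: per-bead earliest-event
scheduling on a binary heap with collision counters for lazy invalidation;
ballistic free flight with per-bead update times; exact impulse rules for
cores, well capture/escape (with reflection when radial kinetic energy is
insufficient), and bond-window reflections, so total energy is conserved to
round-off with the thermostat off. Pair prediction is vectorized over all
partners and JIT-compiled; for the ≤ ~1400-bead systems used here this is
faster and simpler than a cell-list stencil. Periodic boundaries use the
minimum image; a scheduling horizon of box/(8·v_max) bounds prediction
extrapolation so the image branch cannot change under a scheduled event, and
the schedule is rebuilt at each horizon.

PRIME20-style numeric constants are not published in a form this package
could adopt verbatim; the shipped bead diameters, masses, bond lengths and
well depths are nominal, physically reasonable values (flagged as such in
the data-file headers). The file format and engine semantics, not the
numeric fidelity of prior force-field publications, are the contract.

## Fibril metrics

A backbone H-bond is an NH–CO bead pair within 4.5 Å (matched to the H-bond
well range and to the scaffold geometry; the published work does not print
its criterion, so ours is declared, configurable, and used consistently for
both CG frames and scaffold fixtures). Two chains form a *strand pair* when
their mutual H-bond participants form a ladder — participants at most two
residues apart, at least 3 participants on each chain; the gap-2 rule
reflects the intrinsic donor/acceptor alternation of sheet ladders.

* β-sheet content: % of residues spanned by qualifying ladders.
* % parallel content: computed over H-bonded strand *pairs* (not residues);
  a pair is parallel when the dot product of the two chains' end-to-end
  Cα vectors is positive. Frames with no pairs report a sentinel (None),
  not 0%, so kinetics averages are not biased.
* Aggregates: connected components of the chain contact graph (minimum bead
  distance ≤ 13 Å, which bridges the 12 Å sheet stacking of backbone-only
  scaffolds). Layers = strand-pair-graph components with ≥ 2 chains inside
  the largest aggregate.

All metrics are deterministic functions of a frame and invariant under
rigid motion and periodic rewrapping.

## FTIR analysis

Amide-I spectra (1600–1700 cm⁻¹) are baseline-flattened (straight line
through the mean absorbance of two anchor windows, 1590–1605 and
1710–1725 cm⁻¹ by default), smoothed (Savitzky–Golay, window 9, order 3),
and fit with a Gaussian mixture (least squares; initial centers from
detected maxima padded with the canonical component positions 1628 / 1642 /
1665 / 1695 cm⁻¹). The β-index is the fitted *height* ratio of the
1693–1697 cm⁻¹ peak to the 1624–1632 cm⁻¹ main β-sheet peak (height, not
area, following the original intensity-ratio definition), 0 when no
high-frequency component is present. Calls: index < 0.1 → parallel;
index ≥ 0.1 → antiparallel (the boundary itself reads as antiparallel,
taking "under 0.1" strictly). Group comparisons use a one-tailed two-sample
t-test, Welch's variant by default. A seeded synthetic-spectrum generator
(Gaussians + linear baseline + noise on a 1 cm⁻¹ grid) provides
parallel/antiparallel presets for round-trip validation.

## Workflow and problem sizes

`run_round` wires the stages together: design per (case, λ), a temperature
screen at {296, 303, 310} K, an extended run at the temperature with the
highest final β-content (the "highest fibrillization propensity" criterion,
operationalized as max β-content since no quantitative rule is published),
and classification: *predominantly parallel* (final parallel fraction
≥ 50%), *mixed* (< 50%), or *low fibril content* (final β-content < 20%;
this threshold is ours). `refine_scaffold` drapes the best
predominantly-parallel sequence onto a 16-chain capped Class-1 scaffold to
seed the next round.

The paper-scale simulation profile (48 peptides, 200 Å box ≈ 10 mM,
microsecond-equivalent durations) is supported by the engine but is a
long-running computation. The package's desk-scale profile — used by the
test suite and documented as its own choice — is 12 chains in an 80 Å box
(≈ 34 mM, trading concentration for encounter kinetics), bond tolerance
widened to 7.5%, durations of a few thousand τ, and fixed seeds. At this
scale the attractive parameter set reproducibly assembles PP3 (GAIDWVK)
into predominantly parallel sheets at the best of the three screening
temperatures, and a purely repulsive control stays a monomer gas; only this
classification-level behavior, not any quantitative fibril statistic, is
claimed. The mapping from reduced time to the microsecond labels of
experimental-scale reports is nominal and not calibrated.

## Known limitations

* The contact potential and aggregation scale are this package's own
  parameterizations; designed sequences will differ from those found with
  atomistic binding energies, and published absolute score components are
  out of scope.
* Near-extended chains cannot model coil↔strand conversion kinetics, lag
  phases, or hairpins; aggregation kinetics here reflect diffusion and
  docking only.
* One H-bond well per NH–CO pair without valence bookkeeping allows mild
  over-coordination of donors/acceptors in dense clusters.
* The scoring stage ignores the cross-sheet steric-zipper interface
  (side-chain centroids of opposing sheets sit beyond the contact cutoff).
* Synthetic FTIR spectra share the fitted model's functional form; passing
  round trips validates the pipeline's algebra and noise robustness, not
  its behavior on instrument artifacts (sloping non-linear baselines,
  overlapping non-Gaussian bands).
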