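# Methods

This note records the models, conventions and design decisions behind
`efsam`, in the spirit of a methods appendix: what each component assumes,
which knobs matter, and what the synthetic tests do and do not demonstrate.

## Coordinates, numbering, units

Structures are multi-model PDB files (read and written through biotite)
holding ordered same-topology coordinate sets — NMR models or MD snapshots.
Author numbering is the single public numbering; the recombinant EF-SAM
construct spans UniProt residues 58–201 plus a six-residue expression tag
numbered −5..0 (150 residues total, which `SubdomainMap.construct_length`
checks). Tag residues are parsed but excluded from all default segments,
since they are disordered and conventionally left out of fluctuation
analyses. Insertion codes are rejected; alternate locations resolve to the
highest occupancy (ties to the first encountered). Internally everything is
in Å; RMSD, RMSF, Rg and SASA are reported in nm to match the field's plots,
pair distances (d₁, d₂) in Å because the physically meaningful differences
are Å-scale (a binding-loop expansion of ≈ 12 Å).

The default subdomain map pins the segments that the analyses name: the
binding loop Leu74–Ser88, δ1 = 73–88 (16 residues), δ2 = 95–115,
δ3 = 171–184, the global fit range Ser64–Leu199, the probe Phe108, the α10
anchors Leu192/195/199 and the chelators Asp76, Asp78, Asn80, Asp82, Asp84,
Glu87. Individual helix boundaries (α1..α10) are not uniquely published for
this construct; the defaults are chosen consistent with those anchored
facts and are fully overridable from a YAML config.

## Geometric order parameters

Superposition is the closed-form Kabsch/SVD solution with a determinant
correction to exclude reflections; fits with fewer than three or collinear
atoms raise. RMSD and RMSF are unweighted over the selected atoms (the
common Cα convention); Rg is mass-weighted, with masses looked up from the
element. RMSF is computed per atom about its time-average position after
superposition and then averaged within each residue; a "local" fit mode
superposes on one segment only, so that hinge-like motion of the remainder
is not absorbed by the global fit. Contact maps store the minimum
heavy-atom distance per residue pair; hydrophobic contacts use a 4.5 Å
minimum heavy-atom cutoff (the standard side-chain contact convention —
the analyses this reimplements name no cutoff), excluding sequence
neighbours.

## Solvent accessibility and exposure states

SASA is Shrake–Rupley sphere-point rejection over heavy atoms with a
1.4 Å probe and a deterministic golden-section spiral of 960 points — no
randomness, so repeated calls are bit-identical; 960 vs 4000 points changes
the calibration value by < 2 %. The van der Waals radii are a pinned
Chothia-class table (C 1.87, N 1.65, O 1.40, S 1.85, P 1.90, Ca 1.97 Å).
Radii-set choice shifts whole-residue values by roughly ±0.2 nm², which is
why the calibration target — the central Phe of a fully extended
Gly-Phe-Gly tripeptide, ≈ 2.2 nm² — carries a ±0.3 nm² tolerance. Built at
(φ, ψ) = (−120°, 120°), our fixture gives 2.216 nm². Per-residue SASA sums
all of the residue's atoms including backbone, matching whole-residue
reporting of that literature anchor.

Exposure of the probe residue partitions its whole-residue SASA into
buried (< 0.25 nm²), surface-adsorbed (0.25–1 nm², both boundaries
included, per the closed printed interval), and fully exposed (> 1 nm²).

## Secondary structure

Assignment follows the DSSP convention. Amide hydrogens are reconstructed
1.01 Å from N, anti-parallel to the preceding residue's C=O (standard
practice for H-less models); chains are split wherever C(i)–N(i+1) exceeds
2.5 Å, and chain-start residues donate no hydrogen bond. Backbone hydrogen
bonds are scored with the Kabsch–Sander electrostatic energy
E = 0.084·332·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN) kcal/mol and accepted
below −0.5 kcal/mol. Helix (H) requires two consecutive i→i+4 turns;
strand (E) is detected from minimal bridge patterns but is unused by the
pipeline, whose reaction coordinate is α-helical content f_H only. On a
suite of generated helix/strand/coil structures the assignment agrees with
mdtraj's DSSP implementation residue-for-residue (the acceptance bound is
≥ 95 %).

## Folded-state rules and clustering

The per-subdomain folded calls quantify the qualitative criteria used to
dissect unfolding profiles of the full construct:

- hEF folded ⇔ f_H(α3) ≥ 0.7 and f_H(α4) ≥ 0.7, probe SASA ≤ 0.25 nm²
  (reusing the buried threshold), and at least one heavy-atom contact
  ≤ 4.5 Å between the probe and an α10 anchor leucine;
- cEF folded ⇔ f_H(α1) ≥ 0.7 and f_H(α2) ≥ 0.7, d₁ ≤ d₁(reference) + 4 Å
  (expansions that distinguish states are ≈ 12 Å, so 4 Å separates them
  with margin), and some anchor residue contacting both an α1 and an α2
  residue within 4.5 Å (α10 docked in the EF-hand cleft);
- SAM folded ⇔ f_H(SAM) ≥ 0.7 (helicity alone suffices for the stable
  domain).

All four thresholds live in `StateCriteria` and are configurable; a
subdomain's flag is the conjunction of its sub-verdicts, which are reported
individually. Conformational clustering is Daura leader-style
neighbour-counting under a Cα RMSD cutoff of 0.2 nm (the conventional
default of that algorithm family; ties break to the lowest model index for
determinism). "Median conformation" is interpreted as the cluster medoid —
the member minimising summed RMSD to its cluster — and, when classifying
through clusters, the medoid's verdict is attributed to every member, so
cluster sizes weight the folded percentages.

## Corresponding-states thermal profiles

A REST2 replica with solute scaling λ at bath temperature T_ref is treated,
by the law of corresponding states, as the solute at T_eff = T_ref/λ. The
ladder is geometric, λ_k = λ_min^(k/(n−1)) with n = 30 and λ_min = 0.6 by
default (endpoints exact), which keeps neighbouring T_eff ratios constant.
Schedules span 280 ns with only the last 80 ns entering each curve point
(both configurable); each curve point is the mean ± s.e.m. of the retained
per-frame observable of one replica. The melting model is a two-state
van 't Hoff sigmoid with constant folded/unfolded baselines — the minimal
identifiable model for 30-point curves; fits are bounded (T_m within the
data range ± 20 K, ΔH ∈ [10, 2000] kJ/mol), initialised at the point
nearest the half-transition with ΔH₀ = 150 kJ/mol, and a curve that never
crosses its own midrange (span < 0.2) is rejected as non-identifiable
rather than extrapolated. Absolute T_eff values from solute tempering can
be systematically overestimated; differences between conditions (ΔT_m) are
the robust quantity and are what the pipeline emphasises.

## The synthetic-data generator

The generator provides every input with known ground truth. The toy
protein is not the EF-SAM fold; it is the minimal geometry on which all of
the pipeline's bookkeeping is exercisable: helices α1, α2, α3, α4 and α10
built from ideal internal coordinates at (φ, ψ) = (−57°, −47°), a 14-residue
binding loop carrying the chelator residues (Glu87 with a Cδ atom so d₂ is
defined), and a probe Phe108 on the loop that continues α3, packed so the
ring sits in vdW contact (3.8–4.3 Å) with an α10 anchor while an anchor
leucine simultaneously bridges α1 and α2. Side chains are Cβ-only except
the probe ring and Glu87 — enough for the SASA and contact rules without a
rotamer library. Fragments are placed rigidly, so inter-fragment junctions
are chain breaks (handled by the assignment code); backbone bond lengths
within fragments are exact by construction. The loop dihedrals and fragment
placements were fixed once, by seeded numerical design against the
construction contract (probe buried below 0.25 nm², anchor bridging, d₁
baseline ≈ 9.6 Å, no non-bonded heavy-atom pair under 2 Å), and are pinned
as constants.

Unfolding events are constructed, not simulated: the designated helix is
rebuilt at coil dihedrals drawn uniformly from φ ∈ [−180°, −60°],
ψ ∈ [60°, 180°] (guaranteed non-helical); for hEF the probe ring flips 180°
about Cα–Cβ to an exposed rotamer; for cEF the Glu87 end of the loop
translates along the d₁ axis so the expansion offset (default 12 Å, the
magnitude that distinguishes the Ca²⁺-free state) is added to d₁ exactly;
for SAM the unwound α10 also undocks from the cleft, so the anchor contacts
of both EF-hands are lost by construction and the manifest records those
implied flags. Frames are drawn independently from the two-state
equilibrium p_u(T) = 1/(1 + exp[(ΔH/R)(1/T − 1/T_m)]) with per-subdomain
T_m (defaults 320 K for hEF, 360 K for cEF, 430 K for SAM — ordered as the
observed stability ranking — and ΔH = 200 kJ/mol, typical of a small
helical domain); R = 8.314 J mol⁻¹ K⁻¹ is pinned and temperatures are in K
everywhere.

Positional jitter (default σ = 0.3 Å) is applied after state construction
as a spatially correlated Gaussian displacement field (RBF-smoothed over
the reference geometry, correlation length 6 Å, per-atom marginal std σ).
Thermal fluctuation in a folded protein is locally quasi-rigid; independent
per-atom noise of the same amplitude would stretch covalent bonds and break
backbone hydrogen bonds unphysically, destroying secondary structure that a
real 0.3 Å-RMSF ensemble would retain. With the correlated field the
folded-state criteria retain margin at the default σ, which is what the
generator/classifier contract quantifies (100 % agreement at zero jitter,
≥ 99 % at σ = 0.3 Å over 1000 frames).

Replica datasets default to the analysis schedule: 30 replicas, 280 frames
at 1 ns spacing, of which the last-80-ns rule retains 80 per replica.
"Exact" mode writes per-frame folded indicators drawn from the two-state
model directly (optionally with Gaussian observation noise; an analytic
variant writes the equilibrium fraction itself, so a noiseless curve equals
the model exactly and the fit recovers T_m to machine precision).
"Structures" mode generates toy ensembles per replica and pushes them
through the real classifier — slower, intended for small integration runs.
Everything is seeded and regenerates bit-exactly.

What passing these tests shows — and does not. The synthetic ensembles
validate the machinery: selections, metrics, assignment, classification,
curve assembly and fitting, and end-to-end parameter recovery under known
noise. They do not validate force fields, sampling convergence, the
realism of unfolding pathways, or the biological claims about STIM1; the
toy's unfolded states are geometric constructions, its frames are
uncorrelated in time, and its two-state equilibrium is imposed rather than
emergent.

## System-composition audits

The ion arithmetic reproduces box preparation counts: pairs =
round(c·a³·10⁻²⁴·N_A) with round-half-away-from-zero (the only convention
that robustly reproduces the printed 31 pairs from 30.98 at 150 mM in a
7 nm box), and anion rebalancing keeps the cation count fixed while
restoring electroneutrality after a solute charge change (Ca²⁺ removal:
31 → 29 Cl⁻). The solute's formal charge is taken as input (inferred from
the neutrality identity when omitted) rather than computed from sequence.
The Ca²⁺-site check lists O/N ligands within 3.0 Å and declares pentagonal
bipyramidal geometry iff there are exactly seven ligands with an axial pair
at 180° ± 20° and equatorial neighbours spaced 72° ± 20°; the tolerance was
validated by construction against 0.1 Å-jittered ideal sites.

## Problem sizes

The shipped tests and the acceptance script run everything at desk scale:
≤ 50-atom fixtures for formula-oracle equivalence, a 390-atom toy protein,
ensembles of tens to hundreds of frames, 1000 frames for the classifier
contract, and 50 seeded datasets for the noisy-recovery study. Headline
simulation results from massively parallel REST2 runs are represented by
parameter-recovery properties on synthetic data of matching structure, not
by rerunning the simulations.

## Known limitations

- The toy protein omits α5–α9; SAM helicity is measured on the residues
  present (α10). Segment definitions remain correct for real structures.
- Strand detection is minimal (isolated bridges); π- and 3₁₀-helices are
  not subtyped. Only H matters for f_H.
- Pairwise-RMSD clustering is O(n²) in models and intended for the
  ensemble sizes above.
- The λ→T_eff map is the plain corresponding-states relation; alternative
  conventions can be accommodated by scaling T_ref.
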