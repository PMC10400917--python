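# efsam

Trajectory-ensemble analysis of thermal sensing by the STIM1 EF-SAM domain.

STIM1 is the endoplasmic-reticulum Ca²⁺ sensor that initiates store-operated
Ca²⁺ entry, and it is also activated by moderate heating. Its luminal EF-SAM
unit pairs a canonical, Ca²⁺-binding EF-hand (cEF) with a "hidden",
non-binding EF-hand (hEF) packed against a sterile α-motif (SAM) domain. The
working model this package supports analytically is a modular sensor: hEF is
the thermal element (its unfolding exposes the conserved hydrophobic Phe108
and licenses dimerisation), cEF is the Ca²⁺ element (ion loss triggers a
large expansion of the binding loop), and SAM stabilises both.

`efsam` implements, as a tested and reusable pipeline, the analyses by which
such conclusions are reached from conformational ensembles:

- **Structural order parameters** — Kabsch superposition, RMSD (global or
  local fit), per-residue RMSF, mass-weighted radius of gyration, the
  binding-loop expansion distances d₁ (Asp76 Cα–Glu87 Cα) and d₂ (Asn80
  Cα–Glu87 Cδ), and minimum heavy-atom contact maps.
- **Exposure states** — Shrake–Rupley SASA with the three-state partition
  for the Phe108 probe: buried (< 0.25 nm²), surface-adsorbed (0.25–1 nm²),
  fully exposed (> 1 nm²).
- **Secondary structure** — DSSP-convention assignment from Kabsch–Sander
  backbone hydrogen-bond energies; α-helical fraction f_H as the reaction
  coordinate.
- **Folded-state calls** — Daura leader clustering with medoid
  representatives and rule-based folded/unfolded classification of cEF, hEF
  and SAM (helicity of the flanking helices, probe burial and anchoring,
  binding-loop expansion, α10 docking between α1 and α2).
- **Thermal profiles** — replica-exchange-with-solute-tempering (REST2)
  corresponding-states analysis: a geometric λ ladder, the conversion
  T_eff = T_ref/λ, per-replica unfolding curves, and two-state van 't Hoff
  fits

  f(T) = b_u + (b_f − b_u) / (1 + exp[(ΔH/R)(1/T_m − 1/T)]),

  yielding T_m, ΔH and condition differences ΔT_m.
- **Synthetic ensembles** — a generator producing every input with known
  ground truth: a toy multi-helix protein with EF-SAM's bookkeeping (author
  numbering, chelator loop, buried Phe probe, Leu anchors on α10),
  controllable unfolding events, and per-replica observable tables drawn
  from a two-state equilibrium across the λ ladder.

It also audits simulation-system composition: counter-ion counts for a
150 mM KCl box (41 K⁺/31 Cl⁻ at 7 nm) and the electroneutral rebalancing
after Ca²⁺ removal (29 Cl⁻), plus a pentagonal-bipyramid check for the
Ca²⁺ coordination shell.

## Worked example

Two synthetic REST2 datasets emulate a Ca²⁺-loaded (HOLO) and a Ca²⁺-free
(APO) condition whose hEF melting temperatures differ by a constructed 39 K:

```python
import efsam as E
from efsam import synth

holo = synth.GeneratorConfig(seed=1, tm_true={"hEF": 359.0, "cEF": 360.0, "SAM": 430.0})
apo  = synth.GeneratorConfig(seed=2, tm_true={"hEF": 320.0, "cEF": 360.0, "SAM": 430.0})

fits = {}
for name, cfg in [("HOLO", holo), ("APO", apo)]:
    table, _ = synth.make_replica_dataset(cfg, "hEF", mode="exact", noise_sigma=0.05)
    curve = E.build_curve(table, cfg.ladder(), condition=name, subdomain="hEF")
    fits[name] = E.fit_two_state(curve)

ref = synth.build_toy_protein()
```

This prints (formatting elided):

```
HOLO: Tm = 358.8 K, dH = 215 kJ/mol (baselines 1.00/-0.00)
APO: Tm = 320.8 K, dH = 186 kJ/mol (baselines 0.99/0.00)
delta Tm (HOLO - APO) = 38.0 K
probe Phe108 SASA in folded reference: 0.143 nm^2 -> buried
d1 baseline: 9.61 A
```

The per-replica tables span a 280 ns schedule of which only the last 80 ns
enter each curve point; the fitted T_m values recover the configured ground
truth, and their difference recovers the constructed 39 K stability shift
within the sampling noise. The folded toy reference keeps its probe buried
(0.143 nm², below the 0.25 nm² threshold) and its binding loop compact
(d₁ ≈ 9.6 Å); unfolding events raise the probe SASA above 1 nm² and add the
configured offset (default 12 Å) to d₁.

A thin CLI mirrors the library (`efsam audit ions`, `efsam inspect map`,
`efsam metrics run`, `efsam surface run`, `efsam ss run`, `efsam state
classify`, `efsam melt build|fit|compare`, `efsam synth make`).

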