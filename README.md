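# fibrilkit

Stability metrics and receptor selection for cross-β amyloid fibril
trajectories.

Small molecules that destabilize amyloid-β (Aβ42) fibrils are candidate
leads against Alzheimer's disease. Molecular-dynamics studies of
ligand–fibril complexes judge a compound's effect on a stacked, S-shaped
Aβ42 pentamer by a small set of trajectory readouts. `fibrilkit` implements
that analysis layer as a tested Python library and CLI, for structural
bioinformaticians who want the metrics without re-deriving them from a
simulation package:

- **β-sheet structure probability** — per-frame fraction of residues in
  β structure, assigned by the Kabsch–Sander hydrogen-bond model
  (electrostatic energy `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)`
  kcal/mol, bond iff `E < −0.5`, bridge/ladder rules for E/B codes).
- **Order parameter (ordP)** — for chain *c* and residue *n*, the unit
  connecting vector **v**(c,n;t) from the chain's Cα centroid to the
  residue's Cα; `ordP(t) = ⟨ v(c,n;0) · v(c,n;t) ⟩_{c,n}`, averaged over the
  analysis window. 1 means the starting orientation of every chain is
  preserved; lower values mean structural disorder.
- **Inter-chain interaction area** — per adjacent chain pair in the stack,
  the buried solvent-accessible surface
  `½·[SASA(A) + SASA(B) − SASA(A∪B)]` (Shrake–Rupley, deterministic
  Fibonacci quadrature), with a cutoff-based heavy-atom contact count
  reported alongside.
- **Ligand contact probability** — per residue identity (chains pooled),
  the fraction of bound frames with any ligand heavy atom within 0.35 nm,
  with bound-frame masking for ligands that leave the site.
- **Receptor selection** — single-linkage clustering of trailing-window
  frames at a 0.1 nm RMSD cutoff; the most populated cluster's centroid
  (minimum mean RMSD member) is written out as the docking receptor.

A synthetic cross-β generator builds idealized S-meander pentamers
(residues 11–42, 0.48 nm stacking rise, working inter-chain hydrogen-bond
registry) and seeded distortion trajectories for three mechanistic regimes
— inter-chain detachment, pocket distortion, and growing melt — so the
entire pipeline runs and is testable without any MD engine or external
data.

## Worked example

```bash
fibrilkit demo demo_out --seed 0
```

generates one 50 ns-equivalent trajectory (200 frames, 0.25 ns/frame) per
regime, analyzes the trailing 25 ns of each, and prints:

```
        system  beta_percent_mean  beta_percent_sd  ordp_mean  interchain_area_mean_nm2  ...
        stable           81.19375         0.251480   0.999432                 26.727939
          melt           16.98750         4.733838   0.945190                 44.004526
        detach           66.21250         3.357385   0.918620                 21.779937
pocket_distort           57.05000         7.117913   0.984149                 24.474861
```

Read it as a mechanism fingerprint. The stable baseline keeps ~81% β
content and ordP ≈ 1. The melt run loses most of its β structure and
orientation order. The detach run loses exactly one chain's worth of β
content and the whole terminal-pair interface (lowest interaction area).
Pocket distortion selectively melts the pocket-lining strand (β drops by
roughly a third) while the stack's interface survives. Per-frame metrics,
summary and contact-map CSVs for each system are written under
`demo_out/<regime>/`, every file headed by the exact configuration used.

Library use mirrors the CLI:

```python
from fibrilkit import FibrilSpec, build_ideal_fibril, make_trajectory, \
    regime_spec, summarize_complex

fibril = build_ideal_fibril(FibrilSpec())
traj = make_trajectory(fibril, regime_spec("detach", seed=1))
report = summarize_complex(traj, window_ns=25.0)
print(report.beta_percent, report.ordp.mean, report.area.mean)
```

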