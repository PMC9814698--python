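# peptraj

Trajectory post-processing for peptide–methyltransferase systems:
hairpin-state classification, S<sub>N</sub>2 transition-state-like geometry
detection, pooled conformational clustering, residue-contact profiling,
steered-association force expressions, and a two-state FRET melt model —
with an in-package synthetic-trajectory generator so every stage is
testable without running molecular dynamics.

## The scientific problem

SETD2 methylates lysine 36 of histone H3, and a designed 15-mer
"super-substrate" peptide (ssK36, differing from the natural H3K36 peptide
at four positions: A31R, T32F, K37R, H39N) is methylated about 100-fold
faster.  The mechanistic explanation rests on a handful of trajectory
analyses that this package implements as a reusable, tested library:

- **Hairpin classifier** — a frame is a hairpin iff the stem-loop distance
  (G33 Cα–P38 Cα) < 7 Å *and* the end-to-end distance (A29 Cα–P43 Cα)
  < 15 Å.  Run-length analysis of the per-frame flags gives hairpin
  lifetimes.
- **S<sub>N</sub>2 TS-like detector** — a complex frame is
  catalytically competent iff d(Lys Nε, methyl C) < 4 Å, the attack angle
  Cδ–Nε···C is within 109° ± 30°, and the Nε···C–S angle is within
  180° ± 30°.  Events are maximal runs of TS-like frames; long-lived
  events persist ≥ 8 consecutive frames (160 ps at 20 ps writes).
- **k-hybrid clustering** — conformers from both peptides are pooled and
  partitioned by pairwise Kabsch-superposed backbone (N, Cα, C) RMSD:
  farthest-point (k-centers) seeding followed by k-medoids refinement.
  Each cluster is summarised by its medoid structure and per-condition
  composition, with subset-robustness and per-run enrichment t-tests.
- **Contact profiling** — residue pairs are in contact when any two heavy
  atoms are closer than 4.5 Å (two sequence neighbours excluded within a
  chain); profiles are per-pair contact fractions, differenced between
  conditions with an "over 35 %" reporting filter, optionally conditioned
  on TS-like frames.
- **Steered association** — the biasing forces as analytic
  energy/force functions: a pulling force of magnitude 0.5·d (kJ/mol/Å)
  between the lysine amine COM and the cofactor methyl COM, and a
  repulsive force of magnitude 0.3·d separating the peptide termini;
  unfolding is tracked as backbone RMSD to an extended reference versus
  the N–C distance up to the minimum-RMSD frame.
- **Two-state FRET model** — fluorescence of a donor/quencher-labelled
  peptide melting from hairpin (H) to unfolded (U):
  I(T) = scale · [f_H (1−E(r_H)) + (1−f_H)(1−E(r_U))] with
  E(r) = R₀⁶/(R₀⁶ + r⁶), R₀ = 33 Å, and
  f_H = K/(1+K), K = exp(−(ΔH°′ − TΔS°′)/RT).  Least-squares fitting with
  bootstrap confidence intervals recovers ΔH°′, ΔS°′ and the scale.

## Worked example

```python
import numpy as np
from peptraj.synthetic import ComplexSpec, generate_complex_ensemble
from peptraj.detectors import ts_counts, event_table, fold_enrichment

designed, _ = generate_complex_ensemble(
    ComplexSpec(n_replicates=8, n_frames=1000, ts_occupancy=0.22, seed=3))
natural, _ = generate_complex_ensemble(
    ComplexSpec(n_replicates=8, n_frames=1000, ts_occupancy=0.06, seed=4,
                condition_label="H3K36"))

for label, trajs in [("designed", designed), ("natural", natural)]:
    s = ts_counts(trajs)
    long = event_table(trajs, min_len=8)
    print(f"{label}: mean {s.mean:.1f} TS frames/replicate "
          f"(SEM {s.sem:.1f}), {len(long)} long events")
print("fold:", fold_enrichment(ts_counts(designed).mean,
                               ts_counts(natural).mean))
```

```
designed: mean 214.2 TS frames/replicate (SEM 6.6), 51 long events
natural: mean 62.0 TS frames/replicate (SEM 5.6), 17 long events
fold: 3.5
```

The designed-substrate ensemble (planted TS occupancy 0.22 versus 0.06)
yields a 3.5-fold excess of TS-like frames and an excess of long-lived
(≥ 8-frame) TS events — the summary statistics the library computes on
real complex trajectories.

The same API runs on files: `peptraj simulate` writes multi-model PDB
ensembles plus label tables, and `peptraj hairpin-scan / ts-scan /
cluster / contacts / association / fret / report` are thin CLI wrappers
over the corresponding modules.

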