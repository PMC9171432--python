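# mechanoct

Time-lapse micro-CT mechano-regulation analysis of bone healing and
remodeling.

During fracture healing and bone adaptation, where bone forms and where it
is resorbed is thought to follow the local mechanical environment: surfaces
under high strain add bone, surfaces under low strain lose it (Frost's
"mechanostat"). `mechanoct` turns that question into a reproducible
computation for anyone with registered longitudinal micro-CT data: from a
series of mineral-density volumes (mg HA/cm³) and the applied loads, it

1. pre-filters (Gaussian, σ = 1.2, support 1 voxel) and bins each image
   into density bands (395–720 mg HA/cm³ in steps of 25);
2. masks the cortical, medullary and peripheral regions from the baseline
   scan (cortex threshold 645 mg HA/cm³, ray-cast cavity recovery);
3. solves a voxel-based linear-elastic micro-FE model (one hexahedral
   element per voxel; soft tissue 0.003 GPa, medullary cap plate 20 GPa)
   under 1 % axial compression and 1 % edge bending, rescales each solution
   by the ratio of applied to resultant load, and superposes the
   displacement fields to get per-voxel strain energy density `U` and
   effective strain `ε = √(2U/E)`;
4. classifies every voxel between consecutive time points as formation,
   quiescence or resorption by the binary difference of the bone masks, and
   flags quiescent voxels whose density band rose as mineralization;
5. relates events on the bone surface to the normalized effective strain at
   the interval's start, via conditional probability curves
   `p(F/Q/R | ε̄)`, ROC AUC (0.5 = no association), and a two-threshold
   correct-classification-rate sweep whose balanced chance level is 33 %.

Because no imaging dataset is bundled, the package includes a synthetic
longitudinal phantom — a hollow cortical cylinder with a transverse defect
whose weekly formation/resorption events are sampled from a *known*
monotone mechanostat — so every stage, including the full statistics, can
be validated against an exact ground-truth event log.

## Worked example

Simulate a small noise-free phantom for four weekly scans, classify the
remodeling events, and fit the mechano-regulation model:

```python
import pandas as pd
import mechanoct as mc

spec = mc.PhantomSpec(
    grid_shape=(20, 20, 20), cortex_outer_radius=8.0, cortex_inner_radius=5.5,
    defect_height=4, n_timepoints=4, noise_sd=0.0, seed=11,
)
images, log = mc.simulate_healing(spec, mc.surrogate_strain_provider())
masks = mc.make_region_masks(images[0])

tables = []
for t in range(len(images) - 1):
    prev = mc.bin_to_bands(images[t])
    curr = mc.bin_to_bands(images[t + 1])
    remodel = mc.classify_remodeling(prev, curr)
    strain = mc.surrogate_strain_provider()(images[t])
    tables.append(mc.build_event_table(strain, remodel, masks, prev, interval=(t, t + 1)))

events = pd.concat(tables, ignore_index=True)
results = mc.MechanoregulationModel(events).fit()
print(results.summary())
```

```
Mechano-regulation summary
============================================================
surface voxels: 9838
event rates: formation 26.5%, quiescence 73.1%, resorption 0.4%
AUC (formation): 0.829 +/- 0.005 (n_pos=2607, n_neg=7231; 0.5 = no association)
AUC (mineralization): 0.641 +/- 0.008 (n_pos=2190, n_neg=2557; 0.5 = no association)
max CCR: 73.4% at thresholds (lower=0.242, upper=0.394); chance level 33.3%
```

Reading the numbers: strain at the start of each interval classifies the
following week's formation sites far better than chance (AUC 0.83 against
the no-association level of 0.5), mineralization of existing bone is also
strain-associated (AUC 0.64), and the best two-threshold strain rule
assigns formation/quiescence/resorption with a balanced accuracy of 73 %
against a 33 % chance level — the phantom's generative mechanostat is
recovered by the analysis. (This example uses the fast geometric strain
surrogate; `mc.run_subject` runs the same analysis with the real micro-FE
solver.)

The same pipeline runs from the shell:

```bash
mechanoct fixture --size tiny --out fixture --seed 1   # phantom dataset on disk
mechanoct run --config fixture/config.yaml             # filter→FE→events→stats
mechanoct stats --events fixture/surface_events.csv    # summary to stdout
mechanoct plot --run-dir fixture                       # curves, ROC, CCR heatmap
```

## Documentation

`docs/methods.md` describes the model, its assumptions, every tunable
parameter with units and defaults, what the phantom does and does not
emulate, and the package's numerical conventions.
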