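# aieclust

Forward simulation and quantification of **proximity-gated
aggregation-induced-emission (AIE) readouts of membrane receptor
clustering**, built for benchmarking the analysis chain of
cluster-disruption experiments (e.g. HER2 clusters on breast-cancer cells
responding to an anti-HER2 antibody such as Trastuzumab).

## The problem

HER2 and similar receptors organise into nanoscale clusters on the cell
membrane, and therapeutics can dissolve those clusters without changing the
total receptor count. An AIE dye (a tetraphenylethylene conjugated to an
anti-HER2 antibody) only emits when a second labelled fluorophore sits
within a fixed distance window — 2.13–6.62 nm — so its widefield intensity
reports receptor *proximity*, while a conventional dye on the same antibody
reports receptor *amount*. Real experiments of this kind can only be
validated qualitatively because the raw images are rarely distributed. This
package provides the missing synthetic ground truth: a generative model of
the whole experiment, plus the exact quantification chain used on real
images, so every analysis step can be tested against a known world.

## What is modelled

- **Receptor fields** — clustered organisation as a Thomas point process
  (Poisson cluster centres, Poisson offspring with Gaussian scatter σ_c)
  or complete spatial randomness for low-expression cells, inside
  irregular polygonal cell footprints, with a hard-core separation h.
- **Cluster disruption** — each clustered receptor is relocated uniformly
  (count-conserving) with probability
  `p(D, t) = p_max · (1 − e^{−t/τ}) · D^n / (D^n + EC50^n)`.
- **Emission** — AIE rule: a labelled fluorophore is emissive iff another
  labelled fluorophore lies at distance d ∈ [d_min, d_max]; the
  conventional dye is emissive unconditionally.
- **Imaging** — emitters binned to pixels, Gaussian PSF, constant
  background, Poisson shot noise, Gaussian read noise.
- **Quantification** — edge-detection ROI (smooth → Sobel gradient →
  threshold → closing → fill → size filter), masked mean intensity
  (Σ pixels / area), SNR = (μ_fg − μ_bg)/σ_bg, Pearson colocalization and
  2D intensity histograms, dose–response normalization to untreated
  controls with Welch-test significance stars, and hinge-regression onset
  detection.

## Worked example

```python
from aieclust import ExperimentConfig, run_experiment

cfg = ExperimentConfig(doses=(0.0, 1.0, 100.0), times=(24.0,), replicates=3,
                       cells_per_well=25, master_seed=1)
print(run_experiment(cfg).table.to_string(index=False))
```

```
cell_model          dye  dose  time  n  mean_norm  sd_norm  p_value stars
 clustered          AIE   0.0  24.0  3   1.000000 0.039154 1.000000
 clustered          AIE   1.0  24.0  3   0.538690 0.031363 0.000124    **
 clustered          AIE 100.0  24.0  3   0.278992 0.006749 0.000727    **
 clustered conventional   0.0  24.0  3   1.000000 0.036207 1.000000
 clustered conventional   1.0  24.0  3   0.993316 0.030751 0.819745
 clustered conventional 100.0  24.0  3   0.983566 0.011917 0.520825
```

The AIE channel collapses with dose (0.54 at the EC50, 0.28 at 100 µg/mL,
both highly significant) because disruption destroys fluorophore proximity,
while the conventional channel stays at ~1.0: receptor count is conserved,
so a proximity-insensitive dye sees nothing. That two-channel contrast is
the sensor's defining signature.

The same pipeline is scriptable from a shell:

```bash
aieclust chem dar --mass-shift 1015 --dye-mass 749   # -> 1.35
aieclust chem stokes --absorption 354 --emission 518 # -> 164
aieclust simulate-experiment --config docs/example_config.yaml --seed 1 --out-dir results/
aieclust quantify --images 'results/*.tif' --out quant.csv
aieclust coloc --a chA.tif --b chB.tif --out coloc.csv
aieclust make-fixtures --out-dir fixtures/ --seed 0
```

## Acceptance script

`scripts/acceptance.py` re-runs the full simulated plate experiment from
scratch for a given seed — receptor sampling through dose–response tables —
and writes its JSON report plus `wells.csv` / `doseresponse.csv` next to it:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/aieclust/synthetic_membrane.py` — footprints, point processes, disruption
- `src/aieclust/aie_optics.py` — emission rules and image formation
- `src/aieclust/quantify.py` — segmentation, mean intensity, SNR
- `src/aieclust/coloc_stats.py` — Pearson colocalization, 2D histograms
- `src/aieclust/dose_response.py` — normalization, stats, onset, `run_experiment`
- `src/aieclust/chem_utils.py` — DAR and Stokes-shift arithmetic
- `src/aieclust/config.py`, `io.py`, `fixtures.py`, `cli.py` — config schema,
  TIFF I/O, deterministic fixtures, CLI

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
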