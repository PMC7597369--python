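# holotrack

Analysis of two-color live-cell single-molecule tracking (SMT) experiments on
the DNA polymerase δ (Pol δ) – PCNA holoenzyme: how the sliding clamp and the
polymerase assemble on and disassemble from genomic DNA in living nuclei.

In these experiments a SNAP-tagged Pol δ catalytic subunit and a Halo-tagged
PCNA are imaged in alternating channels (~1.34 s per channel, 512×512 px at
84 nm/px, ~22 min per nucleus). Chromatin-bound molecules appear as
diffraction-limited spots; each spot tracked over consecutive frames is one
genomic binding event. The package covers the full analysis chain, plus a
ground-truth simulator so every stage is verifiable by parameter recovery:

- **simulate** — two-channel binding events with a two-population exponential
  residence mixture, colocalized Pol δ/PCNA pairs with a configurable
  arrival/departure order distribution, spatial binding hubs with a
  three-component revisit-latency mixture, sparse labeling, photobleaching,
  localization noise and blinking; optional rendering to 16-bit TIFF movies.
- **tracking** — 2D Gaussian PSF localization, diffusion-gated track linking
  (gating radius `r_max(Δt) = √(4·D·Δt)` with `D = 0.05 µm²/s`, gap closing up
  to 5 s), nuclear-ROI filtering, binding-event projection maps, and
  photobleach-rate estimation from the global bound-signal decay.
- **colocalization** — a Pol δ track lasting > 1.34 s colocalizes with a PCNA
  track when their bound intervals overlap on the interleaved clock and their
  time-averaged positions are within 47 nm; events are classified by which
  molecule arrives first and which departs first (± one frame interval counts
  as simultaneous), with bootstrap uncertainties, an assembly/disassembly
  pathway (quadrant) table, and a positional-randomization null.
- **kinetics** — residence-time survival curves (1 − CDF) fitted with
  exponential mixtures `S(t) = Σ fᵢ·exp(−t/τᵢ)` (k = 1–3). The short-lived
  population (T₁, < 1.7 s) and stable population (T₂, > 1.7 s) are reported
  per cell; model order is selected by corrected AIC. Rank-based two-group
  comparison (Kruskal–Wallis) is included.
- **hubs** — binding-event maps expanded 10-fold (8.4 nm pixels) and raster
  scanned with a 168 nm octagon window; pixels whose window holds ≥ 3 events
  seed hubs (8-connected components). Reported per cell as hubs per 1,000
  binding events, with revisit latencies (time between consecutive visits)
  pooled for mixture fitting.
- **pipeline / CLI** — `holotrack simulate|track|coloc|kinetics|hubs|report`
  orchestrate the stages and emit a JSON report, CSV tables and SVG figures.

## Worked example

Simulate three nuclei at the default imaging conditions and analyze them end
to end:

```python
import holotrack as ht

cfg = ht.RunConfig(
    mode="full", n_cells=3, seed=7, outdir="example_out",
    params=ht.AnalysisParams(n_randomizations=2),
)
report = ht.run_pipeline(cfg)
```

Printing the headline quantities of that run gives:

```
colocalization frequency: 0.89% of 1565 Pol delta tracks
randomized-position null: 0.000%
PCNA arrives first in 85.7% +/- 9.0% of events
Pol delta departs first in 92.9% +/- 6.7%
stable residence T2 = 10.1 s (27% of binding events)
hubs per 1,000 long-lived events: 41.6
```

Reading the numbers: about 1% of the qualifying Pol δ tracks sit within 47 nm
of a concurrently bound PCNA track, far above the ~0% chance level obtained by
re-drawing the same tracks' positions uniformly over the nucleus — so the
pairs are genuine complexes, not coincidence. Among those complexes the clamp
usually loads before the polymerase arrives and outlives it after it leaves,
the ordered assembly/disassembly pathway. The stable binding population lives
~10 s here rather than the generating 12.4 s because photobleaching (τ ≈ 99 s
for the Pol δ dye) competes with unbinding; `ht.bleach_corrected_tau(10.1,
99.3)` inverts the rate sum back to ~11–12 s. The per-event uncertainty is
large with only three simulated nuclei (28 colocalization events); the
acceptance script below runs the same computations at larger n.

The same run from the shell:

```sh
holotrack report --mode full --n-cells 3 --seed 7 --randomize 2 --out example_out
```

writes `report.json`, `coloc_events.csv`, `hubs.csv`, `hub_latencies.csv`,
`residence_per_cell.csv`, the resolved configuration, and SVG figures.

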