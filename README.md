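# nodetrans

Quantification of *in vivo* axonal transport of organelles at the node of
Ranvier (NoR), built for time-lapse tracking data of peripheral motor axons:
retrogradely transported signaling endosomes and bidirectionally moving
mitochondria imaged around the nodal constriction. The package provides

- **track_io** — CSV and TrackMate-XML track ingest, and projection of 2D
  spots onto an axon centerline to obtain the node-centred signed axial
  coordinate *s* (μm, + = distal / toward the muscle);
- **kinematics** — frame-to-frame speeds, pause detection, terminal-pause
  trimming, track qualification, 2 μm binning over an 80 μm window, and
  subdomain summaries (proximal internode 38 μm / nodal constriction 4 μm /
  distal internode 38 μm), plus speed–diameter Pearson correlation;
- **flux_direction** — mitochondrial directionality labels, distinct-organelle
  counts per subdomain × direction, per-minute flux, length statistics
  (stationary vs motile);
- **intensity_profile** — background subtraction, relative-fluorescence
  normalisation, mirrored proximal/distal comparison and distal peak metrics
  of 80 μm line profiles;
- **morphometry** — hierarchical summaries of manual diameter/length tables
  and a half-depth nodal-constriction detector for diameter profiles;
- **synthetic_data** — a stochastic generator of tracks, fluorescence
  profiles and diameter profiles with named presets and full ground truth,
  so that every analysis stage is verifiable by parameter recovery;
- **report / CLI** — end-to-end pipelines, axon→animal aggregation, and the
  `nodetrans` command line.

## The quantities at the core

For consecutive spots of one track, the step speed is
`v_i = ‖(x,y)_{i+1} − (x,y)_i‖ / Δt`. A **pause** is a step with
`v ≤ 0.1 μm/s` of a previously motile organelle; runs of ≥10 consecutive
pause steps touching a track end (**terminal pauses**) are discarded, and a
track qualifies only if it moves for ≥10 consecutive frames. Per location
(2 μm bin or subdomain):

- **mean moving velocity** `v̄ = mean{ v_i : not pause, s_mid,i ∈ location }`
- **relative pause frequency** `pf = #pauses / #steps` within the location.

Nodal effects are reported as percent differences, e.g. the nodal slowdown
`100 × (1 − v̄_node / v̄_proximal)`. Mitochondrial **flux** is the number of
distinct moving mitochondria per direction per subdomain, × 60 / video
duration (s). Fluorescence accumulation is measured on background-subtracted
profiles normalised to whole-window mean 1: the distal peak over the
proximal-internode mean is ≈1.5 when the distal juxtaparanodal cluster holds
~50% more signal. The nodal constriction length is the full width of the
diameter dip at half depth.

## Worked example

```python
from nodetrans import synthetic_data as syn
from nodetrans import report as rpt

ds = syn.simulate_tracks(syn.make_config("endosome_paper", seed=1))
res = rpt.run_kinematics_pipeline(ds.tracks, ds.geometry)
print(res.summary.round(3).to_string())
for k, v in rpt.percent_metrics(res.summary).items():
    print(f"{k}: {v:.1f}%")
```

prints

```
           n_steps  n_pauses  n_moving  mean_moving_velocity  pause_relative_frequency
subdomain
proximal      7566       281      7285                 2.390                     0.037
center        1501       466      1035                 1.307                     0.310
distal        3622       349      3273                 2.108                     0.096
slowdown_node_vs_proximal: 45.3%
slowdown_node_vs_distal: 38.0%
proximal_excess_vs_distal: 13.3%
pause_reduction_proximal: 88.0%
pause_reduction_distal: 69.0%
```

i.e. endosomes transit the proximal internode at ~2.4 μm/s, slow to
~1.3 μm/s inside the nodal constriction while pausing ~8× more often, and
re-accelerate distally — recovering the regional parameters programmed into
the `endosome_paper` preset (2.40 / 1.25 / 2.10 μm/s; pause probabilities
0.042 / 0.30 / 0.099).

The same flow works from the shell:

```
nodetrans simulate --preset endosome_paper --seed 1 --out sim/
nodetrans kinematics --tracks sim/tracks.csv --geometry sim/geometry.yaml --out kin/
nodetrans report --kinematics-dir kin/ --out rep/
```

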