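# plinet

EEG functional brain networks from the Phase Lag Index, weighted
small-world graph measures, and longitudinal two-group trial statistics.

## The problem

In Alzheimer's disease, loss of synapses disturbs communication between
brain regions, and the large-scale organisation of scalp-EEG activity is
thought to drift from a small-world architecture (high local clustering,
short global paths) toward a random one. Longitudinal intervention
trials therefore read out *network organisation* rather than raw signal
power: per subject and visit, a connectivity network is inferred from
multichannel EEG, summarized by two graph measures, and the per-arm
trajectories of those measures are compared with a mixed model.

`plinet` implements that whole chain for 10-20-montage clinical EEG:

1. **Preprocessing** — ASCII/EDF reading, average reference, zero-phase
   band-pass (delta/theta/alpha/beta), deterministic artifact screening,
   four 4096-sample epochs per recording.
2. **Connectivity** — the Phase Lag Index between all channel pairs,

       PLI = | < sign(sin(Δφ(t))) >_t |,  sign(0) = 0,

   with instantaneous phase from the Hilbert transform. PLI ignores
   zero-lag (volume-conducted) correlation by construction.
3. **Network measures** — mean weighted clustering C_w, weighted
   shortest path length L_w (edge length 1/w, Dijkstra), normalized
   against 50 weight-shuffled surrogate networks:
   γ = C_w / ⟨C_w-random⟩, λ = L_w / ⟨L_w-random⟩.
4. **Trial statistics** — REML mixed model for repeated measures on the
   post-baseline visits with group × visit fixed effects, baseline and
   sample-rate covariates, random intercepts for (pooled) site and for
   subject; a 2-df trajectory contrast, a week-24 endpoint contrast, and
   the intraclass correlation; plus quadratic memory-association probes.
5. **Synthetic data** — coupled-oscillator signals on weighted
   Watts–Strogatz topologies and an outcome-level trial generator, so
   every stage is testable without any clinical data.

The implementation is sklearn-shaped: `AverageReference`,
`BandpassFilter`, `EpochSelector`, `PhaseLagIndex` are transformers,
`SmallWorldMetrics` and `TrajectoryMMRM` are estimators with fitted
attributes (`gamma_`, `trajectory_p_`, ...), and module-level functions
wrap them for one-off use.

## Worked example

Simulate a small trial in which the control arm's coupling topology
degrades across visits (rewiring 0.1 → 0.3 → 0.6) while the active
arm's stays small-world, then run the full pipeline on it:

```bash
plinet simulate --out trial --seed 3 --subjects-per-arm 4 --channels 8 --epochs 2
cat > config.yaml <<EOF
manifest: trial/manifest.csv
output_dir: run1
n_epochs: 2
surrogates: 50
seed: 11
bands:
  - {name: beta, low: 13, high: 25}
stats: {pool_min_n: 1}
EOF
plinet run -c config.yaml
```

which prints `run complete: 2 analyses, 0 failures -> run1` and writes
`run1/summary.md` containing, for this seed:

```
## ITT / beta / gamma

| group | baseline | wk12 | wk24 |
|---|---|---|---|
| active | 1.112 (0.120) [4] | 1.160 (0.055) [4] | 1.068 (0.058) [4] |
| control | 1.056 (0.138) [4] | 1.030 (0.108) [4] | 0.914 (0.066) [4] |

trajectory p = 0.0917; endpoint p = 0.0415
```

Each cell is mean (SD) [n] of the normalized clustering coefficient γ in
the beta band: even at 4 subjects per arm the control arm's γ falls from
1.056 to 0.914 over 24 weeks while the active arm's stays near its
baseline, and the week-24 endpoint contrast is already nominally
significant. `run1/measures.csv` holds the per-recording C_w, L_w, γ, λ
(per epoch and epoch-averaged), and `run1/provenance.json` the seeds and
epoch offsets that make the run bit-reproducible.

The statistics also run standalone on any tidy longitudinal table:

```bash
plinet simulate --out sim --seed 2 --outcomes-only
plinet stats --in sim/longitudinal.csv
```

returns the fitted trajectory F, endpoint t, ICC and variance
components as JSON.

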