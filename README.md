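# tempocode

Quantify how pharmacological perturbations alter the stimulus-response
specificity of signaling dynamics.

`tempocode` simulates grids of nuclear-activity trajectories (15 stimulus
conditions x single-drug and pairwise-combination dose regimes) with a
bundled minimal negative-feedback ODE model, reduces the trajectories to
comparison feature spaces — six interpretable dynamic features ("signaling
codons"), non-negative canonical polyadic decomposition (CPD) component
weights, and functional-PCA scores — clusters the stimulus conditions of each
regime with an epsilon network, and reports per-regime specificity (SRS),
confusion (SRC) and inhibition (INH) scores plus stimulus confusion maps and
cross-regime confusion tallies.

## Layout

| module | role |
| --- | --- |
| `tempocode.sim_engine` | dose ladders, drug regimes, ligand forcing curves, the bundled 5-state core model, grid simulation, and a waveform generator with closed-form expected features (test oracle) |
| `tempocode.codons` | the six dynamic features (speed, peak, duration, AUC, early-vs-late, oscillatory band power), non-responder handling, min-max normalization |
| `tempocode.embeddings` | per-drug tensor normalization, non-negative CPD (HALS, best-of-restarts, R2X), area-rescaled temporal patterns and component weights, quadrature fPCA, feature matrices |
| `tempocode.clustering` | epsilon-network clustering, misclustering rate under optimal cluster alignment, epsilon calibration against expert partitions |
| `tempocode.scoring` | SRS/SRC/INH scorecards, binary confusion matrices, pairwise confusion tallies, treated-vs-untreated comparison |
| `tempocode.cli_io` | JSON config schema + validation, CSV/JSON readers and writers, pipeline orchestration with a run manifest, the `tempocode` CLI |

The model is pluggable: any callable `(params, input_fn, grid) -> values`
can replace the bundled simulator, so a full published parameterization can
be substituted behind the same interface.

## CLI

```bash
# full pipeline: simulate -> featurize -> calibrate epsilon -> score -> tally
tempocode run --out results/run

# or stage by stage
tempocode simulate --config cfg.json --out traj.csv [--combinations dd5,dd10]
tempocode featurize --traj traj.csv --threshold 0.05 --cutoff 0.05 --out codons.csv
tempocode embed --traj traj.csv --space cpd --rank 7 --seed 0 --restarts 5 --out cpd7/
tempocode calibrate-epsilon --features codons_norm.csv --expert 'expert/*.json' --out eps.json
tempocode score --features codons_norm.csv --eps eps.json --out scores/
tempocode robustness --features codons_norm.csv --eps eps.json --scores scores/ --out tally.csv
tempocode report --scores scores/scores.csv --out maps.png
```

Exit codes: 0 success, 2 configuration error, 3 stage error. A JSON config
may override any section (`grid`, `model`, `ligands`, `compounds`, `ladder`,
`analysis`); every omitted key takes the bundled default (481-point 1-minute
grid over 0-480 min, 20-step dose ladder from 10^-0.15 to 10^-3, cutoff 0.05).
Unknown keys and out-of-range values are rejected with their key paths.

Expert partitions for epsilon calibration are plain JSON
(`{"elements": [...], "clusters": [[...], ...], "nonresponder_cluster": i}`);
fixtures matching the bundled model's five calibration regimes ship in
`tempocode.data`.

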