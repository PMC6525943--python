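# ilmvu

Feature extraction and evaluation for two-class motor-imagery EEG (left vs.
right hand), built around three ingredients:

1. a 1-D **dual-tree complex wavelet transform** (DTCWT) that splits each
   C3/C4 trial into dyadic subbands (δ, θ, α, β, γ at 128 Hz with four
   levels) with perfect reconstruction and near shift invariance;
2. **ERD/ERS energy features**: sliding-window normalized subband energies
   whose C3−C4 difference captures the contralateral event-related
   desynchronization of the μ (8–13 Hz) and β (13–30 Hz) rhythms,
   `F1 = [AE_α, AE_β]`;
3. **landmark maximum variance unfolding (L-MVU)** with an **incremental
   out-of-sample extension**: the samplewise C3−C4 subband difference over
   the selected time block is a high-dimensional vector per trial; L-MVU
   learns a `d`-dimensional embedding `F2` by solving the semidefinite
   program

   ```
   maximize    trace(Q L Qᵀ)
   subject to  (QLQᵀ)ii − 2(QLQᵀ)ij + (QLQᵀ)jj ≤ ‖xi − xj‖²  for ηij = 1
               Σij (QLQᵀ)ij = 0,    L ⪰ 0
   ```

   over the m×m landmark kernel `L`, where `Q` propagates landmark
   coordinates to all samples through locally-linear-reconstruction weights
   `W` (rows sum to one over each sample's `r` nearest neighbors) and `η` is
   the symmetrized k-nearest-neighbor graph.  Landmark coordinates are
   `√λ_k v_k` from the eigendecomposition of `L`.  A *new* trial is embedded
   without touching the SDP: its `w` nearest training samples are found, the
   same sum-to-one reconstruction is solved, and the weights are applied to
   the stored embedding — `y_new = Σ_j IW_j y_j`.

Fused features `F = [100·F1 ; F2]` are classified with two-class LDA and
evaluated by stratified 10-fold cross-validation, Cohen's kappa, and a
pooled-variance two-sample t-test.

A built-in synthetic generator produces two-class MI-EEG (1/f background,
band-limited μ/β rhythms at C3/Cz/C4, cue-locked contralateral ERD and
ipsilateral ERS) so the whole chain is testable without any recordings.
External data can be supplied in the same plain-text format (one
trials×samples CSV per channel plus a JSON sidecar).

## Worked example

```python
import ilmvu

# 200 synthetic trials; "left" imagery attenuates C4 mu/beta power to 0.3x
ts = ilmvu.generate_trials(ilmvu.SimConfig(n_trials=200, erd_factor=0.3,
                                           rng_seed=1))
res = ilmvu.cross_validate(ts, ilmvu.PipelineConfig(), folds=10, seed=1)
print(f"mean accuracy {res.mean_accuracy:.1f}%  kappa {res.kappa:.2f}")
print(res.details[0]["waves"], res.details[0]["time_block_s"])
```

prints

```
mean accuracy 99.5%  kappa 0.99
['alpha'] [3.0, 6.9921875]
```

The pipeline found the planted effect on its own: every fold selected the α
subband and a 4 s analysis window inside the 3–7 s cue interval, and the
fused features separate the classes almost perfectly.  With
`erd_factor=1.0` (no planted effect) the same call returns accuracy near
50% — the chance-level control.

The same workflow is available from the shell:

```sh
ilmvu simulate --trials 200 --erd 0.3 --seed 1 --out data/
ilmvu evaluate --data data/ --folds 10 --seed 1 --out report.json
```

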