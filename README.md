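# speechtrack

Neural tracking of audiovisual cocktail-party speech: temporal response
functions (TRFs), speech-envelope reconstruction (SER), attention
metrics, representational similarity analysis (RSA), and EEG–fMRI
fusion — with a synthetic-data generator that provides ground truth
for every analysis.

## The scientific problem

When two speech streams overlap, selective attention enhances the
cortical tracking of the attended stream. `speechtrack` implements the
analysis chain used to quantify this with EEG and to localize it with
fMRI, for a 2×2×2×2 within-subject design (Attentional Task ×
Semantic Coherence × Auditory Quality × Visual Quality, 16 conditions)
in which listeners either attend an audiovisual dialogue or ignore all
speech while a background audiobook plays throughout. It is intended
for cognitive-neuroscience researchers analysing continuous-speech
EEG/fMRI experiments of this kind, or prototyping such analyses on
simulated data.

The core quantities:

* **Forward TRF** — per EEG channel, the lagged ridge-regression
  kernel `w = argmin ‖r − S w‖² + λ‖w‖²` mapping the speech amplitude
  envelope `S` (lags −200…800 ms, λ = 10⁵, 128 Hz) to the channel
  response `r`; conceptually an ERP to a continuous regressor.
* **Backward model (SER)** — the same machinery run in reverse: the
  envelope at time *t* is predicted from all channels over
  *t*…*t*+200 ms (λ = 10⁴, 64 Hz), trained leave-one-trial-out.
* **Δr** — the tracking statistic: Pearson correlation of a stream's
  held-out reconstruction with its own envelope minus the correlation
  with the opposite stream's envelope, per 6.5 s line and per quarter
  segment; temporal profiles across the 7 lines and 4 segments are
  tested with orthogonal polynomial contrasts and sign-flip
  permutation t-tests (20,000 permutations, exhaustive when feasible).
* **RDMs** — 16×16 condition dissimilarity matrices: `1 − r(Spearman)`
  of the across-channel TRF vectors at each of 100 time points
  (0–800 ms), and pairwise leave-one-run-out linear-SVM decoding
  accuracies for fMRI ROIs.
* **TRF–fMRI fusion** — partial Spearman correlation between the
  subject-averaged TRF RDM time series and each ROI's RDMs,
  controlling the attentional-task model RDM and the opposite stream's
  TRF RDM; right-tailed group t-tests with Benjamini–Hochberg FDR over
  the joint time × ROI × stream family. The time axis comes entirely
  from EEG, the spatial axis from fMRI.

## Worked example

```python
import speechtrack as st
from speechtrack import pipeline as pl, synthetic_data as sd, rsa_fusion as rf

cfg = sd.SynthConfig(seed=7)              # 8 subjects, 16 channels, 128 Hz
dataset, truth = sd.simulate_eeg_dataset(cfg)

rc = pl.RunConfig(seed=7)
ser = pl.compute_ser(dataset, rc)          # held-out Δr per trial
d = ser[(ser.stream == "dialogue") & (ser.segment == 0) & ser.valid]
print(d.groupby("task").delta_r.mean())
# task
# attend    0.548
# ignore    0.314

trfs, lags = pl.compute_trfs(dataset, rc)
_, group = pl.trf_rdm_series_by_subject(trfs, lags, rc)
fmri = sd.simulate_fmri_rdms(cfg, group)
fusion = rf.fuse(group, fmri)
print(fusion.peak_latency_ms("roi-dial-400", "dialogue"))
# 398.4375
```

Attending the dialogue roughly doubles its injected tracking gain, and
the held-out Δr reflects that (0.55 attended vs 0.31 ignored; a
sign-flip permutation paired t-test across the 8 simulated subjects
gives p = 0.0078). The fusion peak for a synthetic ROI carrying the
dialogue representation at 400 ms lands at 398 ms — within one 7.8 ms
TRF sample of the assigned latency.

The same pipeline runs from the command line:

```sh
speechtrack run --seed 7 --out results/demo          # all stages
speechtrack simulate --seed 7 --out results/demo     # just the container
```

Stage outputs are tidy TSV tables (`ser_scores.tsv`,
`line_profile.tsv`, `attention_decoding.tsv`,
`task_model_correlation.tsv`, `fusion.tsv`) plus a `derived.h5` with
the TRFs, all stamped with the config hash and seed; identical config
and container give byte-identical tables.

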