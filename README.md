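# bleedwatch

Frame-level detection of intraoperative bleeding in surgical video, and its
escalation into an early, surgeon-facing alert — built for robot-assisted
procedures where a pool of blood accumulating in the endoscopic view must
be flagged within seconds. The package is aimed at researchers studying
surgical event detection who need a complete, reproducible pipeline:
detector, alerting logic, and the statistics used to compare machine
alerts against a clinician's review. Every stage runs on a built-in
synthetic scene generator, so the whole chain is exercisable and testable
without any video data.

## What is inside

**Multi-task U-Net.** A shared contracting path feeds two branches: a
U-Net decoder with skip connections segmenting surgical instruments
(per-pixel sigmoid), and a classification head (global average pooling of
the bottleneck → fully connected → 2-way softmax) deciding per frame
between *no blood accumulation* (0) and *blood accumulation* (1). Training
minimises the unweighted sum

    loss = seg_loss + cls_loss

(pixel-mean binary cross-entropy + class cross-entropy): the segmentation
task regularises the shared features the bleeding classifier uses. Event
detection accuracy is `#correct_predictions / #samples`, overall and per
class. The network and its backpropagation are implemented in pure NumPy
and train on one CPU core in minutes at the default desk scale (64×64
input, depth 3, 16 base channels).

**Alert engine.** The per-frame confidence `p(t)` is smoothed with a
causal digital Butterworth low-pass filter (cutoff 5 Hz by default), then
escalated like a parking sensor: any filtered detection above a confidence
floor (0.30) keeps the escalation active, and while active the warning
level `w ∈ [0, 1]` rises at `1/T_esc` per second with `T_esc = 2.2 s`, so
persistently recurring detections — even individually weak ones —
saturate the warning within one escalation window; when detections stop,
`w` decays. Significant bleeding is declared, dichotomously (0/1) with an
onset time, whenever `w` crosses 0.94 (the midpoint of the 93–95 %
operating band) from below.

**Evaluation suite.** System and human event logs are matched one-to-one
(nearest in time, ±10 s tolerance) into TP / FP / FN outcomes; the delta
time `Δ = t_system − t_human` is summarised as median (IQR) and as a
Gaussian kernel density estimate (negative Δ = machine earlier). A
from-scratch Multiple Correspondence Analysis (indicator matrix →
standardised residuals → SVD) examines whether outcome categories
associate with any structure in the evaluation table; principal inertias
sum to the exact identity (J − Q)/Q.

See `docs/methods.md` for the model, the escalation law and every default,
and for what the synthetic scenes do and do not emulate.

## Worked example

Train a detector on synthetic frames, run it over a bleeding sequence, and
compare machine alerts with a (simulated) human reviewer:

```bash
bleedwatch synth --out data/train --mode training --n-frames 500 --seed 0
bleedwatch train --dataset data/train/manifest.json --out model --seed 0
# -> selected epoch 30: val_accuracy=0.9900 (class0=1.0000, class1=0.9800)

bleedwatch synth --out data/bleed --duration-s 14 --precursor-onset-s 4 \
    --bleed-onset-s 10 --seed 3
bleedwatch run --checkpoint model/checkpoint.npz \
    --dataset data/bleed/manifest.json --out run_out
```

`run_out/probs.jsonl` holds one record per frame (raw and filtered
confidence plus warning level); `run_out/events.csv` lists the dichotomic
alerts. The same escalation applied to a library-generated precursor trace
shows the early-warning behaviour directly:

```python
from bleedwatch import (ProbabilitySeries, run_alert_pipeline,
                        generate_precursor_confidence_trace)

values, plateau_onset = generate_precursor_confidence_trace(rng_seed=3)
trace = run_alert_pipeline(ProbabilitySeries(values=values, fps=25.0))
print(plateau_onset, trace.events[0][0], plateau_onset - trace.events[0][0])
# 10.0 6.08 3.92
```

The oozing precursors (2-frame bursts of 0.5–0.7 confidence every 300 ms,
starting 6 s before the sustained phase) drive the warning level past the
0.94 threshold at t = 6.08 s — an alert 3.92 s before frank bleeding
begins at t = 10 s. Evaluating simulated logs where the system leads a
human reviewer by ~3 s:

```python
med, iqr = delta_stats(all_deltas)   # over 40 matched pairs
# median delta -3.05 s (IQR 0.96): negative delta = system earlier
```

`bleedwatch eval --system ... --human ... --out eval_out` writes the same
statistics plus the KDE curve and MCA coordinates (CSV + PNG).

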