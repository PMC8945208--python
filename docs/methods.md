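# Methods

## Data model

A screening sweep is represented as a binary matrix of per-frame detections
over a fixed, ordered vocabulary of 18 fetal cardiac substructures,
partitioned into great vessels (4: pulmonary artery, ascending aorta,
superior vena cava, ductus arteriosus), intracardiac structures (8: crux,
ventricular septum, right atrium, tricuspid valve, right ventricle, left
atrium, mitral valve, left ventricle) and other landmarks (6: descending
aorta, stomach, spine, umbilical vein, inferior vena cava, pulmonary vein).
Files may list channels in any order; loading canonicalises them so the
frame-major flattening fed to the encoders is reproducible. Frames are
0-based, kernel windows half-open `[start, start + w)`.

The composition of the *ideal* 4CV and 3VTV blocks is a modelling choice
(the visible-structure content of these planes is standard sonographic
knowledge but not a fixed physical constant): 4CV = all eight heart
channels + descending aorta + spine; 3VTV = all four vessel channels +
descending aorta + spine. Both sets are configurable via the registry YAML
so alternative plane definitions can be evaluated without code changes.

## Encoder

Each kernel slice (default `w = 16` frames, stride 1, so a T-frame video
yields T−15 points) is compressed to 2D. The cascade wiring compresses the
vessels block (4·w inputs) and heart block (8·w) with separate
auto-encoders to 2D each; those latents plus the others block (6·w) feed
the main auto-encoder, bottleneck 2. All encoders/decoders are
fully-connected nets with two ReLU hidden layers (64, 16; see Defaults)
implemented directly in numpy with hand-written
backpropagation and Adam — the nets are small enough that a deep-learning
framework would add nothing but a dependency.

Losses. Sub-blocks and the simple-variant input are binary, so their
reconstruction loss is sigmoid cross-entropy in logit space. The main
auto-encoder's input mixes the two real-valued sub-latents with the binary
others block; it is reconstructed with MSE on the four latent dimensions
(targets treated as constants, so the main reconstruction does not drag
the sub-latents around) and cross-entropy on the binary dimensions. The
view-proxy loss is the squared Euclidean distance of the encoded ideal 4CV
and 3VTV blocks to (0,1) and (1,0), applied to the main diagram only and
added to every minibatch. Total objective:
`lambda_recon * recon + lambda_proxy * proxy`, both weights defaulting
to 1.

Training is one-class: the fit contract rejects abnormal-labelled input.
Sub and main nets are trained jointly end to end (gradients from the main
reconstruction and proxy flow into the sub-encoders); a stage-wise mode
(sub first, then main with sub weights frozen) is available via
`training_mode="stagewise"` for comparison. A single clean ideal slice per
plane is used as the proxy input rather than a distribution of noisy
variants; the anchors' job is orientation-pinning, for which one exact
exemplar suffices.

## Abnormality score

The trajectory through the ordered latent points is buffered by radius
`r = 0.05` latent units (round caps, `shapely`), giving a capsule-union
region. Buffering makes the area traversal-order invariant and idempotent
under revisits — re-entering an already covered latent neighbourhood adds
nothing — which is what makes the score robust to probe back-and-forth and
speed variation. The abnormality score of diagram *G* is
`1 − area(G) / area(G_max)` with `G_max` the largest-area diagram of the
evaluated collection (clipped to [0,1] for out-of-collection queries). The
screener also freezes the training-collection maximum as an optional
leakage-free reference for sample-wise scoring of new videos
(`score_samples` / `predict`); the collection-normalised protocol
(`score_collection`) is the canonical evaluation path.

## Synthetic sweeps

The simulator emulates the acquisition protocol the method assumes: a
latent probe position advances from the abdominal plane through 4CV to
3VTV with multiplicative speed noise (`speed_sigma = 0.3`) and
backtracking steps (`jitter_prob = 0.1`), then is rescaled to span the
full range. Dwell fractions: abdomen 0.20, transition 0.15, 4CV 0.25,
transition 0.15, 3VTV 0.25. Pure phases emit their visibility sets
deterministically; transitions ramp channels linearly between neighbouring
sets. Detector noise: per-frame per-channel dropout 0.10 and false
positives 0.02 — plausible mid-range operating characteristics for a
frame-level detector, exposed in `SweepConfig` because the upstream
detector's true error rates are scenario-dependent. Sweeps default to
200 frames (a ~10 s clip at a 20 Hz detection rate).

Disease templates are suppression-only: they remove detections of affected
channels with per-channel probabilities and never add structures, mirroring
the premise the score exploits (abnormality manifests as absence of normal
patterns). Bundled templates: TOF-like (pulmonary artery 1.0, ascending
aorta 0.7, ductus arteriosus 0.8) and HLHS-like (left ventricle 1.0,
mitral valve 1.0, ascending aorta 0.8). The default benchmark is 60
normal training videos (2 per case) and a test set of 20 normal + 20
abnormal videos from 10+10 cases, alternating templates across abnormal
cases.

What the simulator does **not** model: acoustic shadowing, fetal movement
other than via detection dropout, gestational-age or device effects,
correlated multi-channel detector failures, and disease phenotypes beyond
channel suppression. Passing synthetic gates therefore demonstrates that
the pipeline recovers the structure it assumes — not clinical performance.

## Evaluation

AUC uses the midrank Mann–Whitney estimator (pairwise win rate with ties
counted half), which is exact under heavy ties — examiner scores take only
ten values. Threshold metrics (accuracy, FPR, recall, precision, F1) use
the strict rule *abnormal iff score > 0.5*: examiner scores
(d·c+5)/10 can never equal 0.5, so the threshold reproduces the raw
decision *d*, and an AI score of exactly 0.5 counts normal. With zero
predicted positives, precision is reported as 0 with an explicit
`precision_undefined` flag. Summary rows report mean, descriptive SD
(ddof = 0), median, min and max over seeds or examiners. The ablation grid
crosses cascade wiring × view-proxy loss, five seeds each (0–4); a
median-of-five model-picking policy is available for selecting a
deployment model from multi-seed runs.

## Defaults and numerical choices

| Parameter | Default | Why |
|---|---|---|
| kernel width `w` | 16 frames | smooth trajectories at 200-frame sweeps; window long enough to span a cardiac-cycle's detection flicker |
| kernel stride (diagram) | 1 | densest trajectory |
| training slice stride | 4 | adjacent windows are nearly duplicates; 4× fewer slices, same coverage |
| hidden sizes | (64, 16) | smallest stack that reliably converges on 288-dim binary windows; keeps a 20-training ablation in minutes on one CPU |
| epochs / lr / batch | 80 / 1e-3 / 256 | convergence of the proxy distance and recon loss plateaus by ~60 epochs; 80 adds margin across seeds |
| buffer radius `r` | 0.05 | thin enough to resolve itinerary gaps at unit latent scale; benchmark AUC is insensitive to `r` in [0.05, 0.3] |
| proxy anchors | (0,1), (1,0) | unit axes: orthogonal, unit scale, away from the origin the decoders favour early in training |

Degenerate inputs: single-point (or fully coincident) trajectories buffer
to a disk of area πr²; `area_max ≤ 0` is rejected; scores are clipped to
[0, 1]. All randomness (simulator, weight init, batch shuffling) flows
from explicit integer seeds; identical seeds give byte-identical datasets
and bit-identical weights.

## Problem sizes used in the shipped checks

The behavioural gates run the default benchmark (60/20+20 videos of 200
frames) for the 4-variant × 5-seed ablation, Monte-Carlo area validation
with 10⁶ samples per trajectory, 200 random instances for the AUC/oracle
equivalence, and a 12-video noise-free training run for the probe-replay
robustness check. These sizes were chosen as the smallest at which the
multi-seed statistics are stable.

## Known limitations

- The upstream object detector is out of scope; timelines are consumed
  as given, and simulator noise rates are assumptions, not measurements.
- The buffered-polyline region is a deliberate first-order shape model; a
  concave-hull/alpha-shape alternative could score coverage differently
  and is not implemented.
- Plane markers on plots are assigned by latent proximity to the proxy
  anchors (threshold 0.15), a visualization heuristic, not a plane
  classifier.
- With very high probe jitter the rescaled sweep position can
  under-represent early phases; the simulator targets moderate jitter.
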