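# Methods

`leafn` estimates leaf nitrogen content (N, percent dry mass) from RGB
photographs of single sugarcane leaves taken against a white board, for two
growth stages (tillering, elongation) modelled as independent datasets.  The
chain is: illumination correction → leaf segmentation → color/texture feature
extraction → feature selection → cross-validated regression.  Because no such
image set is publicly deposited, the package ships a synthetic generator that
plays the role of the field data; everything downstream is tested against its
known ground truth.

## Synthetic data generator

Each sample is an elliptical "leaf" (randomized axes and orientation,
roughly centred) on a board at reflectance 0.96, rendered at 256×256.  Per
plant a latent N is drawn uniformly on [0.8, 2.2] % — the agronomically
realistic range for sugarcane leaves, and uniform rather than normal so that
correlation screening is not driven by a handful of extreme plants.  The
signal enters twice:

- **Color link.**  Mean leaf color is affine in N, `base + slopes·N`, with
  negative per-channel slopes (more N → more chlorophyll → darker, more
  saturated green; steepest on G).  The two stages use different bases and
  slopes.
- **Texture link.**  A Gaussian-filtered white-noise mottling field
  (correlation length 2.5 px) is added to the leaf with amplitude
  `a(N) = a0 + a1·N` (defaults 0.01 + 0.035·N).  Because gray levels are
  min–max quantized inside the mask, what the co-occurrence statistics see is
  the *ratio* of smooth mottling to unstructured pixel noise, which grows
  with N; homogeneity (IDM) and correlation (COR) carry most of that signal.
  The mottling field is re-centred to mean zero over the leaf so that, with
  the noise terms off, leaf-mean color is *exactly* affine in N (this is what
  makes exact slope-recovery tests possible).

Noise sources, all seeded: per-pixel Gaussian noise (SD 0.02, truncated at
±2 SD so background pixels provably stay near the board level), a per-sample
whole-leaf color jitter (SD 0.015) representing plant-to-plant variability,
and an optional multiplicative illumination field (random linear ramp plus a
broad blob, ±15 %).  The sample jitter matters: per-pixel noise averages out
over the ~10⁴ leaf pixels, so without a plant-level noise source every
regression would trivially reach R² ≈ 1.  With the defaults the
cross-validated R² of the better models lands around 0.85–0.93, the regime
the method is meant for.

What the generator does **not** emulate: venation and midrib structure,
specular highlights, shadows, multi-leaf scenes, camera optics and
JPEG artifacts.  Tests passing on this generator therefore demonstrate the
pipeline's correctness and its statistical behaviour under a known link —
not field-level accuracy.

`n_content(m, V, M) = m·V/M × 10⁻³` converts a flow-analyzer reading
(mg/L), a digestion volume (mL) and a dry mass (g) into the label; the raw
formula value is returned and unit interpretation is left to the caller.

## Illumination correction (MSRCR)

Multi-scale retinex with color restoration, per channel i:

    MSR_i = Σ_k w_k · [ln(I_i + ε) − ln(G_σk ∗ I_i + ε)]
    C_i   = β · ln( α·(I_i + ε) / (ΣI_j + 3ε) )
    out_i = stretch(C_i · MSR_i)

Defaults: scales σ = (15, 80, 250) px with equal weights, α = 125, β = 46,
ε = 10⁻⁶, natural logs (the log base only rescales pre-stretch values).
These are the canonical retinex constants; nothing downstream is sensitive
to them as long as the scales span local to near-global neighbourhoods.

The output mapping needs care.  A fully adaptive percentile stretch
(x − P1)/(P99 − P1) is scale-free: it re-amplifies whatever residue survives
the retinex step, so an illumination-only scene comes out just as
non-uniform as it went in.  `leafn` therefore clips at the (1, 99)
percentiles and then applies a *gain-capped, median-centred* stretch:

    out = 0.5 + (clip(x, P1, P99) − median(x)) / max(P99 − P1, min_span)

with `min_span = 2·1.5·β·ln α` (≈ 666 at the defaults), the retinex-unit span
of a full-contrast scene.  This is the same idea as the fixed gain/offset
mapping in the canonical MSRCR formulation: genuinely uniform channels map to
uniform mid-gray instead of amplified noise, while contrasty scenes still use
the full output range.  The median anchors the offset on the dominant
content — the white board under this protocol — so it is stable across
frames.  Measured on fixtures: a constant image is a fixed point; global
dimming by 2× changes the output by < 10⁻⁶; the coefficient of variation of
a pure illumination ramp drops ≈ 6×; the leaf-mean hue of an evenly lit leaf
moves < 3°.

## Segmentation

The imaging protocol guarantees a near-white background, so the leaf body is
recovered classically: Euclidean distance-from-white map → Otsu threshold →
3×3 morphological closing → hole filling → largest connected component.
A minimum area fraction (default 1 %) guards against empty scenes ("no leaf
found").  On the generator this reaches IoU ≥ 0.99 against ground truth with
or without the illumination field.  Externally produced masks (e.g. from a
learned salient-object detector) can be supplied wherever a mask is accepted.

## Features

**Color (24).**  R, G, B are the foreground channel means in [0,1]; ratio and
difference indices are computed from those means (not per-pixel) with an
ε = 10⁻⁶ denominator guard; chromatic coordinates r, g, b = channel/(R+G+B)
with differences gr = g−r, gb = g−b, br = b−r; the mean color is converted to
HSV and CIELAB (sRGB, D65) with H stored as degrees/360 so all features live
on comparable scales for standardized PCA.  Note the vocabulary `gr, gb, br`
denotes chromaticity *differences* here — one reasonable reading of that
shorthand, fixed and documented rather than asserted as canonical.

**Texture (5).**  Rec. 709 luminance, min–max quantized to 64 gray levels
inside the mask (64 keeps distance-1 co-occurrence matrices dense at typical
leaf sizes of ~10⁴ px).  For each of the four azimuths (0°, 45°, 90°, 135°,
distance 1) a symmetric co-occurrence matrix is accumulated over pixel pairs
that are *both* inside the mask, and

    ASM = Σ p²          IDM = Σ p/(1+(i−j)²)     CON = Σ (i−j)²·p
    ENT = −Σ p·ln p     COR = (Σ ij·p − μ₁μ₂)/(σ₁σ₂)

are averaged over the four angles.  COR is undefined (NaN-flagged) when a
marginal SD vanishes, e.g. on constant regions; degenerate foregrounds take
the ASM=1/IDM=1/CON=0/ENT=0 path.  The implementation is verified against a
brute-force pair-enumeration oracle (and against scikit-image on unmasked
rectangles — note the 45°/135° labels mirror between image and trigonometric
row conventions).

## Feature selection

- **SCT route**: per-feature Pearson correlation with N; keep |r| > 0.7.
  The threshold is applied to |r| because published summaries report only
  magnitudes and negatively coded features (e.g. chromaticity differences)
  would otherwise be dropped silently.  Constant columns get r = 0 and a
  flag.
- **PCA route**: the 24-color and 5-texture blocks are standardized and
  eigendecomposed *separately* (correlation-matrix PCA — the blocks live on
  different scales), then the Kaiser criterion retains eigenvalues > 1 with a
  retain-one floor.  The integrated variant (C-T-PCA) concatenates both score
  blocks.  Sign convention: each loading's largest-magnitude entry is
  positive.

Both routes have a fit/transform split and are refit inside every training
fold during cross-validation; a "paper mode" flag reproduces the alternative
discipline of selecting once on the full data before modelling.

The published bookkeeping tables for this pipeline (five eigenvalues and
cumulative variance contribution rates per stage and block) are kept in
`leafn.reference` as a fixed worked example: Kaiser retention yields three
color PCs and one texture PC per stage, and the printed CVCR percentages are
recovered from the printed eigenvalues to < 0.01 pp once the block total is
estimated as the value most consistent with all printed rows (minimax).
Anchoring the total on PC1 alone propagates the three-decimal rounding of
the printed eigenvalues to ~0.012 pp on the texture blocks, which is why the
minimax estimate is used.

## Regression layer

Families: MLR (least squares), PLS, SVR (C = 1), BPNN (multilayer
perceptron) and random forest, plus the stacking fusion model (SFM).
PLS/SVR/BPNN inputs *and* target are min–max scaled to [−1, 1] on the
training fold and predictions inverse-scaled before any metric.  All metrics
are reported as fold means of

    R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²,   RMSE = √(Σ(ŷ−y)²/n),   MAPE = (1/n)Σ|(ŷ−y)/y|

on held-out folds (MAPE as a fraction).

Hyperparameters come from exhaustive grid search under seeded 5-fold CV,
selecting on mean R² (ties: lower RMSE, then grid order).  This mirrors the
GridSearchCV discipline of the source workflow: the winning cell's fold
metrics are reported, which carries the usual mild model-selection optimism;
it is not nested CV.  Default lattices are compact so a full experiment runs
on a desktop:

| family | default grid | study-scale (`full`) grid |
|---|---|---|
| PLS | n_components 1..min(10, d) | same |
| SVR | 4 kernels × {scale, auto} | same |
| BPNN | {1,2} layers × {10,50} neurons × 4 activations × lbfgs | 1–30 layers × 1–100 neurons × 4 activations × {lbfgs, adam, sgd} |
| RF | trees {10,40,70,100} × split {2,5} × leaf {1,3,5} | trees 10–100 step 1 × split {2..5} × leaf {1..5} |

The BPNN default keeps only lbfgs because on n ≈ 50 samples the
gradient-descent solvers cost ~10× more per fit without changing the
selected model (the study-scale optimum — identity activation, lbfgs, 50
neurons — sits inside the default lattice).  BPNN uses α = 10⁻⁴
regularization and a 2 000-iteration default cap (ample at these sample
sizes; any cell may request more via ``max_iter``).  A min_samples_split of 1 is
undefined in scikit-learn, so the RF grid starts at 2.  PLS components are
capped per fold at min(d, n−1) because fold-local selectors can retain
different dimensionalities.

**Stacking (SFM).**  Three bases — PLS, SVR, BPNN — are grid-searched on the
training data; each is then refit k = 5 times on fold complements to fill its
out-of-fold (OOF) prediction column, giving the (m, p) meta-feature matrix.
The meta-learner is a BPNN (one hidden layer of 10, identity activation,
lbfgs — deliberately close to a learned linear blend, which is robust at
these sample sizes) trained on OOF predictions against y.  At inference the
bases are refit on all training data and their predictions feed the meta
model — standard stacking practice.  An audit hook can record the training
indices of every internal fit; the test suite uses it to prove no estimator,
scaler or selector ever saw held-out samples, and a memorizing-base test
(1-nearest-neighbour) confirms OOF columns are genuinely out-of-fold.

## Experiment driver

`run_experiment` executes the full stage × variant × model matrix (2 × 6 × 6
by default), writes per-stage feature tables, correlation reports, PCA
bookkeeping tables and a flat leaderboard, and derives every random stream
from one master seed (per-stage generator seeds, fold seeds, model seeds).
Cell failures are recorded without aborting the run; the report renderer
ranks variants per model and models per variant and flags missing cells.
The numbered scripts under `analysis/` run the same chain stepwise on a
written-to-disk dataset.

## Numerical choices and edge cases

- Pearson screening requires n ≥ 3 and a non-constant target.
- PCA drops constant columns with a warning; all-constant blocks are an
  error; n ≤ d proceeds with a rank-deficiency warning.
- Grid cells that fail to fit are skipped (an error is raised only if every
  cell fails); MLR on singular designs warns and uses the minimum-norm
  solution.
- R² is NaN-flagged for constant targets, MAPE for targets containing zero.
- Quantization of a constant foreground flags "degenerate range" and maps to
  level 0.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; no wall-clock defaults anywhere.

## Problem sizes used in tests and the acceptance run

Tests and the acceptance script use the default study conditions — 60
samples per stage at 256×256 — for end-to-end checks, and smaller seeded
datasets (n = 12–40, 48–128 px frames) for module-level properties.  The
oracle comparisons run on ≤ 8×8 images where brute-force enumeration is
exact.  These sizes are the package's chosen defaults; scaling n or the
frame up only sharpens the statistics.

## Known limitations

- The synthetic link between texture statistics and N is simpler than real
  canopy texture; ASM/ENT correlations are weaker than IDM/COR here.
- Fold-mean R² under grid search is mildly optimistic (no nesting).
- The whiteboard segmentation assumes the protocol's background; it is not a
  general leaf detector.
- MSRCR constants are literature defaults, not fitted to a camera model.
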