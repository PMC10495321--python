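# leafn — leaf-image estimation of crop nitrogen content

`leafn` estimates leaf nitrogen content (N, % dry mass) of sugarcane from RGB
photographs of single leaves on a white board, the low-cost alternative to
SPAD meters and hyperspectral rigs.  It implements the full analysis chain as
a tested Python library:

1. **Illumination correction** — multi-scale retinex with color restoration
   (MSRCR): per channel, `MSR_i = Σ_k w_k [ln(I_i+ε) − ln(G_σk∗I_i+ε)]`
   weighted by the chromatic factor `C_i = β ln(α I_i / ΣI_j)`, with a
   gain-capped percentile stretch back to [0,1].
2. **Segmentation** — distance-from-white map, Otsu threshold, morphology,
   largest connected component (the white-board protocol makes a trained
   salient-object detector unnecessary; external masks can be supplied).
3. **Features** — 24 color features (RGB means and indices, chromaticity
   coordinates, HSV, CIELAB) plus 5 gray-level co-occurrence statistics
   (ASM, IDM, CON, ENT, COR; distance 1, averaged over 0°/45°/90°/135°,
   64 gray levels).
4. **Selection** — Pearson screening (keep |r| > 0.7 with N) and blockwise
   standardized PCA with Kaiser retention (eigenvalue > 1), giving six input
   variants: CF-SCT, TF-SCT, CTIF-SCT, CF-PCA, TF-PCA, C-T-PCA.
5. **Regression** — MLR, PLS, SVR, BPNN and random forest under seeded 5-fold
   cross-validated grid search, plus a two-layer **stacking fusion model**
   (PLS/SVR/BPNN bases → out-of-fold meta-features → BPNN meta-learner),
   reporting fold-mean R², RMSE and MAPE:
   `R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²`, `RMSE = √(Σ(ŷ−y)²/n)`,
   `MAPE = (1/n) Σ|(ŷ−y)/y|`.

Because no field dataset is deposited for this protocol, the package includes
a first-class synthetic generator (`leafn.synthgen`): seeded single-leaf
scenes whose mean color is affine in a latent N and whose mottling amplitude
grows with N, under per-pixel noise, plant-to-plant color jitter and a smooth
multiplicative illumination field — with ground-truth masks and N values, so
segmentation is scored by IoU and the regression layer by parameter
recovery.  See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from leafn import (GeneratorConfig, generate_dataset, extract_table,
                   evaluate_variant)
from leafn.pipeline import preprocess_samples

ds = generate_dataset(GeneratorConfig(n_samples=60, stage="tillering", seed=42))
images, masks = preprocess_samples(ds)          # MSRCR + segmentation
table = extract_table(images, masks)            # 60 x 29 feature table
y = np.array([s.n_value for s in ds])

res = evaluate_variant(table, y, "C-T-PCA", "SFM", seed=42)
print(f"SFM on C-T-PCA: R2={res.mean_r2:.4f} RMSE={res.mean_rmse:.4f} "
      f"MAPE={res.mean_mape:.4f}")
```

Output:

```
SFM on C-T-PCA: R2=0.8855 RMSE=0.1241 MAPE=0.0704
```

i.e. on the default synthetic conditions the stacked model explains ~89 % of
the plant-to-plant variance in leaf N, with a root-mean-square error of
0.12 % N and a mean relative error of 7.0 % — in the same accuracy regime
single-feature models only reach with more informative inputs.  The numbered
scripts under `analysis/` run the same chain stepwise (generate → preprocess
→ extract → select → train → report) and write their tables under
`results/`; the `leafn` command-line tool exposes each step
(`leafn generate|preprocess|extract|select|train|report|run-all`).

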