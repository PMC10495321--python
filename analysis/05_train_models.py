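"""Cross-validated model comparison over the full variant x family matrix.

For each stage: six input variants (CF/TF/CTIF under correlation screening;
CF/TF/integrated under PCA) x six regressors (MLR, PLS, SVR, BPNN, RF and the
stacking fusion model), 5-fold CV with per-fold selector refits and grid
search.  Writes the flat leaderboard CSV used by 06_report.py.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from leafn.models import evaluate_variant
from leafn.pipeline import MODEL_NAMES
from leafn.select import VARIANT_NAMES

DATA = Path("results/data")
SEED = 7

rows = []
for stage_dir in sorted(DATA.iterdir()):
    if not (stage_dir / "features.csv").exists():
        continue
    table = pd.read_csv(stage_dir / "features.csv", index_col=0)
    y = (
        pd.read_csv(stage_dir / "labels.csv")
        .set_index("sample_id")
        .loc[table.index, "n_value"]
        .to_numpy()
    )
    for variant in VARIANT_NAMES:
        for family in MODEL_NAMES:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = evaluate_variant(table, y, variant, family, seed=SEED)
            except Exception as exc:
                print(f"{stage_dir.name} {variant:9s} {family:4s}: FAILED ({exc})")
                continue
            rows.append({"stage": stage_dir.name, "variant": variant, "family": family,
                         "R2": res.mean_r2, "RMSE": res.mean_rmse, "MAPE": res.mean_mape})
            print(f"{stage_dir.name} {variant:9s} {family:4s}: "
                  f"R2={res.mean_r2:.4f} RMSE={res.mean_rmse:.4f} MAPE={res.mean_mape:.4f}")

lb = pd.DataFrame(rows)
Path("results").mkdir(exist_ok=True)
lb.to_csv("results/leaderboard.csv", index=False)
print(f"\nwrote {len(lb)} cells -> results/leaderboard.csv")
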