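"""Summarize the leaderboard along the two comparison axes.

Axis 1: for each regressor, which input variant estimates leaf N best?
Axis 2: for each input variant, which regressor wins?  Also reports how the
stacked model compares with its own base learners on the integrated PCA
features.
"""

import pandas as pd

lb = pd.read_csv("results/leaderboard.csv")

for stage, sub in lb.groupby("stage"):
    print(f"== {stage} ==")
    print("best variant per family:")
    for fam, fsub in sub.groupby("family"):
        best = fsub.loc[fsub["R2"].idxmax()]
        print(f"  {fam:4s}: {best['variant']:9s} R2={best['R2']:.4f} RMSE={best['RMSE']:.4f}")
    print("best family per variant:")
    for var, vsub in sub.groupby("variant"):
        best = vsub.loc[vsub["R2"].idxmax()]
        print(f"  {var:9s}: {best['family']:4s} R2={best['R2']:.4f}")
    ct = sub[sub["variant"] == "C-T-PCA"].set_index("family")["R2"]
    if "SFM" in ct.index:
        bases = ct.reindex(["PLS", "SVR", "BPNN"]).dropna()
        print(f"C-T-PCA stack vs bases: SFM={ct['SFM']:.4f}, "
              f"best base={bases.max():.4f} ({bases.idxmax()})")
    top = sub.loc[sub["R2"].idxmax()]
    print(f"overall best: {top['variant']} + {top['family']} (R2={top['R2']:.4f})\n")
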