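"""Correlation screening and blockwise PCA per stage.

Prints which features clear |r| > 0.7 (the strongly-correlated-term sets) and
the eigenvalue / cumulative-variance bookkeeping with Kaiser retention;
writes both tables as CSV.
"""

from pathlib import Path

import pandas as pd

from leafn.select import fit_pca, pearson_screen

DATA = Path("results/data")

for stage_dir in sorted(DATA.iterdir()):
    if not (stage_dir / "features.csv").exists():
        continue
    table = pd.read_csv(stage_dir / "features.csv", index_col=0)
    y = pd.read_csv(stage_dir / "labels.csv").set_index("sample_id").loc[table.index, "n_value"]

    report = pearson_screen(table, y.to_numpy(), threshold=0.7)
    report.to_frame().to_csv(stage_dir / "correlation.csv")
    print(f"== {stage_dir.name} ==")
    print(f"  SCT set (|r| > 0.7): {report.selected}")

    frames = []
    for blk, cols in (("CF", table.columns[:24]), ("TF", table.columns[24:])):
        model = fit_pca(table.loc[:, list(cols)], block=blk)
        frames.append(model.to_frame())
        top = ", ".join(f"{e:.3f}" for e in model.eigenvalues[:5])
        print(f"  {blk}: eigenvalues [{top} ...] -> retain {model.k_retained} PCs "
              f"(CVCR at cut: {model.cvcr[model.k_retained - 1]:.1f}%)")
    pd.concat(frames, ignore_index=True).to_csv(stage_dir / "pca.csv", index=False)
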