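"""Extract the 24 color + 5 texture features for every segmented leaf.

Writes one features CSV per stage (rows = samples, columns = the fixed
29-name vocabulary) plus the matching labels CSV.
"""

import csv
from pathlib import Path

from leafn.features import extract_table
from leafn.preprocess import load_image, load_mask

DATA = Path("results/data")

for stage_dir in sorted(DATA.iterdir()):
    manifest = stage_dir / "manifest.csv"
    if not manifest.exists():
        continue
    with open(manifest) as fh:
        rows = list(csv.DictReader(fh))
    images, masks, ids = [], [], []
    for row in rows:
        name = Path(row["image_path"]).name
        images.append(load_image(stage_dir / "corrected" / name))
        masks.append(load_mask(stage_dir / "pred_masks" / name).mask)
        ids.append(row["sample_id"])
    table = extract_table(images, masks, ids)
    table.to_csv(stage_dir / "features.csv")
    with open(stage_dir / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "n_value"])
        for row in rows:
            w.writerow([row["sample_id"], row["n_value"]])
    print(f"{stage_dir.name}: {table.shape[0]} x {table.shape[1]} feature table "
          f"-> {stage_dir / 'features.csv'}")
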