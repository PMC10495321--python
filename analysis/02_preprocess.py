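"""De-illuminate (MSRCR) and segment every generated leaf image.

Reports the segmentation quality against the generator's ground-truth masks;
writes corrected images and predicted masks next to the raw data.
"""

import csv
from pathlib import Path

import numpy as np

from leafn.preprocess import load_image, load_mask, msrcr, save_image, save_mask, segment_leaf

DATA = Path("results/data")

for stage_dir in sorted(DATA.iterdir()):
    if not (stage_dir / "manifest.csv").exists():
        continue
    out_img = stage_dir / "corrected"
    out_mask = stage_dir / "pred_masks"
    out_img.mkdir(exist_ok=True)
    out_mask.mkdir(exist_ok=True)
    ious = []
    with open(stage_dir / "manifest.csv") as fh:
        for row in csv.DictReader(fh):
            image = load_image(row["image_path"])
            corrected = msrcr(image)
            mask = segment_leaf(corrected)
            truth = load_mask(row["mask_path"]).mask
            ious.append((mask.mask & truth).sum() / (mask.mask | truth).sum())
            name = Path(row["image_path"]).name
            save_image(corrected, out_img / name)
            save_mask(mask, out_mask / name)
    print(f"{stage_dir.name}: IoU mean={np.mean(ious):.4f} min={np.min(ious):.4f} "
          f"over {len(ious)} leaves")
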