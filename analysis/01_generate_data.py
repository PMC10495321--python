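"""Generate the two synthetic stage datasets (60 single-leaf images each).

Emulates the field protocol: one leaf per plant on a white board, latent leaf
N drawn per plant, leaf color and mottling coupled to N, smooth illumination
field on.  Writes PNG images + masks + a CSV manifest per stage.
"""

from pathlib import Path

from leafn.synthgen import STAGES, GeneratorConfig, generate_dataset, write_dataset

OUT = Path("results/data")
SEED = 7

for i, stage in enumerate(STAGES):
    cfg = GeneratorConfig(n_samples=60, stage=stage, seed=SEED + i)
    samples = generate_dataset(cfg)
    manifest = write_dataset(samples, OUT / stage)
    n_vals = [s.n_value for s in samples]
    print(f"{stage}: {len(samples)} samples, N in [{min(n_vals):.2f}, {max(n_vals):.2f}] "
          f"-> {manifest}")
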