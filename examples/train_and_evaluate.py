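"""Train the reduced model on a tiny synthetic corpus and evaluate it.

Eight 64x64 tiles of striped polygonal fields are enough for the
attention model to demonstrate its mechanics on a CPU in about a
minute: the loss falls, the dynamic fusion weights alpha/beta move
from their initial draws, and the five confusion-count metrics are
computed under the micro-averaging protocol (pooled pixel counts).
"""

import numpy as np

from dsca import (ModelSpec, TrainConfig, build_model, evaluate_dataset,
                  tiny_corpus, train)

records = tiny_corpus(n_tiles=8, tile_size=64, seed=0)
print(f"corpus: {len(records)} tiles, foreground fractions "
      f"{[round(float(r.load_mask().mean()), 2) for r in records]}")

model = build_model(ModelSpec.reduced(), seed=1)
print(f"reduced model: {model.num_parameters():,} parameters, output stride 4")

init = {name: (float(b.alpha.data), float(b.beta.data))
        for name, b in model.attention_blocks().items()}
cfg = TrainConfig(epochs=120, batch_size=8, seed=3, max_steps=120)
result = train(model, records, cfg)
print(f"\ntrained {result.steps} steps; loss {result.history.train_loss[0]:.3f} "
      f"-> {result.history.train_loss[-1]:.3f}; best training IoU {result.best_val_iou:.3f}")

print("\ndynamic fusion weights (alpha, beta), initial -> trained:")
for name, blk in model.attention_blocks().items():
    a0, b0 = init[name]
    print(f"  {name:<8} ({a0:+.3f}, {b0:+.3f}) -> "
          f"({float(blk.alpha.data):+.3f}, {float(blk.beta.data):+.3f})")

model.load_state_dict(result.best_state)
report = evaluate_dataset(model, records, normalization=result.normalization)
print("\nmicro-averaged metrics (% of pooled pixels):", report.micro.percent())
print("macro (mean of per-tile scores):              ", report.macro.percent())
print("\nThe micro F1 equals 2*IoU/(1+IoU) exactly — the identity that only")
print("holds when the scores come from one pooled confusion table.")
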