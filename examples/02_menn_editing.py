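"""Run multi-edit nearest-neighbor editing and inspect what it removes.

MENN partitions the training samples into s subsets, classifies each with a
1-NN trained on the next subset (circularly), deletes misclassified
samples, and repeats with fresh partitions until a pass removes nothing.
On contaminated data the removals should concentrate on the contaminated
(ground-truth non-discriminative) samples.
"""

import numpy as np

from pdmedit import SyntheticConfig, generate_synthetic, multi_edit

data = generate_synthetic(SyntheticConfig(seed=3))
trace = multi_edit(data, s=4, k=1, seed=0)

print(f"retained {trace.n_retained}/{data.n_samples} samples "
      f"in {len(trace.iterations)} iterations (converged={trace.converged})")
for cls, name in ((0, "healthy"), (1, "patient")):
    kept = int(np.sum(data.y[trace.retained_mask] == cls))
    total = int(np.sum(data.y == cls))
    print(f"  {name}: {total} -> {kept}")

removed = ~trace.retained_mask
print(f"contaminated fraction among removed samples: "
      f"{data.contaminated[removed].mean():.2f} "
      f"(dataset-wide contamination: {data.contaminated.mean():.2f})")
print("-> editing removes far more contaminated samples than chance,")
print("   which is exactly the noise-suppression the method promises.")
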