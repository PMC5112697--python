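"""Generate a subject-clustered speech-feature-style dataset.

Two classes (healthy / patient), each subject contributing many samples
around a subject-specific center; a fraction of each subject's samples are
contaminated — drawn from the opposite class's distribution while keeping
the subject's label.  The closed-form Bayes error tells us the best any
single-sample classifier could do on this mixture.
"""

import numpy as np

from pdmedit import SyntheticConfig, bayes_error_rate, generate_synthetic

config = SyntheticConfig(seed=7)  # defaults: 20+20 subjects, 26 samples, d=26
data = generate_synthetic(config)

print(f"samples: {data.n_samples}, subjects: {len(data.subjects)}, d: {data.d}")
print(f"contaminated samples: {int(data.contaminated.sum())} "
      f"({data.contaminated.mean():.1%} of all samples)")

# the optimal rule thresholds the first (class-separating) coordinate
pred = (data.X[:, 0] > config.class_separation / 2).astype(int)
print(f"closed-form Bayes error: {bayes_error_rate(config):.4f}")
print(f"empirical error of the optimal rule: {np.mean(pred != data.y):.4f}")
print("-> no single-sample classifier can beat the Bayes line; the gap to it")
print("   is what instance selection and subject-level voting must close.")
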