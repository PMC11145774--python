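"""Equalize a skewed severity distribution with SMOTE and ADASYN.

Oversamples the group-target features so every severity class reaches the
majority count, and shows where the synthetic rows land.
"""
import numpy as np

import bdcfgp as b

table = b.generate_dataset(b.GeneratorSpec(seed=7))
features = b.fgp_transform(table)
X = features[list(b.TARGET_COLUMNS)]
y = features["PT"].to_numpy()
print("before:", np.bincount(y).tolist(), "total", len(y))

for method in ("smote", "adasyn"):
    cfg = b.OversamplerConfig(method=method, seed=1, value_range=(0, 5))
    Xb, yb, is_synth = b.oversample(X, y, cfg)
    print(f"{method}: after {np.bincount(yb).tolist()} total {len(yb)} "
          f"({int(is_synth.sum())} synthetic)")
# both raise every class to 360, totalling 2160 rows; snapped to the 0-5 grid
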