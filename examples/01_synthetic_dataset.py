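"""Generate a planted-structure dataset and look at what each role carries.

Builds a small expression-style matrix with shifted (univariate), XOR,
redundant and noise features, then prints the mutual information each role
shares with the class: univariate features carry bits, XOR members and
noise carry none — that invisibility is the problem the pair table solves.
"""

import numpy as np

from pairfs import DiscretizationSpec, SyntheticSpec, generate, mi_score
from pairfs.core_io import discretize_codes

spec = SyntheticSpec(n_samples=200, n_univariate=4, effect_size=1.0,
                     n_xor_pairs=1, n_redundant=2, n_noise=4, seed=7)
ds, roles = generate(spec)
print(f"dataset: {ds.n_samples} samples x {ds.n_features} features, "
      f"classes {[str(c) for c in ds.classes]}")

codes = discretize_codes(ds, DiscretizationSpec())
print(f"\n{'feature':<8} {'role':<22} MI with class (bits)")
for f, name in enumerate(ds.feature_names):
    mi = mi_score(codes[:, f], ds.labels)
    print(f"{name:<8} {roles[name]:<22} {mi:.3f}")

print("\nUnivariate/redundant features carry ~0.1-0.4 bits; the two XOR "
      "members and the noise features are indistinguishable (~0 bits), "
      "even though the XOR pair jointly determines the class.")
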