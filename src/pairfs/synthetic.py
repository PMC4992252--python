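"""Synthetic expression-style datasets with known feature roles.

The generator plants four kinds of features in a Gaussian matrix so that
every selector — and specifically the interaction advantage of the pairwise
pre-evaluation — can be tested without external data:

* **univariate** features whose class means are shifted by ``effect_size``
  standard deviations (adjacent classes one shift apart);
* **XOR pairs**: two standard-Gaussian features whose signed product
  determines a binary class; each member is marginally independent of the
  class, so no univariate filter can see the pair;
* **redundant** features: noisy copies of univariate parents;
* **noise** features: standard Gaussians independent of the class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Dataset

__all__ = ["SyntheticSpec", "generate", "xor_pair_indices"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative recipe; identical specs yield byte-identical datasets.

    ``effect_size`` is the class-mean shift of univariate features in SD
    units (1.0 by default — a clearly detectable but noisy marginal effect
    typical of a differentially expressed gene).  ``label_noise_rate``
    flips the class encoded by each XOR pair's sign product.
    """

    n_samples: int = 100
    n_classes: int = 2
    n_univariate: int = 10
    effect_size: float = 1.0
    n_xor_pairs: int = 0
    n_redundant: int = 0
    redundant_noise_sd: float = 0.3
    n_noise: int = 40
    label_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4 or self.n_classes < 2:
            raise ValueError("need >= 4 samples and >= 2 classes")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if not 0.0 <= self.label_noise_rate < 1.0:
            raise ValueError("label_noise_rate must be in [0, 1)")
        if self.n_xor_pairs > 0 and self.n_classes != 2:
            raise ValueError("XOR pairs require exactly 2 classes")
        if self.n_redundant > 0 and self.n_univariate == 0:
            raise ValueError("redundant features need univariate parents")
        if min(self.n_univariate, self.n_xor_pairs, self.n_redundant,
               self.n_noise) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_features == 0:
            raise ValueError("spec generates no features")

    @property
    def n_features(self) -> int:
        return (self.n_univariate + 2 * self.n_xor_pairs
                + self.n_redundant + self.n_noise)


def generate(spec: SyntheticSpec) -> tuple[Dataset, dict[str, str]]:
    """Build the dataset and its role map (feature name -> role).

    Roles are ``"univariate"``, ``"xor_member:<pair id>"``,
    ``"redundant:<parent name>"`` and ``"noise"``.  Class labels are
    balanced (remainders go to the lowest classes) and shuffled.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    base = np.repeat(np.arange(spec.n_classes), n // spec.n_classes)
    extra = np.arange(n - len(base)) % spec.n_classes
    class_idx = rng.permutation(np.concatenate([base, extra]))
    labels = np.array([f"c{c}" for c in class_idx])

    width = len(str(max(spec.n_features, 1)))
    columns: list[np.ndarray] = []
    names: list[str] = []
    roles: dict[str, str] = {}

    def add(col: np.ndarray, role: str) -> str:
        name = f"f{len(names) + 1:0{width}d}"
        names.append(name)
        columns.append(col)
        roles[name] = role
        return name

    uni_names: list[str] = []
    uni_cols: list[np.ndarray] = []
    for _ in range(spec.n_univariate):
        col = rng.standard_normal(n) + spec.effect_size * class_idx
        uni_cols.append(col)
        uni_names.append(add(col, "univariate"))

    for p in range(spec.n_xor_pairs):
        x = rng.standard_normal(n)
        mag = np.abs(rng.standard_normal(n))
        target = np.where(class_idx == 1, 1.0, -1.0)
        flips = rng.random(n) < spec.label_noise_rate
        target[flips] *= -1.0
        sx = np.where(x >= 0, 1.0, -1.0)
        y = mag * target * sx            # sign(x * y) encodes the class
        add(x, f"xor_member:{p}")
        add(y, f"xor_member:{p}")

    for r in range(spec.n_redundant):
        parent = r % spec.n_univariate
        col = uni_cols[parent] + rng.normal(0.0, spec.redundant_noise_sd, n)
        add(col, f"redundant:{uni_names[parent]}")

    for _ in range(spec.n_noise):
        add(rng.standard_normal(n), "noise")

    ds = Dataset(np.column_stack(columns), labels, names)
    return ds, roles


def xor_pair_indices(ds: Dataset, roles: dict[str, str]
                     ) -> list[tuple[int, int]]:
    """Column-index pairs of the planted XOR members, by pair id."""
    by_pair: dict[str, list[int]] = {}
    for idx, name in enumerate(ds.feature_names):
        role = roles.get(name, "")
        if role.startswith("xor_member:"):
            by_pair.setdefault(role.split(":", 1)[1], []).append(idx)
    return [tuple(sorted(v)) for _, v in sorted(by_pair.items(),
                                                key=lambda kv: int(kv[0]))]
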