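"""Per-SNP weighting schemes.

Rare-variant analyses upweight low-frequency variants through the
Beta(1, 25) density of the minor allele frequency, normalised to sum one.
TWAS-style analyses reuse externally estimated eQTL effects, transformed
per test family: squared for the variance-component tests (SKAT/SKATO),
scaled absolute values for the p-value combiners that need nonnegative
normalised weights (ACAT/HMP), and the raw signed effects for the burden
test, whose power depends on effect direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class WeightVector:
    w: np.ndarray
    mode: str  # maf_beta | eqtl_raw | eqtl_squared | eqtl_abs_scaled

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.mode in ("maf_beta", "eqtl_abs_scaled"):
            if abs(self.w.sum() - 1.0) > 1e-8:
                raise ValueError(f"{self.mode} weights must sum to one")
        if self.mode == "eqtl_squared" and np.any(self.w < 0):
            raise ValueError("squared weights must be nonnegative")

    @property
    def m(self) -> int:
        return len(self.w)


def maf_beta_weights(maf, shape1: float = 1.0, shape2: float = 25.0) -> WeightVector:
    """w_j proportional to the Beta(1, 25) pdf at MAF_j, scaled to sum one."""
    maf = np.asarray(maf, dtype=float)
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ValueError("MAF must lie in (0, 0.5]")
    w = stats.beta.pdf(maf, shape1, shape2)
    return WeightVector(w=w / w.sum(), mode="maf_beta")


# which transform each test family uses
_EQTL_MODES = {
    "BT": "eqtl_raw",
    "SKAT": "eqtl_squared",
    "SKATO": "eqtl_squared",
    "ACAT": "eqtl_abs_scaled",
    "HMP": "eqtl_abs_scaled",
}


def transform_eqtl_weights(w_raw, target_method: str) -> WeightVector:
    """Map raw (signed) eQTL effects onto the weight convention of a test."""
    w = np.asarray(w_raw, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    if np.all(w == 0):
        raise ValueError("all-zero eQTL weights")
    mode = _EQTL_MODES.get(target_method.upper())
    if mode is None:
        raise ValueError(f"no eQTL weighting convention for {target_method}")
    if mode == "eqtl_raw":
        return WeightVector(w=w.copy(), mode=mode)
    if mode == "eqtl_squared":
        return WeightVector(w=w**2, mode=mode)
    a = np.abs(w)
    return WeightVector(w=a / a.sum(), mode="eqtl_abs_scaled")
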