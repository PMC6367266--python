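"""Non-linear fusion of RNA and protein base features into complex features.

For each RNA m-mer frequency r_i and protein n-gram frequency p_j, four
fused families are computed:

- GM:    sqrt(r_i * p_j)                (geometric mean)
- HM:    2 r_i p_j / (r_i + p_j)        (harmonic mean; 0 at r_i = p_j = 0)
- PowRP: log_{r_i}(p_j) = ln p_j / ln r_i
- PowPR: log_{p_j}(r_i) = ln r_i / ln p_j

The log-based families are undefined for zero frequencies and for a base of
exactly 1, so both inputs are smoothed additively by ``epsilon`` and any
smoothed value within ``log_guard`` of 1 is nudged just outside that band;
every emitted value is finite.

The full fused vector for one pair has |families| * 4^m * 7^n entries, named
``FAMILY:<rna-kmer>:<protein-ngram>`` and ordered family-major, then RNA
k-mer lexicographic, then protein n-gram lexicographic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .base_features import BaseFeatureVector

FAMILIES: tuple[str, ...] = ("GM", "HM", "PowRP", "PowPR")


@dataclass(frozen=True)
class FusionConfig:
    """Which fusion families to build and how logs are regularized."""

    families: tuple[str, ...] = FAMILIES
    epsilon: float = 1e-6
    log_guard: float = 1e-6

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("at least one fusion family is required")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown fusion families: {sorted(unknown)}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.log_guard <= 0:
            raise ValueError("log_guard must be > 0")


@dataclass(frozen=True)
class ComplexFeatureVector:
    """Fused feature vector for one RNA-protein pair."""

    pair_id: str
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"pair {self.pair_id}: non-finite complex feature value")


def gm_feature(r: float, p: float) -> float:
    """Geometric mean sqrt(r*p) of two non-negative frequencies."""
    return math.sqrt(r * p)


def hm_feature(r: float, p: float) -> float:
    """Harmonic mean 2rp/(r+p), continuously extended to 0 at r=p=0."""
    s = r + p
    if s == 0.0:
        return 0.0
    return 2.0 * r * p / s


def _nudge_base(b: np.ndarray, log_guard: float) -> np.ndarray:
    """Push values inside the (1-guard, 1+guard) band onto its nearer edge."""
    b = np.asarray(b, dtype=np.float64).copy()
    inside = np.abs(b - 1.0) < log_guard
    below = inside & (b < 1.0)
    b[inside] = 1.0 + log_guard
    b[below] = 1.0 - log_guard
    return b


def pow_features(
    r: float, p: float, epsilon: float = 1e-6, log_guard: float = 1e-6
) -> tuple[float, float]:
    """Directed log-power pair (log_r p, log_p r) with smoothing.

    Both inputs are shifted by ``epsilon``; values within ``log_guard`` of 1
    are nudged outside the band so neither logarithm's denominator vanishes.
    The two outputs are exact reciprocals of each other.
    """
    rb = float(_nudge_base(np.array([r + epsilon]), log_guard)[0])
    pb = float(_nudge_base(np.array([p + epsilon]), log_guard)[0])
    log_r, log_p = math.log(rb), math.log(pb)
    return log_p / log_r, log_r / log_p


def _family_block(
    family: str, r: np.ndarray, p: np.ndarray, config: FusionConfig
) -> np.ndarray:
    """|r| x |p| matrix of one fusion family over all (r_i, p_j)."""
    R = r[:, None]
    P = p[None, :]
    if family == "GM":
        return np.sqrt(R * P)
    if family == "HM":
        s = R + P
        out = np.zeros((len(r), len(p)), dtype=np.float64)
        np.divide(2.0 * R * P, s, out=out, where=s > 0)
        return out
    log_r = np.log(_nudge_base(r + config.epsilon, config.log_guard))[:, None]
    log_p = np.log(_nudge_base(p + config.epsilon, config.log_guard))[None, :]
    if family == "PowRP":
        return log_p / log_r
    if family == "PowPR":
        return log_r / log_p
    raise ValueError(f"unknown fusion family {family!r}")


def complex_feature_names(
    rna_names: tuple[str, ...],
    protein_names: tuple[str, ...],
    families: tuple[str, ...] = FAMILIES,
) -> tuple[str, ...]:
    """Names FAMILY:<rna-kmer>:<protein-ngram>, family-major order."""
    return tuple(
        f"{fam}:{rk}:{pk}" for fam in families for rk in rna_names for pk in protein_names
    )


def fuse_values(
    r: np.ndarray, p: np.ndarray, config: FusionConfig, chunk: int = 4096
) -> np.ndarray:
    """Flat fused vector of length |families| * |r| * |p|.

    The protein axis is processed in chunks of ``chunk`` columns so the
    working set stays bounded for large m, n.
    """
    r = np.asarray(r, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if np.any(r < 0) or np.any(p < 0):
        raise ValueError("base frequencies must be non-negative")
    nr, np_ = len(r), len(p)
    out = np.empty(len(config.families) * nr * np_, dtype=np.float64)
    for f, fam in enumerate(config.families):
        block = out[f * nr * np_ : (f + 1) * nr * np_].reshape(nr, np_)
        for j0 in range(0, np_, chunk):
            j1 = min(j0 + chunk, np_)
            block[:, j0:j1] = _family_block(fam, r, p[j0:j1], config)
    return out


def build_complex_vector(
    rbase: BaseFeatureVector,
    pbase: BaseFeatureVector,
    config: FusionConfig = FusionConfig(),
) -> ComplexFeatureVector:
    """Fuse one RNA and one protein base vector into the complex vector."""
    if rbase.kind != "rna" or pbase.kind != "protein":
        raise ValueError("build_complex_vector expects (rna, protein) base vectors")
    values = fuse_values(rbase.values, pbase.values, config)
    names = complex_feature_names(rbase.names, pbase.names, config.families)
    return ComplexFeatureVector(
        pair_id=f"{rbase.owner_id}|{pbase.owner_id}", values=values, names=names
    )


def concat_base_vector(
    rbase: BaseFeatureVector, pbase: BaseFeatureVector
) -> ComplexFeatureVector:
    """Plain concatenation baseline: RNA block then protein block.

    Names are prefixed R:/P:; length 4^m + 7^n.
    """
    values = np.concatenate([rbase.values, pbase.values])
    names = tuple(f"R:{n}" for n in rbase.names) + tuple(
        f"P:{n}" for n in pbase.names
    )
    return ComplexFeatureVector(
        pair_id=f"{rbase.owner_id}|{pbase.owner_id}", values=values, names=names
    )
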