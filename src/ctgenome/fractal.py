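"""Box-counting (Minkowski-Bouligand) fractal dimension of topology matrices.

The topology matrix is binarised — 1 for entangled cells (parallel or
cross), 0 otherwise — and the resulting point set is covered by grids of
boxes of side l = n/2, n/4, ..., 2, 1 on the zero-padded matrix.  The
dimension D is the least-squares slope of log N(l) against log(1/l), where
N(l) is the number of occupied boxes.  Saturated scales (N(l) = 1 or
N(l) = number of set cells) are dropped from the fit to avoid plateau
bias.  Because D correlates with the number of contacts, chromosomes are
compared via the normalised dimension D / N_contacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .ct_core import ENTANGLED, RelationCode, TopologyMatrix
from .errors import InputError, ParameterError


@dataclass(frozen=True)
class BinaryMatrix:
    """Square 0/1 matrix with zero diagonal; ``provenance`` names the codes
    mapped to 1."""

    values: np.ndarray
    provenance: str = "entangled"

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InputError(f"binary matrix must be square, got {v.shape}")
        v = (v != 0).astype(np.uint8)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FractalResult:
    """Box-counting outcome: dimension, per-scale counts, fit diagnostics."""

    D: float
    box_sizes: np.ndarray
    counts: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    warnings: tuple = ()

    def normalized(self, n_contacts: int) -> float:
        return normalized_dimension(self, n_contacts)

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "box_sizes": [int(v) for v in self.box_sizes],
            "counts": [int(v) for v in self.counts],
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "warnings": list(self.warnings),
        }


def binarize_entangled(m: TopologyMatrix, entangled=ENTANGLED) -> BinaryMatrix:
    """1 where the relation code is entangled, else 0 (diagonal stays 0)."""
    return BinaryMatrix(values=m.mask(entangled),
                        provenance="+".join(sorted(RelationCode(c).name
                                                   for c in entangled)))


def _pad_to_pow2(a: np.ndarray) -> np.ndarray:
    n = max(a.shape)
    n_pad = 1 << max(1, (n - 1).bit_length())
    out = np.zeros((n_pad, n_pad), dtype=bool)
    out[: a.shape[0], : a.shape[1]] = a
    return out


def box_count_dimension(b: BinaryMatrix) -> FractalResult:
    """Box-counting dimension of the set of 1-cells.

    The matrix is zero-padded to the next power of two; box sizes run from
    half the padded size down to 1.  The fit uses only scales with
    1 < N(l) < total set cells; a slope outside [0, 2] is clamped with a
    diagnostic warning.  An empty (or single-cell) set has dimension 0.
    """
    a = b.values.astype(bool)
    total = int(a.sum())
    warns = []
    if total == 0:
        warns.append("empty set: dimension defined as 0")
        return FractalResult(0.0, np.array([], int), np.array([], int),
                             0.0, 0.0, 1.0, tuple(warns))
    padded = _pad_to_pow2(a)
    n_pad = padded.shape[0]
    sizes, counts = [], []
    l = n_pad // 2
    while l >= 1:
        k = n_pad // l
        blocks = padded.reshape(k, l, k, l).any(axis=(1, 3))
        sizes.append(l)
        counts.append(int(blocks.sum()))
        l //= 2
    sizes = np.array(sizes, dtype=int)
    counts = np.array(counts, dtype=int)
    valid = (counts > 1) & (counts < total)
    if valid.sum() < 2:
        # a point-like or otherwise degenerate set: no scaling range
        warns.append("degenerate set: fewer than 2 informative scales, D = 0")
        return FractalResult(0.0, sizes, counts, 0.0, 0.0, 1.0, tuple(warns))
    x = np.log(1.0 / sizes[valid])
    y = np.log(counts[valid].astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    D = float(slope)
    if D < 0 or D > 2:
        warns.append(f"raw slope {D:.3f} outside [0, 2]; clamped")
        D = float(np.clip(D, 0.0, 2.0))
    return FractalResult(D, sizes, counts, float(slope), float(intercept),
                         r2, tuple(warns))


def normalized_dimension(f: FractalResult, n_contacts: int) -> float:
    """D / N: dimension normalised by contact count for cross-chromosome
    comparison (chromosome-scale matrices land in the ~1e-3 decade)."""
    if n_contacts < 1:
        raise ParameterError("normalisation requires at least one contact")
    return f.D / n_contacts


def topology_fractal_dimension(m: TopologyMatrix, entangled=ENTANGLED) -> FractalResult:
    """Convenience: binarise a topology matrix and box-count it."""
    return box_count_dimension(binarize_entangled(m, entangled))


def write_fractal_json(f: FractalResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(f.to_dict(), fh, indent=2)
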