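"""Cumulative-window scans of circuit-topology parameters.

A chain is analysed over windows of growing size (5, 10, ..., n-5, n
beads, i.e. 0.5 Mb steps at 100 kb resolution), starting from either chain
end.  Each window keeps only the contacts with both endpoints inside it,
rebuilds the topology matrix and evaluates a metric (entangled fraction or
box-counting dimension).  Smoothing the resulting series and tracking
local maxima by topographic prominence reveals the characteristic length
scale of entanglement fluctuations; for the fractal dimension, the window
beyond which the series stays within a relative tolerance of its
full-chain value marks the onset of scale invariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .chain_io import BEAD_BP, ContactSet, contact_set
from .errors import InputError, ParameterError
from .fractal import topology_fractal_dimension
from .ct_core import build_topology_matrix
from .topo_metrics import entangled_fraction

METRICS = ("entangled_fraction", "fractal_D")


@dataclass(frozen=True)
class WindowSeries:
    """Metric values over cumulative windows (sizes in beads).

    Window sizes are arithmetic with step 5 and always end at the full
    chain length; windows with fewer than 2 contacts carry NaN.
    """

    windows: np.ndarray
    values: np.ndarray
    metric: str
    direction: str = "left_to_right"

    def __post_init__(self):
        w = np.asarray(self.windows, dtype=int)
        v = np.asarray(self.values, dtype=float)
        if w.shape != v.shape or w.ndim != 1:
            raise InputError("windows and values must be equal-length 1D arrays")
        object.__setattr__(self, "windows", w)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values) -> "WindowSeries":
        return WindowSeries(self.windows, values, self.metric, self.direction)


def window_sizes(n_beads: int, step: int = 5) -> np.ndarray:
    """5, 10, ..., up to and always including the full chain length."""
    w = np.arange(step, n_beads + 1, step)
    if len(w) == 0 or w[-1] != n_beads:
        w = np.append(w, n_beads)
    return w.astype(int)


def _restrict(contacts: ContactSet, lo: int, hi: int) -> ContactSet:
    """Contacts with both endpoints in beads [lo, hi)."""
    pairs = [(c.i - lo, c.j - lo) for c in contacts
             if lo <= c.i and c.j < hi]
    return contact_set(pairs, n_beads=max(2, hi - lo), source=contacts.source)


def cumulative_scan(contacts: ContactSet, metric: str = "entangled_fraction",
                    direction: str = "left_to_right", step: int = 5) -> WindowSeries:
    """Evaluate a metric over cumulative windows of the chain.

    ``metric`` is ``"entangled_fraction"`` or ``"fractal_D"``;
    ``direction`` chooses which chain end the windows grow from.  Windows
    with fewer than 2 contacts yield NaN.
    """
    if metric not in METRICS:
        raise ParameterError(f"unknown metric {metric!r}; choose from {METRICS}")
    if direction not in ("left_to_right", "right_to_left"):
        raise ParameterError(f"unknown direction {direction!r}")
    n = contacts.n_beads
    if n < 10:
        raise InputError("cumulative scan needs a chain of at least 10 beads")
    ws = window_sizes(n, step)
    values = np.full(len(ws), np.nan)
    for k, w in enumerate(ws):
        lo, hi = (0, w) if direction == "left_to_right" else (n - w, n)
        sub = _restrict(contacts, lo, hi)
        if len(sub) < 2:
            continue
        m = build_topology_matrix(sub)
        if metric == "entangled_fraction":
            values[k] = entangled_fraction(m)
        else:
            values[k] = topology_fractal_dimension(m).D
    return WindowSeries(ws, values, metric, direction)


def smooth(series: WindowSeries, window: int = 15, degree: int = 2) -> WindowSeries:
    """Local least-squares polynomial smoothing (degree 2, 15-point window).

    At the edges the fit window shrinks symmetrically, so endpoints are
    left unchanged and an exact degree-``degree`` polynomial series is
    reproduced to numerical precision.  Series shorter than ``window`` are
    returned unsmoothed with a warning.
    """
    v = series.values
    n = len(v)
    if n < window:
        import warnings

        warnings.warn(f"series of length {n} shorter than smoothing window "
                      f"{window}; returned unsmoothed")
        return series.with_values(v.copy())
    half = window // 2
    out = v.copy()
    x = np.arange(n, dtype=float)
    for k in range(n):
        h = min(half, k, n - 1 - k)
        if h < 1:
            continue
        sl = slice(k - h, k + h + 1)
        xs, ys = x[sl], v[sl]
        ok = np.isfinite(ys)
        if ok.sum() < 2:
            continue
        deg = min(degree, int(ok.sum()) - 1)
        coef = np.polyfit(xs[ok], ys[ok], deg)
        out[k] = np.polyval(coef, x[k])
    return series.with_values(out)


def find_peaks(series: WindowSeries, prominence: float = 0.2) -> np.ndarray:
    """Window sizes of local maxima with topographic prominence >= threshold.

    NaN stretches (windows with too few contacts) are compressed out
    before peak detection; returned positions are window sizes in beads.
    """
    v = series.values
    finite = np.isfinite(v)
    idx_map = np.flatnonzero(finite)
    if len(idx_map) < 3:
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(v[finite], prominence=prominence)
    return series.windows[idx_map[peaks]]


@dataclass(frozen=True)
class PeakSpacing:
    """Consecutive peak spacings and their modal value."""

    spacings_beads: np.ndarray
    spacings_mb: np.ndarray
    modal_beads: float
    modal_mb: float


def peak_spacing(positions, bin_width: int = 10,
                 bead_bp: int = BEAD_BP) -> PeakSpacing:
    """Spacings between consecutive peaks and their histogram mode.

    The mode is the mean spacing inside the most populated ``bin_width``-bead
    histogram bin (earliest bin on ties).  Requires at least 2 peaks.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        raise InputError("insufficient peaks: need at least 2 for spacings")
    sp = np.diff(np.sort(positions))
    edges = np.arange(0, sp.max() + 2 * bin_width, bin_width)
    hist, _ = np.histogram(sp, bins=edges)
    b = int(np.argmax(hist))
    in_bin = sp[(sp >= edges[b]) & (sp < edges[b + 1])]
    modal = float(in_bin.mean())
    return PeakSpacing(sp, sp * bead_bp / 1e6, modal, modal * bead_bp / 1e6)


def convergence_threshold(series: WindowSeries, tol: float = 0.05):
    """Smallest window beyond which the series stays near its final value.

    Returns ``(window, converged)``: the smallest window size W such that
    every later finite value v(w) satisfies |v(w) - v(n)| / |v(n)| <= tol
    (NaN windows after W also count as violations).  If no plateau exists
    the full chain length is returned with ``converged=False``.
    """
    v = series.values
    ref = v[-1]
    if not np.isfinite(ref) or ref == 0:
        raise InputError("full-chain value undefined; convergence has no reference")
    within = np.isfinite(v) & (np.abs(v - ref) / abs(ref) <= tol)
    # walk back from the end to the smallest W with all later windows within
    k = len(v) - 1
    while k - 1 >= 0 and within[k - 1]:
        k -= 1
    if k == len(v) - 1:
        return int(series.windows[-1]), False  # no plateau before the last window
    return int(series.windows[k]), True


def write_scan(series: WindowSeries, smoothed: WindowSeries | None, path,
               bead_bp: int = BEAD_BP) -> None:
    """TSV export: window_beads, window_Mb, value, smoothed_value."""
    with open(path, "w") as fh:
        fh.write(f"# metric={series.metric} direction={series.direction}\n")
        fh.write("# window_beads\twindow_Mb\tvalue\tsmoothed_value\n")
        sm = smoothed.values if smoothed is not None else series.values
        for w, v, s in zip(series.windows, series.values, sm):
            fh.write(f"{w}\t{w * bead_bp / 1e6:.2f}\t{v:.6f}\t{s:.6f}\n")
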