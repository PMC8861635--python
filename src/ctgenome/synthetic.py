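"""Synthetic chains, contact fixtures and null models.

These generators define the study conditions for everything else in the
package: a confined lattice random walk is the null model against which
chromosome topology is contrasted; trefoil series and the canonical
nine-contact L-loop are the worked motifs; periodic traces and
rho-correlated expression tracks exercise the scan and correlation
pipelines.  All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain_io import BeadChain, ContactSet, contact_set
from .errors import InputError, ParameterError
from .topo_metrics import Trace


@dataclass(frozen=True)
class LatticeBox:
    """Confining box for the lattice walk; wall lengths in particles (>= 2)."""

    x: int
    y: int
    z: int

    def __post_init__(self):
        if min(self.x, self.y, self.z) < 2:
            raise ParameterError("box walls must be at least 2 particles")

    @property
    def walls(self):
        return (self.x, self.y, self.z)


def box_from_chain(chain: BeadChain) -> LatticeBox:
    """Box matching a reference chain's per-axis extent (in particles)."""
    ext = chain.coords.max(axis=0) - chain.coords.min(axis=0)
    walls = [max(2, int(np.ceil(e)) + 1) for e in ext]
    return LatticeBox(*walls)


_MOVES = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                   [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def random_chain(n_steps: int, box: LatticeBox, seed: int,
                 max_restarts: int = 100) -> BeadChain:
    """Random walk on the unit lattice confined to a box.

    The walk starts at a uniformly random in-box site; every step is one of
    the <= 6 axis moves that stays inside the box and does not reverse the
    previous step (the chain may not fold onto itself in two steps).  The
    grid step is one particle (100 kb), matching chromosome bead models.
    ``n_steps`` is the number of beads produced.

    The walk is not self-avoiding; revisits are allowed and are what
    creates contacts under a unit spatial cutoff.
    """
    if n_steps < 2:
        raise ParameterError("need at least 2 beads")
    rng = np.random.default_rng(seed)
    walls = np.array(box.walls)
    for _ in range(max_restarts):
        pos = rng.integers(0, walls)
        path = [pos.copy()]
        prev_move = None
        ok = True
        for _step in range(n_steps - 1):
            cand = []
            for mv in _MOVES:
                if prev_move is not None and (mv == -prev_move).all():
                    continue
                nxt = path[-1] + mv
                if ((nxt >= 0) & (nxt < walls)).all():
                    cand.append(mv)
            if not cand:
                ok = False
                break
            mv = cand[rng.integers(0, len(cand))]
            path.append(path[-1] + mv)
            prev_move = mv
        if ok:
            return BeadChain(label=f"random_seed{seed}",
                             coords=np.array(path, dtype=float))
    raise InputError("random walk dead-ended repeatedly; box too degenerate")


def trefoil_series(k: int) -> ContactSet:
    """``k`` disjoint trefoils in series along the chain.

    Each trefoil is a contact triple {(5t, 5t+2), (5t+2, 5t+4), (5t, 5t+4)}:
    two concerted-series contacts enveloped by a concerted-parallel one,
    closing one triangle in the contact-site graph.  Sites are spaced so
    that contacts respect the first-neighbour exclusion and consecutive
    trefoils share no bead, giving an average clustering coefficient of
    exactly 1.
    """
    if k < 1:
        raise ParameterError("need at least one trefoil")
    pairs = []
    for t in range(k):
        b = 5 * t
        pairs += [(b, b + 2), (b + 2, b + 4), (b, b + 4)]
    return contact_set(pairs, n_beads=5 * (k - 1) + 5, source=("synthetic", None))


def series_contacts(k: int, spacing: int = 3) -> ContactSet:
    """``k`` mutually series contacts with all-distinct endpoints."""
    if k < 1:
        raise ParameterError("need at least one contact")
    pairs = [(spacing * t, spacing * t + 2) for t in range(k)]
    return contact_set(pairs, n_beads=spacing * (k - 1) + 3,
                       source=("synthetic", None))


#: canonical nine-contact L-loop: two turns (c1, c2), pockets (c3, c6, c9),
#: inner turns (c4, c5, c7) and one cross contact (c8) striping c7
LLOOP_CONTACTS = ((0, 120), (1, 119), (2, 12), (14, 110), (15, 109),
                  (16, 26), (28, 100), (50, 112), (60, 70))

LLOOP_N_BEADS = 124


def lloop_fixture() -> ContactSet:
    """The canonical nine-contact L-loop on a 124-bead chain.

    Contact 1 envelops all eight others (outer L-pattern length 8), the
    turn + pocket motif repeats three times ({c1, c2}, {c4, c5}, {c7} head
    three nested L-patterns), and contact 8 crosses the inner loop.
    """
    return contact_set(LLOOP_CONTACTS, n_beads=LLOOP_N_BEADS,
                       source=("synthetic", None))


def lloop_rich_contacts(n_loops: int, seed: int) -> ContactSet:
    """A structured chain tiled with L-loop motifs (jittered copies of the
    canonical fixture laid in series), for contrasts against random chains."""
    if n_loops < 1:
        raise ParameterError("need at least one loop")
    rng = np.random.default_rng(seed)
    pairs = []
    offset = 0
    for _ in range(n_loops):
        jit = rng.integers(0, 3)
        for i, j in LLOOP_CONTACTS:
            pairs.append((offset + i + (jit if i > 0 else 0), offset + j - jit))
        offset += LLOOP_N_BEADS
    return contact_set(pairs, n_beads=offset, source=("synthetic", None))


def periodic_trace(period_beads: int, amplitude: float, noise_sd: float,
                   n: int, seed: int, baseline: float = 0.5) -> Trace:
    """Sinusoid of given period (beads) plus seeded Gaussian noise, >= 0.

    Emulates the periodic fluctuation of cumulative entangled-fraction
    traces; used to validate the smooth -> find_peaks -> peak_spacing
    pipeline.  Requires n >= 3 * period so several peaks fit.
    """
    if period_beads < 10:
        raise ParameterError("period must be at least 10 beads")
    if n < 3 * period_beads:
        raise ParameterError("trace must span at least 3 periods")
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)
    values = baseline + amplitude * np.sin(2 * np.pi * t / period_beads)
    values = values + rng.normal(0.0, noise_sd, size=n)
    return Trace(positions=t, values=np.clip(values, 0.0, None),
                 kind="windowed_fraction")


def synthetic_expression(trace: Trace, rho: float, seed: int,
                         mean: float = 500.0, sd: float = 100.0,
                         chrom: str = "chrS"):
    """Expression track with controlled correlation to a binned trace.

    Per-bin abundance is an affine map of ``rho * z + sqrt(1-rho^2) * eps``
    where z is the standardised trace and eps seeded standard normal;
    negative values are clipped to zero (rare at the default scale).
    """
    from .chain_io import ExpressionTrack

    if not -1.0 <= rho <= 1.0:
        raise ParameterError(f"rho must be in [-1, 1], got {rho}")
    v = np.asarray(trace.values, dtype=float)
    if np.std(v) == 0:
        raise InputError("constant trace cannot seed a correlated track")
    z = (v - v.mean()) / v.std()
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(len(v))
    mix = rho * z + np.sqrt(max(0.0, 1.0 - rho ** 2)) * eps
    abundance = np.clip(mean + sd * mix, 0.0, None)
    if len(trace.positions) > 1:
        width = int(trace.positions[1] - trace.positions[0])
    else:
        width = 1_000_000
    bins = tuple((int(p), int(p) + width, float(a))
                 for p, a in zip(trace.positions, abundance))
    return ExpressionTrack(chrom=chrom, bins=bins)
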