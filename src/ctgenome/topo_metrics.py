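"""First-order entanglement statistics and their sequence projections.

The entangled fraction of a chain is the share of entangled contact pairs
(parallel or cross) among all N(N-1)/2 pairs.  Row sums of the topology
matrix give a per-contact entanglement count, which can be projected onto
the chain sequence (each contact site inherits the counts of the contacts
it participates in), binned at 1 Mb, and correlated with gene-expression
tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chain_io import BEAD_BP, BeadChain, ContactSet, ExpressionTrack
from .ct_core import ENTANGLED, TopologyMatrix
from .errors import InputError, ParameterError


@dataclass(frozen=True)
class Trace:
    """A 1D series of a topological quantity along positions.

    ``positions`` are strictly increasing (bead indices or bp), same length
    as ``values``; ``kind`` names the quantity.
    """

    positions: np.ndarray
    values: np.ndarray
    kind: str = "per_site_entanglement"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.shape != val.shape or pos.ndim != 1:
            raise InputError("positions and values must be equal-length 1D arrays")
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise InputError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    def __len__(self) -> int:
        return len(self.values)


def entangled_fraction(m: TopologyMatrix, entangled=ENTANGLED) -> float:
    """Fraction of unordered contact pairs in an entangled relation.

    Defined for N >= 2 contacts.  By default entangled = {P, P_INV, X};
    pass :data:`~ctgenome.ct_core.ENTANGLED_WITH_CP` to include
    concerted-parallel relations in a sensitivity analysis.
    """
    if m.n < 2:
        raise InputError("entangled fraction undefined for fewer than 2 contacts")
    iu = np.triu_indices(m.n, k=1)
    ent = m.mask(entangled)
    return float(ent[iu].sum() / (m.n * (m.n - 1) / 2))


def contact_entanglement(m: TopologyMatrix, entangled=ENTANGLED) -> np.ndarray:
    """Per-contact entanglement: number of entangled relations on each row."""
    return m.mask(entangled).sum(axis=1).astype(np.int64)


def entanglement_contact_map(m: TopologyMatrix, entangled=ENTANGLED) -> np.ndarray:
    """Contact map (n_beads x n_beads) coloured by per-contact entanglement.

    Cells (i, j) and (j, i) of each contact carry that contact's row count;
    this is a rendering of :func:`contact_entanglement`, not a separate
    statistic.
    """
    counts = contact_entanglement(m, entangled)
    n = m.contacts.n_beads
    out = np.zeros((n, n))
    for c, w in zip(m.contacts, counts):
        out[c.i, c.j] = w
        out[c.j, c.i] = w
    return out


def site_entanglement_trace(contacts: ContactSet, row_counts: np.ndarray) -> Trace:
    """Project per-contact entanglement onto chain positions.

    The value at bead b is the sum of row counts of all contacts having b
    as either endpoint (both endpoints of a contact are credited), so the
    trace total equals twice the sum of row counts.
    """
    row_counts = np.asarray(row_counts)
    if len(row_counts) != len(contacts):
        raise InputError("row_counts length must match the contact set")
    values = np.zeros(contacts.n_beads)
    for c, w in zip(contacts, row_counts):
        values[c.i] += w
        values[c.j] += w
    return Trace(positions=np.arange(contacts.n_beads, dtype=float) * BEAD_BP,
                 values=values, kind="per_site_entanglement")


def bin_trace(trace: Trace, bin_bp: int, bead_bp: int = BEAD_BP) -> Trace:
    """Sum a per-site trace into fixed genomic bins.

    ``bin_bp`` must be a multiple of the bead size (default 100 kb); the
    standard coarse-graining is 1 Mb.  Bin positions are bin start bp.
    """
    if bin_bp < bead_bp or bin_bp % bead_bp:
        raise ParameterError(
            f"bin size {bin_bp} must be a positive multiple of {bead_bp} bp")
    n_bins = int(np.ceil((trace.positions[-1] + bead_bp) / bin_bp)) if len(trace) else 0
    values = np.zeros(max(n_bins, 1))
    idx = (trace.positions // bin_bp).astype(int)
    np.add.at(values, idx, trace.values)
    return Trace(positions=np.arange(len(values), dtype=float) * bin_bp,
                 values=values, kind="binned_" + trace.kind)


def bin_contact_entanglement(contacts: ContactSet, row_counts: np.ndarray,
                             bin_bp: int, bead_bp: int = BEAD_BP) -> Trace:
    """Bin per-contact entanglement by the first contact site.

    Each contact's row count is credited to the bin of its smaller
    endpoint (the contact site that happens first along the sequence).
    """
    if bin_bp < bead_bp or bin_bp % bead_bp:
        raise ParameterError(
            f"bin size {bin_bp} must be a positive multiple of {bead_bp} bp")
    row_counts = np.asarray(row_counts)
    if len(row_counts) != len(contacts):
        raise InputError("row_counts length must match the contact set")
    n_bins = max(1, int(np.ceil(contacts.n_beads * bead_bp / bin_bp)))
    values = np.zeros(n_bins)
    for c, w in zip(contacts, row_counts):
        values[(c.i * bead_bp) // bin_bp] += w
    return Trace(positions=np.arange(n_bins, dtype=float) * bin_bp,
                 values=values, kind="binned_contact_entanglement")


def bin_expression(track: ExpressionTrack, bin_bp: int, n_bins: int) -> np.ndarray:
    """Per-bin gene abundance: sum abundances of genes whose midpoint falls
    in each bin."""
    values = np.zeros(n_bins)
    for s, e, v in track.bins:
        b = int(((s + e) // 2) // bin_bp)
        if 0 <= b < n_bins:
            values[b] += v
    return values


def correlate_with_expression(binned: Trace, track: ExpressionTrack,
                              bin_bp: int = 1_000_000,
                              abundance_floor: float = 50.0):
    """Pearson correlation between a binned entanglement trace and expression.

    Gene abundance is summed per bin by gene midpoint, abundances below
    ``abundance_floor`` (default 50 per Mb) are set to zero, and the
    two-sided Pearson r and p-value are computed over the common bins.
    """
    n_bins = len(binned)
    expr = bin_expression(track, bin_bp, n_bins)
    expr[expr < abundance_floor] = 0.0
    if n_bins < 3:
        raise InputError("need at least 3 common bins for a correlation")
    if np.allclose(np.std(binned.values), 0) or np.allclose(np.std(expr), 0):
        raise InputError("constant input: Pearson correlation undefined")
    r, p = stats.pearsonr(binned.values, expr)
    return float(r), float(p)


def radius_of_gyration(chain: BeadChain) -> float:
    """Root-mean-square distance of beads from their centroid (particle radii)."""
    d = chain.coords - chain.coords.mean(axis=0)
    return float(np.sqrt((d ** 2).sum(axis=1).mean()))


def write_trace(trace: Trace, path, comment: str = "") -> None:
    """Write a trace as TSV ``position  value``."""
    with open(path, "w") as fh:
        fh.write(f"# kind={trace.kind}" + (f" {comment}" if comment else "") + "\n")
        for p, v in zip(trace.positions, trace.values):
            fh.write(f"{p:.0f}\t{v:.6f}\n")
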