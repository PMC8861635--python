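"""Input/output for bead chains, contact sets and expression tracks.

Chromosomes are modelled as bead-on-a-string polymers at 100 kb resolution:
one bead per 100 kb, coordinates in units of particle radii.  Contacts are
pairs of non-adjacent beads that lie closer than a spatial cutoff ``r_c``
(for 3D models) or whose Hi-C count exceeds a threshold (for contact maps).
Contacts between first neighbours (|i - j| <= 1) are always excluded.

Bead indices are 0-based throughout the library; files written or read by
this module use 1-based indices, noted in their headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InputError, ParameterError, ParseError

#: genomic span of one bead (bp)
BEAD_BP = 100_000

#: spatial cutoffs (particle radii) explored in the analyses; 1.0 is the default
SUPPORTED_CUTOFFS = (0.5, 1.0, 1.5, 2.0)

#: default Hi-C count threshold for calling a contact from a population map
DEFAULT_HIC_THRESHOLD = 250


@dataclass(frozen=True)
class BeadChain:
    """An ordered 3D bead chain for one chromosome.

    Parameters
    ----------
    label : str
        Chromosome (or fixture) name.
    coords : numpy.ndarray, shape (n_beads, 3)
        Bead coordinates in particle radii; bead *k* covers the *k*-th
        100 kb of sequence.
    """

    label: str
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError(f"coords must be (n, 3), got {coords.shape}")
        if coords.shape[0] < 2:
            raise InputError("a chain needs at least 2 beads")
        if not np.isfinite(coords).all():
            raise InputError("non-finite coordinate in chain")
        object.__setattr__(self, "coords", coords)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True, order=True)
class Contact:
    """A binary contact between beads ``i < j`` with ``j >= i + 2``."""

    i: int
    j: int

    def __post_init__(self):
        if self.i < 0:
            raise InputError(f"negative bead index in contact ({self.i}, {self.j})")
        if self.j <= self.i + 1:
            raise InputError(
                f"contact ({self.i}, {self.j}) violates first-neighbour exclusion"
            )

    @property
    def span(self) -> int:
        return self.j - self.i


@dataclass(frozen=True)
class ContactSet:
    """Sorted, deduplicated contacts on a chain of ``n_beads`` beads.

    ``source`` records provenance: ``("spatial_cutoff", r_c)``,
    ``("count_threshold", t)`` or ``("synthetic", None)``.
    """

    contacts: tuple
    n_beads: int
    source: tuple = ("synthetic", None)

    def __post_init__(self):
        cs = tuple(sorted(set(self.contacts)))
        for c in cs:
            if c.j >= self.n_beads:
                raise InputError(
                    f"contact ({c.i}, {c.j}) outside chain of {self.n_beads} beads"
                )
        object.__setattr__(self, "contacts", cs)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    @property
    def pairs(self) -> np.ndarray:
        """(N, 2) integer array of (i, j) endpoints in sorted order."""
        if not self.contacts:
            return np.empty((0, 2), dtype=np.int64)
        return np.array([(c.i, c.j) for c in self.contacts], dtype=np.int64)


def contact_set(pairs: Iterable[tuple], n_beads: int,
                source: tuple = ("synthetic", None)) -> ContactSet:
    """Build a :class:`ContactSet` from (i, j) index pairs."""
    return ContactSet(tuple(Contact(int(i), int(j)) for i, j in pairs),
                      n_beads=n_beads, source=source)


@dataclass(frozen=True)
class ExpressionTrack:
    """Per-interval gene abundance along one chromosome.

    ``bins`` is a list of ``(start_bp, end_bp, abundance)`` with 0-based
    half-open coordinates, sorted and non-overlapping.
    """

    chrom: str
    bins: tuple

    def __post_init__(self):
        bins = tuple(sorted((int(s), int(e), float(v)) for s, e, v in self.bins))
        for s, e, v in bins:
            if e <= s:
                raise InputError(f"empty or inverted bin [{s}, {e})")
            if v < 0:
                raise InputError(f"negative abundance {v} in bin [{s}, {e})")
        for (s1, e1, _), (s2, e2, _) in zip(bins, bins[1:]):
            if s2 < e1:
                raise InputError(
                    f"overlapping bins [{s1}, {e1}) and [{s2}, {e2})"
                )
        object.__setattr__(self, "bins", bins)

    def __len__(self) -> int:
        return len(self.bins)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_chain(path, label: str | None = None) -> BeadChain:
    """Read a bead chain from a whitespace/TSV coordinate table.

    Columns are ``[label] x y z``; an optional single header line is skipped.
    Row *k* becomes bead *k* (0-based).
    """
    path = Path(path)
    rows: list[list[float]] = []
    file_label = label
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 4:
                lab, *xyz = parts
            elif len(parts) == 3:
                lab, xyz = None, parts
            else:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 3 or 4 columns, got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in xyz])
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # header line
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric coordinate in {parts!r}"
                ) from None
            if lab is not None and file_label is None:
                file_label = lab
    if len(rows) < 2:
        raise InputError(f"{path.name}: a chain needs at least 2 beads, got {len(rows)}")
    return BeadChain(label=file_label or path.stem, coords=np.array(rows))


def write_chain(chain: BeadChain, path) -> None:
    """Write a chain as a 4-column TSV (label, x, y, z)."""
    with open(path, "w") as fh:
        for x, y, z in chain.coords:
            fh.write(f"{chain.label}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def write_contacts(contacts: ContactSet, path, chrom: str = "chr") -> None:
    """Write contacts as TSV ``chrom  i  j`` with 1-based indices."""
    src, val = contacts.source
    with open(path, "w") as fh:
        fh.write(f"# n_beads={contacts.n_beads} source={src} param={val}\n")
        fh.write("# 1-based bead indices\n")
        for c in contacts:
            fh.write(f"{chrom}\t{c.i + 1}\t{c.j + 1}\n")


def read_contacts(path) -> ContactSet:
    """Read a contact TSV written by :func:`write_contacts`."""
    path = Path(path)
    n_beads = None
    source = ("synthetic", None)
    pairs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("n_beads="):
                        n_beads = int(tok.split("=", 1)[1])
                    elif tok.startswith("source="):
                        source = (tok.split("=", 1)[1], source[1])
                    elif tok.startswith("param=") and tok != "param=None":
                        source = (source[0], float(tok.split("=", 1)[1]))
                continue
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path.name}:{lineno}: expected 3 columns")
            try:
                i, j = int(parts[1]) - 1, int(parts[2]) - 1
            except ValueError:
                raise ParseError(f"{path.name}:{lineno}: non-integer index") from None
            pairs.append((i, j))
    if n_beads is None:
        n_beads = (max(j for _, j in pairs) + 1) if pairs else 2
    return contact_set(pairs, n_beads=n_beads, source=source)


def read_expression(path) -> ExpressionTrack:
    """Read a BED-like 4-column TSV (chrom, start, end, abundance)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "abundance"])
    if df.empty:
        raise InputError(f"{path}: empty expression track")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise InputError(f"{path}: expected a single chromosome, got {list(chroms)}")
    return ExpressionTrack(chrom=str(chroms[0]),
                           bins=tuple(zip(df["start"], df["end"], df["abundance"])))


def write_expression(track: ExpressionTrack, path) -> None:
    with open(path, "w") as fh:
        for s, e, v in track.bins:
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.6f}\n")


# ---------------------------------------------------------------------------
# contact extraction
# ---------------------------------------------------------------------------

def extract_contacts(chain: BeadChain, r_c: float = 1.0) -> ContactSet:
    """Identify contacts in a 3D chain under a spatial cutoff.

    A contact (i, j) is called when the Euclidean distance between beads i
    and j is <= ``r_c`` (inclusive) and j >= i + 2 (first neighbours are
    never contacts).  The result is invariant under rigid motions of the
    chain and monotone in ``r_c``.

    Parameters
    ----------
    chain : BeadChain
    r_c : float
        Spatial cutoff in particle radii (> 0); the reference analyses use
        0.5, 1.0, 1.5 and 2.0, with 1.0 as the default.
    """
    if r_c <= 0:
        raise ParameterError(f"cutoff must be positive, got {r_c}")
    tree = cKDTree(chain.coords)
    # cKDTree.query_pairs uses distance <= r; pad by a tiny epsilon so that
    # exact-grid distances (lattice chains) are robust to rounding
    eps = 1e-9 * max(1.0, r_c)
    pairs = tree.query_pairs(r=r_c + eps, output_type="ndarray")
    keep = pairs[pairs[:, 1] - pairs[:, 0] >= 2]
    return contact_set(map(tuple, keep), n_beads=chain.n_beads,
                       source=("spatial_cutoff", r_c))


def contacts_from_hic(matrix, threshold: float = DEFAULT_HIC_THRESHOLD,
                      bin_bp: int = BEAD_BP) -> ContactSet:
    """Call contacts from a Hi-C count matrix by thresholding counts.

    ``matrix`` may be a dense square array or an (M, 3) COO triplet array
    ``(bin_i, bin_j, count)``.  Upper-triangular storage is accepted; the
    matrix is symmetrised by the element-wise maximum of mirror entries and
    then validated.  A contact is called for every bin pair with
    count >= ``threshold`` and |i - j| > 1; the contact coordinate is the
    bin index (genomically, the bin midpoint).
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim == 2 and a.shape[1] == 3 and a.shape[0] != a.shape[1]:
        # COO triplets
        ii = a[:, 0].astype(int)
        jj = a[:, 1].astype(int)
        n = int(max(ii.max(), jj.max())) + 1
        dense = np.zeros((n, n))
        for i, j, v in zip(ii, jj, a[:, 2]):
            dense[i, j] = max(dense[i, j], v)
        a = dense
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InputError(f"Hi-C matrix must be square, got shape {a.shape}")
    if (a < 0).any():
        raise InputError("Hi-C matrix has negative counts")
    sym = np.maximum(a, a.T)
    # reject genuinely asymmetric inputs (both triangles populated, unequal)
    both = (a > 0) & (a.T > 0)
    if not np.allclose(a[both], a.T[both]):
        raise InputError("Hi-C matrix is asymmetric beyond triangular storage")
    iu, ju = np.triu_indices_from(sym, k=2)
    mask = sym[iu, ju] >= threshold
    cs = contact_set(zip(iu[mask], ju[mask]), n_beads=sym.shape[0],
                     source=("count_threshold", float(threshold)))
    return cs


def read_hic_dense(path) -> np.ndarray:
    """Read a dense whitespace-separated Hi-C count matrix."""
    return np.loadtxt(path)


def read_hic_coo(path) -> np.ndarray:
    """Read COO triplets ``i j count`` (0-based bins)."""
    a = np.loadtxt(path)
    if a.ndim == 1:
        a = a[None, :]
    if a.shape[1] != 3:
        raise InputError(f"COO file must have 3 columns, got {a.shape[1]}")
    return a
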