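"""Pairwise circuit-topology relations and the topology matrix.

Circuit topology classifies every ordered pair of intra-chain contacts,
viewed as closed integer intervals [i, j] and [r, s] of bead indices, into
one of:

* ``S``   (series): the intervals are disjoint.
* ``P`` / ``P_INV`` (parallel / inverse parallel): one interval is strictly
  contained in the open interior of the other; the inner contact is P with
  respect to the outer, the outer is P_INV.
* ``X``   (cross): the intervals overlap without containment.
* ``CS`` / ``CP`` / ``CP_INV`` (concerted): the two contacts share exactly
  one contact site.  CS when the intervals meet only at the shared site,
  CP/CP_INV when one interval contains the other with a common endpoint.

Concerted relations take precedence: whenever a site is shared, the pair is
CS or CP(_INV), never S/P/X.  Classification is total and exclusive on all
admissible pairs of distinct contacts.

The topology matrix is N x N over the N contacts of a chain, indexed in
(i, j)-sorted order (contacts numbered by scanning the chain left to
right); the diagonal carries ``NONE`` and is excluded from every statistic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .chain_io import Contact, ContactSet
from .errors import DuplicateContactError, InputError


class RelationCode(enum.IntEnum):
    """Relation codes; integer values are the on-disk export convention."""

    NONE = 0
    S = 1
    P = 2
    P_INV = 3
    X = 4
    CS = 5
    CP = 6
    CP_INV = 7


#: default entangled set: parallel and cross promote local compaction;
#: series and concerted relations do not count as entangled
ENTANGLED = frozenset({RelationCode.P, RelationCode.P_INV, RelationCode.X})

#: entangled set extended with concerted-parallel, for sensitivity analyses
ENTANGLED_WITH_CP = ENTANGLED | {RelationCode.CP, RelationCode.CP_INV}


def classify_pair(a: Contact, b: Contact) -> RelationCode:
    """Classify the circuit-topology relation of contact ``a`` toward ``b``.

    Returns the code of *a relative to b*: ``P`` means *a* is enveloped by
    *b*; ``P_INV`` means *a* envelops *b* (and symmetrically for CP).
    S, X and CS are symmetric.

    Raises
    ------
    DuplicateContactError
        If the two contacts are identical (relations are defined only on
        distinct contacts; the diagonal of the topology matrix is excluded).
    """
    i, j = a.i, a.j
    r, s = b.i, b.j
    if (i, j) == (r, s):
        raise DuplicateContactError(f"duplicate contact ({i}, {j})")
    if i == s or j == r:
        return RelationCode.CS          # intervals touch only at the shared site
    if i == r or j == s:
        # containment with one shared endpoint; shorter interval is inner
        return RelationCode.CP if (j - i) < (s - r) else RelationCode.CP_INV
    if j < r or s < i:
        return RelationCode.S
    if r < i and j < s:
        return RelationCode.P
    if i < r and s < j:
        return RelationCode.P_INV
    return RelationCode.X


@dataclass(frozen=True)
class TopologyMatrix:
    """N x N relation codes over a contact set; diagonal is ``NONE``."""

    codes: np.ndarray
    contacts: ContactSet

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=np.int8)
        n = len(self.contacts)
        if codes.shape != (n, n):
            raise InputError(f"codes shape {codes.shape} != ({n}, {n})")
        object.__setattr__(self, "codes", codes)

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    def mask(self, codes) -> np.ndarray:
        """Boolean matrix marking cells whose code is in ``codes``."""
        lut = np.zeros(8, dtype=bool)
        for c in codes:
            lut[int(c)] = True
        return lut[self.codes]


def build_topology_matrix(contacts: ContactSet) -> TopologyMatrix:
    """Build the full topology matrix of a contact set.

    ``codes[a, b] == classify_pair(contact_a, contact_b)`` for ``a != b``,
    with contacts in (i, j)-sorted order; the diagonal is ``NONE``.
    Classification is vectorised; :func:`classify_pair` is the scalar
    reference it must agree with.
    """
    if len(contacts) == 0:
        raise InputError("no contacts: topology matrix is undefined")
    p = contacts.pairs
    I, J = p[:, 0][:, None], p[:, 1][:, None]      # rows: contact a
    R, S = p[:, 0][None, :], p[:, 1][None, :]      # cols: contact b
    codes = np.full((len(contacts), len(contacts)), RelationCode.X, dtype=np.int8)
    shared_touch = (I == S) | (J == R)
    shared_end = (I == R) | (J == S)
    inner = (J - I) < (S - R)
    codes[(J < R) | (S < I)] = RelationCode.S
    codes[(R < I) & (J < S)] = RelationCode.P
    codes[(I < R) & (S < J)] = RelationCode.P_INV
    codes[shared_touch] = RelationCode.CS
    codes[shared_end & inner] = RelationCode.CP
    codes[shared_end & ~inner] = RelationCode.CP_INV
    np.fill_diagonal(codes, RelationCode.NONE)
    return TopologyMatrix(codes=codes, contacts=contacts)


def relation_counts(m: TopologyMatrix) -> dict:
    """Count relations over the N(N-1)/2 unordered contact pairs.

    P/P_INV collapse to one parallel pair and CP/CP_INV to one
    concerted-parallel pair, so counts sum to N(N-1)/2.
    """
    iu = np.triu_indices(m.n, k=1)
    upper = m.codes[iu]
    counts = {"S": 0, "P": 0, "X": 0, "CS": 0, "CP": 0}
    fold = {RelationCode.S: "S", RelationCode.P: "P", RelationCode.P_INV: "P",
            RelationCode.X: "X", RelationCode.CS: "CS",
            RelationCode.CP: "CP", RelationCode.CP_INV: "CP"}
    for code in upper:
        counts[fold[RelationCode(int(code))]] += 1
    return counts


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_topology_tsv(m: TopologyMatrix, path) -> None:
    """Export integer relation codes as TSV (S=1, P=2, P_INV=3, X=4, CS=5,
    CP=6, CP_INV=7, NONE=0)."""
    header = ("# topology matrix codes: NONE=0 S=1 P=2 P_INV=3 X=4 "
              "CS=5 CP=6 CP_INV=7")
    np.savetxt(path, m.codes, fmt="%d", delimiter="\t", header=header[2:])


def write_topology_tiff(m: TopologyMatrix, path) -> None:
    """Export the code matrix as an 8-bit grayscale TIFF (same code map)."""
    import tifffile

    tifffile.imwrite(path, m.codes.astype(np.uint8))


def read_topology_tiff(path) -> np.ndarray:
    """Read an 8-bit code (or binary) matrix from TIFF."""
    import tifffile

    return np.asarray(tifffile.imread(path))
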