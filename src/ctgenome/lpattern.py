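"""L-pattern and L-loop profiling of the topology matrix.

An *L-pattern* is the elongated, parallel-dominated feature a looping
structure leaves along the topology-matrix diagonal, possibly striped by
cross contacts.  The generating fold, the *L-loop*, consists of one or
more enveloping *turns*, small nested *pockets*, and occasional cross
contacts where the loop meets other chain segments.

The length of a contact's L-pattern is the number of entangled relations
on its row counted rightward from the diagonal, so every entangled pair is
attributed exactly once (to its earlier contact) and the lengths sum to
the total number of entangled pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain_io import ContactSet
from .ct_core import ENTANGLED, RelationCode, TopologyMatrix
from .errors import InputError, ParameterError
from .fractal import BinaryMatrix, binarize_entangled


def lpattern_lengths(m: TopologyMatrix, entangled=ENTANGLED) -> np.ndarray:
    """Per-contact L-pattern length: entangled codes right of the diagonal."""
    ent = m.mask(entangled)
    return np.triu(ent, k=1).sum(axis=1).astype(np.int64)


def split_components(m: TopologyMatrix):
    """Split the entangled set into its parallel and cross components.

    Returns (parallel-only, cross-only) binary matrices whose union is the
    binarised entangled matrix.
    """
    par = BinaryMatrix(m.mask({RelationCode.P, RelationCode.P_INV}),
                       provenance="P+P_INV")
    cro = BinaryMatrix(m.mask({RelationCode.X}), provenance="X")
    return par, cro


def turn_groups(m: TopologyMatrix, min_enveloped: int = 2) -> list:
    """Group turn contacts into nested L-patterns, outermost first.

    A *turn* is a contact whose L-pattern length (entangled relations from
    the diagonal rightward) is at least ``min_enveloped``.  Consecutive
    turns are grouped when they are adjacent in chain order and the earlier
    directly envelops the later, with no non-turn contact between them;
    each group heads one nested L-pattern.  Returns a list of lists of
    0-based contact indices.
    """
    lengths = lpattern_lengths(m)
    is_turn = lengths >= min_enveloped
    groups: list[list[int]] = []
    current: list[int] = []
    for c in range(m.n):
        if not is_turn[c]:
            if current:
                groups.append(current)
                current = []
            continue
        if current:
            prev = current[-1]
            envelops = (c == prev + 1 and m.codes[prev, c]
                        in (RelationCode.P_INV, RelationCode.CP_INV))
            if envelops:
                current.append(c)
                continue
            groups.append(current)
        current = [c]
    if current:
        groups.append(current)
    return groups


@dataclass(frozen=True)
class LProfile:
    """L-pattern profile of one chain: lengths, turn groups, barcode."""

    lengths: np.ndarray
    groups: list
    barcode: np.ndarray


def segment_barcode(lengths: np.ndarray, contacts: ContactSet,
                    n_segments: int = 4) -> np.ndarray:
    """Per-segment sums of L-pattern lengths ("chromosome barcode").

    The chain is split into ``n_segments`` segments of equal bead count
    (remainder beads join the last segment); each contact's length is
    credited to the segment containing its smaller endpoint.  Four and
    eight segments are the standard resolutions.
    """
    if n_segments < 2:
        raise ParameterError("need at least 2 segments")
    if n_segments > contacts.n_beads:
        raise ParameterError(
            f"{n_segments} segments exceed the {contacts.n_beads}-bead chain")
    lengths = np.asarray(lengths)
    if len(lengths) != len(contacts):
        raise InputError("lengths must match the contact set")
    seg_len = contacts.n_beads // n_segments
    out = np.zeros(n_segments, dtype=np.int64)
    for c, w in zip(contacts, lengths):
        out[min(c.i // seg_len, n_segments - 1)] += w
    return out


def maxima_position(barcode: np.ndarray):
    """1-based index of the maximal barcode segment (smallest on ties).

    Returns ``None`` when the barcode is all zero (no L-loops to locate).
    """
    barcode = np.asarray(barcode)
    if len(barcode) == 0:
        raise InputError("empty barcode")
    if (barcode == 0).all():
        return None
    return int(np.argmax(barcode)) + 1


def quantile_split(lengths):
    """Split nonzero L-pattern lengths at their median.

    Returns ``(below, above)`` as sorted lists: below = lengths strictly
    under the median, above = lengths at or over it (an odd count's median
    element goes to 'above').
    """
    nz = sorted(v for v in np.asarray(lengths).ravel().tolist() if v > 0)
    if len(nz) < 2:
        raise InputError("need at least 2 nonzero lengths to split")
    med = float(np.median(nz))
    below = [v for v in nz if v < med]
    above = [v for v in nz if v >= med]
    return below, above


def lprofile(m: TopologyMatrix, n_segments: int = 4,
             min_enveloped: int = 2) -> LProfile:
    """Full L-pattern profile of a topology matrix."""
    lengths = lpattern_lengths(m)
    return LProfile(lengths=lengths,
                    groups=turn_groups(m, min_enveloped),
                    barcode=segment_barcode(lengths, m.contacts, n_segments))


def write_profile(profile: LProfile, path) -> None:
    """TSV: per-contact L-pattern lengths (matrix profile), then barcode."""
    with open(path, "w") as fh:
        fh.write("# contact_index(1-based)\tlpattern_length\n")
        for k, v in enumerate(profile.lengths, start=1):
            fh.write(f"{k}\t{v}\n")
        fh.write("# barcode: " + "\t".join(str(int(v)) for v in profile.barcode) + "\n")
        fh.write("# turn_groups: " +
                 "; ".join(",".join(str(c + 1) for c in g) for g in profile.groups) +
                 "\n")
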