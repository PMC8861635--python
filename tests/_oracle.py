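"""Independent straight-line classifiers used as oracles by the tests.

Everything here works on explicit Python sets of bead indices — no shared
code with the library's interval arithmetic — so agreement between the two
routes is a genuine cross-check.
"""

import numpy as np


def oracle_classify(a, b):
    """Set-algebra relation classifier over closed integer intervals."""
    i, j = a
    r, s = b
    if (i, j) == (r, s):
        raise ValueError("duplicate contact")
    A = set(range(i, j + 1))
    B = set(range(r, s + 1))
    inter = A & B
    shared_sites = {i, j} & {r, s}
    if shared_sites:
        if inter == {i} or inter == {j}:
            return "CS"
        return "CP" if A < B else "CP_INV"
    if not inter:
        return "S"
    if A < B:
        return "P"
    if B < A:
        return "P_INV"
    return "X"


def admissible_pairs(max_bead):
    """All ordered pairs of distinct admissible contacts with endpoints in
    {0..max_bead}."""
    contacts = [(i, j) for i in range(max_bead + 1)
                for j in range(i + 2, max_bead + 1)]
    for a in contacts:
        for b in contacts:
            if a != b:
                yield a, b


def random_contact_pairs(n, max_bead, rng):
    """n random ordered pairs of distinct admissible contacts."""
    out = []
    while len(out) < n:
        i, r = rng.integers(0, max_bead - 1, size=2)
        j = rng.integers(i + 2, max_bead + 1)
        s = rng.integers(r + 2, max_bead + 1)
        if (i, j) != (r, s):
            out.append(((int(i), int(j)), (int(r), int(s))))
    return out


def random_contact_set_pairs(rng, n_beads=60, max_contacts=25):
    """A random deduplicated admissible contact list on an n_beads chain."""
    k = int(rng.integers(2, max_contacts + 1))
    pairs = set()
    while len(pairs) < k:
        i = int(rng.integers(0, n_beads - 2))
        j = int(rng.integers(i + 2, n_beads))
        pairs.add((i, j))
    return sorted(pairs)


def oracle_entangled_pairs(pairs):
    """Number of unordered entangled (P/P_INV/X) pairs, by the oracle."""
    ent = 0
    for x in range(len(pairs)):
        for y in range(x + 1, len(pairs)):
            if oracle_classify(pairs[x], pairs[y]) in ("P", "P_INV", "X"):
                ent += 1
    return ent
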