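"""Classify circuit-topology relations between pairs of chain contacts.

Each contact is an arc (i, j) on the bead chain; every pair of contacts is
in exactly one relation: series (disjoint arcs), parallel (nested),
cross (overlapping), or a concerted variant when a contact site is shared.
"""

from ctgenome import build_topology_matrix, classify_pair, contact_set
from ctgenome.chain_io import Contact

pairs = [
    ((1, 5), (7, 9)),    # disjoint          -> series
    ((3, 7), (1, 9)),    # nested            -> parallel (inner first)
    ((1, 5), (3, 9)),    # overlapping       -> cross
    ((1, 5), (5, 9)),    # shared site, touching -> concerted series
    ((1, 5), (1, 9)),    # shared endpoint, nested -> concerted parallel
]

print("pairwise relations:")
for a, b in pairs:
    code = classify_pair(Contact(*a), Contact(*b))
    print(f"  {a} vs {b}: {code.name}")

# A full topology matrix for a small contact set: rows and columns are
# contacts in chain order, each cell the relation of the row contact
# toward the column contact (diagonal excluded).
cs = contact_set([(0, 8), (2, 6), (10, 14)], n_beads=16)
m = build_topology_matrix(cs)
print("\ntopology matrix codes (0=NONE 1=S 2=P 3=P_INV 4=X):")
print(m.codes)
print("\nContact (2,6) is nested inside (0,8) (P/P_INV mirror pair) and")
print("both are in series with (10,14): one entangled pair out of three.")
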