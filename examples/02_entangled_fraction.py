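"""Entangled fraction of a fold and its projection onto the sequence.

Runs the first-order analysis on the canonical nine-contact L-loop: the
share of contact pairs in parallel/cross relation, the per-contact row
counts, and the per-bead entanglement trace binned at 1 Mb.
"""

import numpy as np

from ctgenome import (bin_trace, build_topology_matrix, contact_entanglement,
                      correlate_with_expression, entangled_fraction,
                      lloop_fixture, site_entanglement_trace,
                      synthetic_expression)

cs = lloop_fixture()
m = build_topology_matrix(cs)

frac = entangled_fraction(m)
rows = contact_entanglement(m)
print(f"contacts: {len(cs)} on a {cs.n_beads}-bead (12.4 Mb) chain")
print(f"entangled fraction: {frac:.3f}  "
      f"({rows.sum() // 2} of {m.n * (m.n - 1) // 2} contact pairs)")
print(f"per-contact entangled relations: {rows.tolist()}")

trace = site_entanglement_trace(cs, rows)
binned = bin_trace(trace, 1_000_000)
print(f"1 Mb binned entanglement trace: {binned.values.astype(int).tolist()}")

# couple the binned trace to a synthetic expression track with a planted
# correlation of 0.6, then recover it
track = synthetic_expression(binned, rho=0.6, seed=42)
r, p = correlate_with_expression(binned, track, abundance_floor=0.0)
print(f"planted rho = 0.6, recovered Pearson r = {r:.2f} (p = {p:.3f})")
print("High bins mark sequence regions whose contacts are heavily "
      "entangled; the correlation mimics the entanglement-expression "
      "coupling seen in real data.")
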