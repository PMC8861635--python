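import numpy as np
import pytest

from ctgenome import (BeadChain, Trace, bin_contact_entanglement, bin_trace,
                      build_topology_matrix, contact_entanglement, contact_set,
                      correlate_with_expression, entangled_fraction,
                      radius_of_gyration, site_entanglement_trace,
                      synthetic_expression)
from ctgenome.ct_core import ENTANGLED_WITH_CP
from ctgenome.errors import InputError, ParameterError

from _oracle import oracle_entangled_pairs, random_contact_set_pairs

MB = 1_000_000


def matrix_of(pairs, n_beads):
    return build_topology_matrix(contact_set(pairs, n_beads=n_beads))


class TestEntangledFraction:
    def test_pure_series_is_zero(self):
        assert entangled_fraction(matrix_of([(0, 3), (4, 7)], 8)) == 0.0

    def test_single_crossing_pair_is_one(self):
        assert entangled_fraction(matrix_of([(0, 4), (2, 6)], 7)) == 1.0

    def test_lloop_fixture(self, lloop_matrix):
        assert entangled_fraction(lloop_matrix) == pytest.approx(27 / 36)

    def test_undefined_below_two_contacts(self):
        with pytest.raises(InputError):
            entangled_fraction(matrix_of([(0, 3)], 4))

    def test_matches_oracle_on_random_sets(self, rng):
        for _ in range(20):
            pairs = random_contact_set_pairs(rng)
            m = matrix_of(pairs, 60)
            expected = oracle_entangled_pairs(pairs) / (m.n * (m.n - 1) / 2)
            assert entangled_fraction(m) == pytest.approx(expected)

    def test_row_sum_identity(self, rng, lloop_matrix):
        """entangled_fraction == sum(row counts) / (N(N-1)): each pair is
        counted on two rows."""
        for m in [lloop_matrix] + [matrix_of(random_contact_set_pairs(rng), 60)
                                   for _ in range(5)]:
            rows = contact_entanglement(m)
            assert entangled_fraction(m) == pytest.approx(
                rows.sum() / (m.n * (m.n - 1)))

    def test_adding_series_contact_decreases_fraction(self, lloop):
        pairs = [(c.i, c.j) for c in lloop]
        base = entangled_fraction(matrix_of(pairs, 140))
        extended = entangled_fraction(matrix_of(pairs + [(130, 135)], 140))
        assert extended < base

    def test_concerted_set_changes_fraction_of_trefoil(self, trefoils5):
        m = build_topology_matrix(trefoils5)
        assert entangled_fraction(m) == 0.0
        assert entangled_fraction(m, ENTANGLED_WITH_CP) > 0.0


class TestContactEntanglement:
    def test_pure_series_rows_are_zero(self):
        assert contact_entanglement(matrix_of([(0, 3), (4, 7)], 8)).tolist() == [0, 0]

    def test_single_crossing_pair(self):
        assert contact_entanglement(matrix_of([(0, 4), (2, 6)], 7)).tolist() == [1, 1]

    def test_lloop_row_counts(self, lloop_matrix):
        # frozen from the set-algebra oracle over all 36 pairs
        assert contact_entanglement(lloop_matrix).tolist() == \
            [8, 8, 2, 7, 7, 4, 6, 6, 6]


class TestSiteTrace:
    def test_uncontacted_bead_is_zero(self):
        cs = contact_set([(0, 4), (2, 6)], n_beads=8)
        trace = site_entanglement_trace(cs, contact_entanglement(
            build_topology_matrix(cs)))
        assert trace.values[7] == 0
        assert trace.values[[0, 4, 2, 6]].tolist() == [1, 1, 1, 1]

    def test_lloop_bead0_carries_outer_row_count(self, lloop, lloop_matrix):
        trace = site_entanglement_trace(lloop, contact_entanglement(lloop_matrix))
        assert trace.values[0] == 8

    def test_total_is_twice_row_sum(self, rng):
        for _ in range(10):
            cs = contact_set(random_contact_set_pairs(rng), n_beads=60)
            rows = contact_entanglement(build_topology_matrix(cs))
            trace = site_entanglement_trace(cs, rows)
            assert trace.values.sum() == 2 * rows.sum()


class TestBinning:
    def test_uniform_trace_bins_to_sums(self):
        trace = Trace(np.arange(20) * 100_000.0, np.ones(20))
        binned = bin_trace(trace, MB)
        assert binned.values.tolist() == [10.0, 10.0]

    def test_contact_credited_to_first_site_bin(self):
        cs = contact_set([(5, 95)], n_beads=100)
        binned = bin_contact_entanglement(cs, np.array([3.0]), MB)
        assert binned.values[0] == 3.0
        assert binned.values[1:].sum() == 0

    def test_zero_trace_gives_zero_bins(self):
        trace = Trace(np.arange(20) * 100_000.0, np.zeros(20))
        assert bin_trace(trace, MB).values.sum() == 0

    def test_bin_smaller_than_bead_rejected(self):
        trace = Trace(np.arange(20) * 100_000.0, np.ones(20))
        with pytest.raises(ParameterError):
            bin_trace(trace, 50_000)


class TestExpressionCorrelation:
    def _binned(self, n, rng):
        return Trace(np.arange(n, dtype=float) * MB,
                     rng.uniform(0, 100, size=n), kind="binned")

    def test_exact_linear_transform_gives_r_one(self, rng):
        binned = self._binned(50, rng)
        track = synthetic_expression(binned, rho=1.0, seed=1)
        r, p = correlate_with_expression(binned, track, abundance_floor=0.0)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_planted_rho_recovered(self, rng):
        binned = self._binned(200, rng)
        track = synthetic_expression(binned, rho=0.6, seed=7)
        r, _ = correlate_with_expression(binned, track, abundance_floor=0.0)
        assert abs(r - 0.6) < 0.15

    def test_constant_track_rejected(self, rng):
        binned = self._binned(10, rng)
        track = synthetic_expression(binned, rho=0.0, seed=3)
        flat = type(track)(chrom=track.chrom,
                           bins=tuple((s, e, 5.0) for s, e, _ in track.bins))
        with pytest.raises(InputError):
            # floor forces every abundance to zero -> constant input
            correlate_with_expression(binned, flat, abundance_floor=10.0)

    def test_too_few_bins_rejected(self, rng):
        binned = self._binned(2, rng)
        track = synthetic_expression(binned, rho=0.5, seed=3)
        with pytest.raises(InputError):
            correlate_with_expression(binned, track)


class TestRadiusOfGyration:
    def test_coincident_beads(self):
        chain = BeadChain("c", np.zeros((5, 3)) + 2.0)
        assert radius_of_gyration(chain) == 0.0

    def test_two_beads_at_distance_two(self):
        chain = BeadChain("c", np.array([[0, 0, 0], [2, 0, 0]], dtype=float))
        assert radius_of_gyration(chain) == pytest.approx(1.0)

    def test_unit_rod_of_four_beads(self):
        chain = BeadChain("c", np.column_stack([np.arange(4.0),
                                                np.zeros(4), np.zeros(4)]))
        assert radius_of_gyration(chain) == pytest.approx(np.sqrt(5) / 2)
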