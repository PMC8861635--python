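import numpy as np
import pytest

from ctgenome import (BeadChain, contact_set, contacts_from_hic,
                      extract_contacts, read_chain, read_expression,
                      write_chain)
from ctgenome.chain_io import Contact, read_contacts, write_contacts
from ctgenome.errors import InputError, ParameterError, ParseError


def rod(n):
    return BeadChain("rod", np.column_stack([np.arange(n, dtype=float),
                                             np.zeros(n), np.zeros(n)]))


class TestReadChain:
    def test_reads_rows_in_order(self, tmp_path):
        p = tmp_path / "chain.tsv"
        p.write_text("0 0 0\n1 0 0\n2 0 0\n3 0 0\n")
        chain = read_chain(p)
        assert chain.n_beads == 4
        assert np.allclose(chain.coords[:, 0], [0, 1, 2, 3])

    def test_label_column_and_header(self, tmp_path):
        p = tmp_path / "chain.tsv"
        p.write_text("label x y z\nchr1 0 0 0\nchr1 1 1 1\n")
        chain = read_chain(p)
        assert chain.label == "chr1"
        assert chain.n_beads == 2

    def test_non_numeric_cell_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("0 0 0\n1 oops 0\n2 0 0\n")
        with pytest.raises(ParseError, match="bad.tsv:2"):
            read_chain(p)

    def test_too_few_beads(self, tmp_path):
        p = tmp_path / "short.tsv"
        p.write_text("0 0 0\n")
        with pytest.raises(InputError):
            read_chain(p)

    def test_round_trip(self, tmp_path, rng):
        chain = BeadChain("c", rng.normal(size=(17, 3)))
        p = tmp_path / "rt.tsv"
        write_chain(chain, p)
        back = read_chain(p)
        assert np.allclose(back.coords, chain.coords, atol=1e-6)
        assert back.label == "c"


class TestExtractContacts:
    def test_straight_rod_has_no_contacts(self):
        # only first neighbours fall within the cutoff on a unit-spaced rod
        assert len(extract_contacts(rod(4), r_c=1.0)) == 0

    def test_hairpin_contact(self):
        coords = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0.8, 0, 0]])
        cs = extract_contacts(BeadChain("h", coords), r_c=1.0)
        assert [(c.i, c.j) for c in cs] == [(0, 3)]

    def test_first_neighbour_excluded_even_when_close(self):
        coords = np.array([[0, 0, 0], [0.5, 0, 0], [5, 5, 5]])
        assert len(extract_contacts(BeadChain("h", coords), r_c=1.0)) == 0

    def test_cutoff_is_inclusive(self):
        coords = np.array([[0, 0, 0], [5, 5, 5], [1, 0, 0]])
        cs = extract_contacts(BeadChain("h", coords), r_c=1.0)
        assert [(c.i, c.j) for c in cs] == [(0, 2)]

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ParameterError):
            extract_contacts(rod(4), r_c=0.0)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(30, 3))
        chain = BeadChain("a", coords)
        # random rotation (QR orthogonalisation) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = BeadChain("b", coords @ q.T + rng.normal(size=3))
        for r_c in (0.5, 1.0, 1.5, 2.0):
            assert (extract_contacts(chain, r_c).contacts
                    == extract_contacts(moved, r_c).contacts)

    def test_monotone_in_cutoff(self, rng):
        chain = BeadChain("a", rng.normal(size=(40, 3)))
        prev = set()
        for r_c in (0.5, 1.0, 1.5, 2.0):
            cur = set(extract_contacts(chain, r_c).contacts)
            assert prev <= cur
            prev = cur


class TestContactsFromHic:
    def _mat(self, entries, n=5):
        m = np.zeros((n, n))
        for (i, j), v in entries.items():
            m[i, j] = m[j, i] = v
        return m

    def test_single_entry_above_threshold(self):
        cs = contacts_from_hic(self._mat({(0, 3): 300}), threshold=250)
        assert [(c.i, c.j) for c in cs] == [(0, 3)]
        assert cs.source == ("count_threshold", 250.0)

    def test_threshold_is_inclusive_and_monotone(self):
        m = self._mat({(0, 3): 300, (1, 4): 250})
        assert len(contacts_from_hic(m, threshold=250)) == 2
        assert len(contacts_from_hic(m, threshold=301)) == 0
        prev_n = 10
        for t in (100, 200, 250, 300, 301):
            n = len(contacts_from_hic(m, threshold=t))
            assert n <= prev_n
            prev_n = n

    def test_adjacent_bins_excluded(self):
        assert len(contacts_from_hic(self._mat({(0, 1): 999}), threshold=250)) == 0

    def test_upper_triangle_storage_mirrored(self):
        m = np.zeros((5, 5))
        m[0, 3] = 300  # upper triangle only
        cs = contacts_from_hic(m, threshold=250)
        assert [(c.i, c.j) for c in cs] == [(0, 3)]

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((5, 5))
        m[0, 3] = 300
        m[3, 0] = 100
        with pytest.raises(InputError):
            contacts_from_hic(m, threshold=250)

    def test_non_square_rejected(self):
        with pytest.raises(InputError):
            contacts_from_hic(np.zeros((4, 5)), threshold=250)


class TestExpression:
    def test_read_sorts_bins(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("chr1\t1000000\t2000000\t20\nchr1\t0\t1000000\t10\n")
        track = read_expression(p)
        assert len(track) == 2
        assert track.bins[0][0] == 0

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("chr1\t0\t1000000\t10\nchr1\t500000\t1500000\t20\n")
        with pytest.raises(InputError, match="overlap"):
            read_expression(p)


class TestContactSetContracts:
    def test_first_neighbour_contact_rejected(self):
        with pytest.raises(InputError):
            Contact(2, 3)

    def test_sorted_and_deduplicated(self):
        cs = contact_set([(4, 7), (0, 3), (4, 7)], n_beads=8)
        assert [(c.i, c.j) for c in cs] == [(0, 3), (4, 7)]

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            contact_set([(0, 9)], n_beads=8)

    def test_contact_tsv_round_trip(self, tmp_path, lloop):
        p = tmp_path / "contacts.tsv"
        write_contacts(lloop, p)
        back = read_contacts(p)
        assert back.contacts == lloop.contacts
        assert back.n_beads == lloop.n_beads
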