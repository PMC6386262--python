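"""Pedigree algebra: sorting, inbreeding, relationship matrices, generations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedsel.pedigree import Pedigree, PedigreeError, PedigreeRecord, topo_sort

from conftest import path_counting_inbreeding, random_pedigree


def founders(n, sex="unknown"):
    return [PedigreeRecord(f"f{i}", sex=sex) for i in range(n)]


class TestTopoSort:
    def test_founders_any_order(self):
        ped = topo_sort(founders(3))
        assert len(ped) == 3
        assert sorted(ped.ids) == ["f0", "f1", "f2"]

    def test_child_listed_before_sire(self):
        recs = [
            PedigreeRecord("kid", "papa", None),
            PedigreeRecord("papa", sex="male"),
        ]
        ped = topo_sort(recs)
        assert ped.ids.index("papa") < ped.ids.index("kid")

    def test_cycle_raises_naming_an_animal(self):
        recs = [PedigreeRecord("x", "y", None), PedigreeRecord("y", "x", None)]
        with pytest.raises(PedigreeError, match="cycle"):
            topo_sort(recs)

    def test_dangling_parent_raises(self):
        with pytest.raises(PedigreeError, match="ghost"):
            topo_sort([PedigreeRecord("a", "ghost", None)])

    def test_duplicate_id_raises(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            topo_sort([PedigreeRecord("a"), PedigreeRecord("a")])

    def test_sex_inconsistent_parent_raises(self):
        recs = [PedigreeRecord("mom", sex="female"),
                PedigreeRecord("kid", sire_id="mom")]
        with pytest.raises(PedigreeError, match="female"):
            topo_sort(recs)


class TestInbreeding:
    def test_founders_have_zero_f(self):
        ped = topo_sort(founders(5))
        assert np.all(ped.inbreeding() == 0.0)

    def test_full_sib_mating_gives_quarter(self):
        recs = [
            PedigreeRecord("s", sex="male"), PedigreeRecord("d", sex="female"),
            PedigreeRecord("b1", "s", "d", sex="male"),
            PedigreeRecord("b2", "s", "d", sex="female"),
            PedigreeRecord("kid", "b1", "b2"),
        ]
        ped = topo_sort(recs)
        assert ped.F[ped.index("kid")] == pytest.approx(0.25, abs=1e-15)

    def test_f_is_half_parent_relationship(self, rng):
        recs = random_pedigree(rng, 60, n_founders=8)
        ped = topo_sort(recs)
        A = ped.nrm()
        for i in range(len(ped)):
            s, d = ped.sire[i], ped.dam[i]
            expect = 0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0
            assert ped.F[i] == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_path_counting_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(10, 51))
        recs = random_pedigree(rng, n, n_founders=4)
        ped = topo_sort(recs)
        oracle = path_counting_inbreeding(recs)
        for aid, f_oracle in oracle.items():
            assert ped.F[ped.index(aid)] == pytest.approx(f_oracle, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_f_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        recs = random_pedigree(rng, int(rng.integers(3, 40)))
        F = topo_sort(recs).F
        assert np.all(F >= 0.0) and np.all(F < 1.0)


class TestRelationshipMatrices:
    def test_unrelated_founders_identity(self):
        ped = topo_sort(founders(4))
        assert np.array_equal(ped.nrm(), np.eye(4))
        assert np.allclose(ped.nrm_inverse().toarray(), np.eye(4))

    def test_parent_offspring_half(self):
        ped = topo_sort([PedigreeRecord("p", sex="male"),
                         PedigreeRecord("m", sex="female"),
                         PedigreeRecord("k", "p", "m")])
        assert ped.relationship("p", "k") == pytest.approx(0.5)

    def test_diag_equals_one_plus_f(self, rng):
        ped = topo_sort(random_pedigree(rng, 80, n_founders=6))
        assert np.allclose(np.diag(ped.nrm()), 1.0 + ped.F, atol=1e-12)

    def test_single_known_parent_alpha(self):
        # one known non-inbred parent: Mendelian variance 0.75, alpha = 4/3
        ped = topo_sort([PedigreeRecord("p", sex="male"),
                         PedigreeRecord("k", "p", None)])
        Ainv = ped.nrm_inverse().toarray()
        assert Ainv[ped.index("k"), ped.index("k")] == pytest.approx(4.0 / 3.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_inverse_times_nrm_is_identity(self, seed):
        rng = np.random.default_rng(2000 + seed)
        n = int(rng.integers(20, 201))
        ped = topo_sort(random_pedigree(rng, n, n_founders=8))
        prod = ped.nrm_inverse().toarray() @ ped.nrm()
        assert np.abs(prod - np.eye(n)).max() < 1e-8

    def test_dense_cap_enforced(self, rng):
        ped = topo_sort(founders(10))
        ped.DENSE_CAP = 5
        with pytest.raises(PedigreeError, match="nrm_inverse"):
            ped.nrm()


class TestGenerationCoefficients:
    def test_founder_is_zero(self):
        ped = topo_sort(founders(2))
        g, cls = ped.generation_coefficients()
        assert np.all(g == 0.0) and np.all(cls == 0)

    def test_both_parents_founders_gives_one(self):
        ped = topo_sort([PedigreeRecord("s", sex="male"),
                         PedigreeRecord("d", sex="female"),
                         PedigreeRecord("k", "s", "d")])
        g, cls = ped.generation_coefficients()
        assert g[ped.index("k")] == 1.0
        assert cls[ped.index("k")] == 1

    def test_half_up_rounding_of_mixed_parents(self):
        # parents at g = 1 and g = 2 -> child 2.5 -> class 3 under half-up
        recs = [
            PedigreeRecord("f1", sex="male"), PedigreeRecord("f2", sex="female"),
            PedigreeRecord("p1", "f1", "f2", sex="male"),          # g = 1
            PedigreeRecord("q1", "f1", "f2", sex="female"),        # g = 1
            PedigreeRecord("p2", "p1", "q1", sex="female"),        # g = 2
            PedigreeRecord("kid", "p1", "p2"),                     # g = 2.5
        ]
        ped = topo_sort(recs)
        g, cls = ped.generation_coefficients("half_up")
        assert g[ped.index("kid")] == pytest.approx(2.5)
        assert cls[ped.index("kid")] == 3
        _, cls_even = ped.generation_coefficients("half_even")
        assert cls_even[ped.index("kid")] == 2

    def test_unknown_parent_acts_as_phantom_founder(self):
        ped = topo_sort([PedigreeRecord("s", sex="male"),
                         PedigreeRecord("k", "s", None)])
        g, _ = ped.generation_coefficients()
        assert g[ped.index("k")] == 1.0

    def test_monotone_above_parent_average(self, rng):
        ped = topo_sort(random_pedigree(rng, 100, n_founders=8))
        g, _ = ped.generation_coefficients()
        for i in range(len(ped)):
            if ped.sire[i] < 0 and ped.dam[i] < 0:
                continue
            # phantom (unknown) parents contribute g = 0 to the average
            parent_avg = 0.5 * sum(g[p] if p >= 0 else 0.0
                                   for p in (ped.sire[i], ped.dam[i]))
            assert g[i] > parent_avg
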