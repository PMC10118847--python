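"""Sharing (Venn, Morisita-Horn), dominant clones and CDR3 homology."""

import itertools

import numpy as np
import pytest

from conftest import (
    oracle_percent_identity,
    sample_from_counts,
    sample_from_keyed_counts,
)
from tcrep.errors import EmptyRepertoireError, TcrepError
from tcrep.io import Rearrangement
from tcrep.overlap import (
    convergence_groups,
    dominant_clone,
    morisita,
    overlap_matrix,
    percent_identity,
    shared_sequences,
    venn_counts,
)

NT = {
    "a": "TGTGCAAAA", "b": "TGTGCACCC", "c": "TGTGCAGGG",
    "d": "TGTGCATTT", "e": "TGTGCAACC", "w": "TGTGCAAGG",
    "x": "TGTGCAATT", "y": "TGTGCACAA", "z": "TGTGCACGG",
}


def _s(names, sample_id, counts=None):
    counts = counts or {}
    return sample_from_keyed_counts(
        {NT[n]: counts.get(n, 1) for n in names}, sample_id=sample_id
    )


class TestSharedSequences:
    def test_exact_intersection(self):
        assert shared_sequences(_s("xyz", "1"), _s("yzw", "2")) == {
            NT["y"], NT["z"],
        }

    def test_disjoint_samples_share_nothing(self):
        assert shared_sequences(_s("ab", "1"), _s("cd", "2")) == set()

    def test_in_frame_scope_includes_stop_reads(self):
        stop = "TGTTAAAGC"
        a = sample_from_keyed_counts({stop: 1, NT["a"]: 1}, sample_id="1")
        b = sample_from_keyed_counts({stop: 2}, sample_id="2")
        assert shared_sequences(a, b, scope="in_frame") == {stop}
        with pytest.raises(EmptyRepertoireError):
            morisita(a, b, scope="productive")


class TestVennCounts:
    def test_identical_samples_all_in_center(self):
        regions = venn_counts([_s("abc", "1"), _s("abc", "2"), _s("abc", "3")])
        assert regions[("1", "2", "3")] == 3
        assert sum(v for k, v in regions.items() if len(k) < 3) == 0

    def test_pairwise_disjoint_samples(self):
        regions = venn_counts([_s("ab", "1"), _s("cd", "2"), _s("we", "3")])
        assert regions[("1",)] == regions[("2",)] == regions[("3",)] == 2
        assert all(v == 0 for k, v in regions.items() if len(k) > 1)

    def test_three_way_example_against_set_algebra(self):
        samples = [_s("abc", "1"), _s("bcd", "2"), _s("cde", "3")]
        regions = venn_counts(samples)
        # exhaustive set-membership oracle
        sets = {s.sample_id: {r.cdr3_nt for r in s.rearrangements}
                for s in samples}
        ids = list(sets)
        for k in (1, 2, 3):
            for combo in itertools.combinations(ids, k):
                members = set.intersection(*(sets[i] for i in combo))
                for other in ids:
                    if other not in combo:
                        members -= sets[other]
                assert regions[combo] == len(members)
        assert sum(regions.values()) == len(set.union(*sets.values()))

    def test_more_than_three_samples_unsupported(self):
        with pytest.raises(TcrepError):
            venn_counts([_s("a", str(i)) for i in range(4)])


class TestMorisita:
    def test_self_overlap_is_one(self):
        s = _s("abc", "1", counts={"a": 5, "b": 2, "c": 1})
        assert morisita(s, s) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_give_zero(self):
        assert morisita(_s("ab", "1"), _s("cd", "2")) == 0.0

    def test_hand_evaluated_small_case(self):
        # x = (2, 1), y = (1, 1) on shared keys -> 18/19
        a = _s("ab", "1", counts={"a": 2, "b": 1})
        b = _s("ab", "2", counts={"a": 1, "b": 1})
        assert morisita(a, b) == pytest.approx(18 / 19, abs=1e-12)

    def test_invariance_symmetry_and_bounds_on_random_pairs(self):
        rng = np.random.default_rng(7)
        names = list(NT)
        for _ in range(200):
            ka = rng.choice(names, size=rng.integers(2, 8), replace=False)
            kb = rng.choice(names, size=rng.integers(2, 8), replace=False)
            ca = {n: int(rng.integers(1, 30)) for n in ka}
            cb = {n: int(rng.integers(1, 30)) for n in kb}
            a = _s(ka, "1", counts=ca)
            b = _s(kb, "2", counts=cb)
            v = morisita(a, b)
            assert 0.0 <= v <= 1.0 + 1e-12
            assert morisita(b, a) == pytest.approx(v, abs=1e-12)
            scaled = _s(ka, "1s", counts={n: 7 * c for n, c in ca.items()})
            assert morisita(scaled, b) == pytest.approx(v, abs=1e-12)

    def test_classical_variant_available(self):
        a = _s("ab", "1", counts={"a": 2, "b": 1})
        assert morisita(a, a, variant="classical") == pytest.approx(
            2 * 5 / ((2 / 6 + 2 / 6) * 9), abs=1e-12
        )


class TestOverlapMatrix:
    def test_symmetric_unit_diagonal(self):
        samples = [_s("abc", "1"), _s("bcd", "2"), _s("ae", "3")]
        m = overlap_matrix(samples).values
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)

    def test_duplicate_sample_has_unit_off_diagonal(self):
        a = _s("abc", "1", counts={"a": 3})
        b = _s("abc", "2", counts={"a": 3})
        m = overlap_matrix([a, b]).values
        assert m.loc["1", "2"] == pytest.approx(1.0)


class TestDominantClone:
    def test_planted_dominant_returned(self):
        s = sample_from_counts([301] + [1] * 699)
        clone, freq = dominant_clone(s)
        assert freq == pytest.approx(0.301)
        assert clone.template_count == 301

    def test_tie_broken_by_lexicographic_cdr3_nt(self):
        s = sample_from_keyed_counts({NT["b"]: 5, NT["a"]: 5}, sample_id="t")
        clone, freq = dominant_clone(s)
        assert clone.cdr3_nt == min(NT["a"], NT["b"])
        assert freq == 0.5

    def test_single_clone_sample(self):
        s = sample_from_counts([4])
        _, freq = dominant_clone(s)
        assert freq == 1.0


class TestPercentIdentity:
    def test_identical_strings(self):
        assert percent_identity("CASSLG", "CASSLG") == 100.0

    def test_one_mismatch_in_fourteen(self):
        a = "CASSLGGAQETQYF"
        b = "CASSLGGAQETQYA"
        assert percent_identity(a, b) == pytest.approx(100 * 13 / 14)

    def test_terminal_gap_case(self):
        assert percent_identity("CASS", "CASSF") == pytest.approx(80.0)

    def test_empty_string_is_an_error(self):
        with pytest.raises(TcrepError):
            percent_identity("", "CASS")

    def test_symmetry_and_oracle_agreement_on_short_strings(self):
        rng = np.random.default_rng(11)
        alphabet = "ACDE"
        for _ in range(150):
            a = "".join(rng.choice(list(alphabet), rng.integers(1, 6)))
            b = "".join(rng.choice(list(alphabet), rng.integers(1, 6)))
            v = percent_identity(a, b)
            assert v == pytest.approx(percent_identity(b, a), abs=1e-12)
            assert v == pytest.approx(oracle_percent_identity(a, b), abs=1e-12)


class TestConvergenceGroups:
    def test_synonymous_variants_with_distinct_v_flagged(self):
        r1 = Rearrangement.from_nt("TGTGCAAGC", "TRBV1", "TRBJ1-1")  # CAS
        r2 = Rearrangement.from_nt("TGCGCAAGC", "TRBV2", "TRBJ1-1")  # CAS
        groups = convergence_groups([r1, r2])
        assert len(groups) == 1 and groups[0].convergent
        assert groups[0].cdr3_aa == "CAS"

    def test_distinct_aa_not_flagged(self):
        r1 = Rearrangement.from_nt("TGTGCAAGC", "TRBV1", "TRBJ1-1")
        r2 = Rearrangement.from_nt("TGTGGGAGC", "TRBV1", "TRBJ1-1")
        assert not any(g.convergent for g in convergence_groups([r1, r2]))

    def test_identical_records_grouped_but_not_flagged(self):
        r = Rearrangement.from_nt("TGTGCAAGC", "TRBV1", "TRBJ1-1")
        (g,) = convergence_groups([r, r])
        assert len(g.members) == 2 and not g.convergent
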