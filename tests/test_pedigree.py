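import itertools
import math

import numpy as np
import pandas as pd
import pytest

from houndpop import pedigree as pg
from houndpop.pedigree import (
    PedigreeError,
    average_relatedness,
    completeness,
    delta_f_and_ne,
    founder_stats,
    inbreeding,
    pedigree_metrics,
    validate_pedigree,
)

from conftest import random_pedigree_frame


def frame(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"])


def tabular_A(ped):
    """Independent tabular-method numerator relationship matrix."""
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[j, s]
            if d >= 0:
                v += 0.5 * A[j, d]
            A[i, j] = A[j, i] = v
    return A


FULL_SIB = frame(
    [("A", "", "", "male"), ("B", "", "", "female"),
     ("S1", "A", "B", "male"), ("S2", "A", "B", "female"),
     ("P", "S1", "S2", "")]
)

HALF_SIB = frame(
    [("A", "", "", "male"), ("B", "", "", "female"), ("C", "", "", "female"),
     ("H1", "A", "B", "male"), ("H2", "A", "C", "female"),
     ("P", "H1", "H2", "")]
)


class TestValidate:
    def test_founder_only_unchanged(self):
        ped = validate_pedigree(frame([("X", "", "", ""), ("Y", "", "", "")]))
        assert ped.ids == ["X", "Y"]
        assert (ped.sire == -1).all() and (ped.dam == -1).all()

    def test_cycle_detected(self):
        df = frame([("a", "b", "", "male"), ("b", "a", "", "male")])
        with pytest.raises(PedigreeError, match="cycle"):
            validate_pedigree(df)

    def test_sire_and_dam_conflict(self):
        df = frame(
            [("X", "", "", ""), ("Y", "", "", ""),
             ("c1", "X", "Y", ""), ("c2", "Y", "X", "")]
        )
        with pytest.raises(PedigreeError, match="both sire and dam"):
            validate_pedigree(df)

    def test_shuffled_rows_same_canonical_order(self, rng):
        df = random_pedigree_frame(rng, n_founders=8, n_gen=3, per_gen=10)
        ped_a = validate_pedigree(df)
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        ped_b = validate_pedigree(shuffled)
        assert ped_a.ids == ped_b.ids
        # oracle check: order is a valid topological sort
        for ped in (ped_a, ped_b):
            for i in range(ped.n):
                assert ped.sire[i] < i and ped.dam[i] < i

    def test_birthdate_violation_warns(self):
        df = pd.DataFrame(
            {"id": ["p", "c"], "sire": ["", "p"], "dam": ["", ""],
             "sex": ["male", ""], "birthdate": ["2010-01-01", "2005-01-01"]}
        )
        with pytest.warns(UserWarning, match="born after"):
            validate_pedigree(df)


class TestInbreeding:
    def test_full_sib_offspring(self):
        ped = validate_pedigree(FULL_SIB)
        F = dict(zip(ped.ids, inbreeding(ped)))
        assert F["P"] == pytest.approx(0.25)

    def test_half_sib_offspring(self):
        ped = validate_pedigree(HALF_SIB)
        F = dict(zip(ped.ids, inbreeding(ped)))
        assert F["P"] == pytest.approx(0.125)

    def test_parent_offspring_mating(self):
        df = frame(
            [("A", "", "", "male"), ("B", "", "", "female"),
             ("C", "A", "B", "female"), ("P", "A", "C", "")]
        )
        ped = validate_pedigree(df)
        assert dict(zip(ped.ids, inbreeding(ped)))["P"] == pytest.approx(0.25)

    def test_equals_tabular_method_on_random_pedigrees(self):
        """Meuwissen-Luo path trace vs full A-matrix diagonal: exact."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = random_pedigree_frame(
                rng,
                n_founders=int(rng.integers(4, 8)),
                n_gen=int(rng.integers(2, 5)),
                per_gen=int(rng.integers(4, 12)),
            )
            ped = validate_pedigree(df)
            F = inbreeding(ped)
            assert np.allclose(F, np.diag(tabular_A(ped)) - 1, atol=1e-12)

    def test_relabeling_invariance(self, rng):
        df = random_pedigree_frame(rng)
        ped = validate_pedigree(df)
        F = dict(zip(ped.ids, inbreeding(ped)))
        renamed = df.copy()
        mapping = {i: f"zz_{i}" for i in df["id"]}
        for col in ("id", "sire", "dam"):
            renamed[col] = [mapping.get(x, x) if x else "" for x in renamed[col]]
        ped2 = validate_pedigree(renamed)
        F2 = dict(zip(ped2.ids, inbreeding(ped2)))
        for ind, f in F.items():
            assert F2[mapping[ind]] == pytest.approx(f)

    def test_added_founder_changes_nothing(self, rng):
        df = random_pedigree_frame(rng)
        ped = validate_pedigree(df)
        F = dict(zip(ped.ids, inbreeding(ped)))
        df2 = pd.concat(
            [df, frame([("lonely", "", "", "male")])], ignore_index=True
        )
        ped2 = validate_pedigree(df2)
        F2 = dict(zip(ped2.ids, inbreeding(ped2)))
        for ind, f in F.items():
            assert F2[ind] == pytest.approx(f)


class TestAverageRelatedness:
    def test_unrelated_individuals(self):
        ped = validate_pedigree(frame([(f"x{i}", "", "", "") for i in range(4)]))
        assert np.allclose(average_relatedness(ped), 0.25)  # a_ii/N = 1/4

    def test_parent_offspring_pair(self):
        ped = validate_pedigree(frame([("p", "", "", "male"), ("c", "p", "", "")]))
        assert np.allclose(average_relatedness(ped), 0.75)

    def test_equals_dense_row_means(self, rng):
        for seed in range(20):
            local = np.random.default_rng(seed)
            df = random_pedigree_frame(local, n_founders=6, n_gen=3, per_gen=8)
            ped = validate_pedigree(df)
            AR = average_relatedness(ped)
            assert np.allclose(AR, tabular_A(ped).mean(axis=1), atol=1e-12)

    def test_grand_sum_identity(self, rng):
        df = random_pedigree_frame(rng)
        ped = validate_pedigree(df)
        AR = average_relatedness(ped)
        A = tabular_A(ped)
        assert AR.sum() * ped.n == pytest.approx(A.sum())


class TestCompleteness:
    def test_two_full_generations(self):
        df = frame(
            [("gp1", "", "", "male"), ("gm1", "", "", "female"),
             ("gp2", "", "", "male"), ("gm2", "", "", "female"),
             ("f", "gp1", "gm1", "male"), ("m", "gp2", "gm2", "female"),
             ("x", "f", "m", "")]
        )
        ped = validate_pedigree(df)
        row = completeness(ped).set_index("id").loc["x"]
        assert (row["gen_max"], row["gen_complete"]) == (2, 2)
        assert row["gen_equiv"] == pytest.approx(2.0)  # 2*(1/2) + 4*(1/4)

    def test_only_sire_known(self):
        ped = validate_pedigree(frame([("p", "", "", "male"), ("x", "p", "", "")]))
        row = completeness(ped).set_index("id").loc["x"]
        assert (row["gen_max"], row["gen_complete"]) == (1, 0)
        assert row["gen_equiv"] == pytest.approx(0.5)

    def test_matches_recursive_oracle(self, rng):
        def oracle(ped, i):
            s, d = ped.sire[i], ped.dam[i]
            gm = 0
            ge = 0.0
            for p in (s, d):
                if p >= 0:
                    pm, pc, pe = oracle(ped, p)
                    gm = max(gm, 1 + pm)
                    ge += 0.5 * (1 + pe)
            gc = (
                1 + min(oracle(ped, s)[1], oracle(ped, d)[1])
                if s >= 0 and d >= 0
                else 0
            )
            return gm, gc, ge

        for seed in range(10):
            local = np.random.default_rng(seed)
            ped = validate_pedigree(random_pedigree_frame(local))
            table = completeness(ped)
            for i in range(ped.n):
                gm, gc, ge = oracle(ped, i)
                assert table["gen_max"][i] == gm
                assert table["gen_complete"][i] == gc
                assert table["gen_equiv"][i] == pytest.approx(ge)


class TestDeltaFNe:
    def test_single_individual(self):
        delta_f, ne = delta_f_and_ne(np.array([0.25]), np.array([2.0]))
        assert delta_f == pytest.approx(0.25)
        assert ne == pytest.approx(2.0)

    def test_no_inbreeding_infinite_ne(self):
        delta_f, ne = delta_f_and_ne(np.array([0.0, 0.0]), np.array([3.0, 2.0]))
        assert delta_f == 0.0 and math.isinf(ne)

    def test_inversion_arithmetic(self):
        delta_f, ne = delta_f_and_ne(np.array([0.0045]), np.array([2.0]))
        assert ne == pytest.approx(1 / (2 * 0.0045))
        assert ne == pytest.approx(111.11, abs=0.01)

    def test_no_eligible_individual_rejected(self):
        with pytest.raises(PedigreeError):
            delta_f_and_ne(np.array([0.1]), np.array([1.0]))


def exhaustive_founder_oracle(ped, ref_ids):
    """Path-enumeration re-implementation of f_e and greedy f_a (tiny pedigrees).

    Contributions are computed by explicitly enumerating descent paths from a
    candidate down to each reference member; paths entering a selected
    ancestor from its parents are forbidden (their links are cut), and the
    marginal is scaled by the unexplained fraction of the candidate's genome,
    itself computed by enumerating upward paths absorbed at selected
    ancestors.
    """
    ref = [ped.index[r] for r in ref_ids]
    children = [[] for _ in range(ped.n)]
    for i in range(ped.n):
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                children[p].append(i)

    def down_paths(j, target, blocked):
        # count sum over paths j -> target of (1/2)^len, never entering a
        # blocked node from above (blocked nodes keep no parent links)
        if j == target:
            return 1.0
        total = 0.0
        for c in children[j]:
            if c in blocked:
                continue  # c's parent links are cut
            total += 0.5 * down_paths(c, target, blocked)
        return total

    def contribution(j, blocked):
        return sum(down_paths(j, r, blocked) for r in ref) / len(ref)

    def explained(j, selected):
        if j in selected:
            return 1.0
        e = 0.0
        for p in (ped.sire[j], ped.dam[j]):
            if p >= 0:
                e += 0.5 * explained(p, selected)
        return e

    # f_e from founder contributions (all founders are complete in fixtures)
    founders = [i for i in range(ped.n) if ped.sire[i] < 0 and ped.dam[i] < 0]
    q = [contribution(f, set()) for f in founders]
    f_e = 1.0 / sum(x * x for x in q)

    candidates = set()
    for r in ref:
        candidates |= ped.ancestors_of(r)
    selected, p_vals = set(), []
    while True:
        best, best_val = None, 1e-12
        for j in sorted(candidates - selected):
            val = contribution(j, selected) * (1 - explained(j, selected))
            if val > best_val:
                best, best_val = j, val
        if best is None:
            break
        selected.add(best)
        p_vals.append(best_val)
    f_a = 1.0 / sum(x * x for x in p_vals)
    return f_e, f_a


class TestFounderStats:
    def test_balanced_four_founders(self):
        df = frame(
            [("F1", "", "", "male"), ("F2", "", "", "female"),
             ("F3", "", "", "male"), ("F4", "", "", "female"),
             ("R1", "F1", "F2", ""), ("R2", "F3", "F4", "")]
        )
        fs = founder_stats(validate_pedigree(df), ["R1", "R2"])
        assert fs.n_founders == 4
        assert fs.f_e == pytest.approx(4.0)
        assert fs.f_a == pytest.approx(4.0)

    def test_popular_nonfounder_sire_bottleneck(self):
        rows = [("GA", "", "", "male"), ("GB", "", "", "female"),
                ("S", "GA", "GB", "male")]
        for k in range(5):
            rows += [(f"D{k}", "", "", "female"), (f"R{k}", "S", f"D{k}", "")]
        ped = validate_pedigree(frame(rows))
        fs = founder_stats(ped, [f"R{k}" for k in range(5)])
        assert fs.f_a < fs.f_e
        assert sum(fs.ancestor_contributions.values()) == pytest.approx(1.0)
        f_e, f_a = exhaustive_founder_oracle(ped, [f"R{k}" for k in range(5)])
        assert fs.f_e == pytest.approx(f_e)
        assert fs.f_a == pytest.approx(f_a)

    def test_matches_exhaustive_oracle_on_random_pedigrees(self):
        for seed in range(8):
            rng = np.random.default_rng(seed + 50)
            df = random_pedigree_frame(rng, n_founders=4, n_gen=2, per_gen=5)
            ped = validate_pedigree(df)
            ref_ids = [ped.ids[i] for i in ped.offspringless()]
            fs = founder_stats(ped, ref_ids)
            f_e, f_a = exhaustive_founder_oracle(ped, ref_ids)
            assert fs.f_e == pytest.approx(f_e)
            assert fs.f_a == pytest.approx(f_a)
            assert fs.f_a <= fs.f_e + 1e-9

    def test_ratio_arithmetic(self):
        assert 59 / 100 == pytest.approx(0.59)


class TestMetrics:
    def test_founder_only_population(self):
        df = frame([(f"x{i}", "", "", "") for i in range(4)])
        ped = validate_pedigree(df)
        F = inbreeding(ped)
        assert (F == 0).all()
        assert np.allclose(average_relatedness(ped), 0.25)

    def test_assembled_fields_match_component_oracles(self, rng):
        df = random_pedigree_frame(rng, n_founders=6, n_gen=3, per_gen=8)
        ped = validate_pedigree(df)
        m = pedigree_metrics(ped)
        F = inbreeding(ped)
        comp = completeness(ped)
        assert m.n_total == ped.n
        assert m.n_inbred == int((F > 1e-12).sum())
        assert m.f_mean == pytest.approx(F.mean())
        assert m.ar_mean == pytest.approx(average_relatedness(ped).mean())
        assert m.gen_equiv_mean == pytest.approx(comp["gen_equiv"].mean())
        delta_f, ne = delta_f_and_ne(F, comp["gen_equiv"].to_numpy())
        assert m.delta_f == pytest.approx(delta_f)
        assert m.ne_realized == pytest.approx(ne)
        assert m.f_a <= m.f_e <= m.n_founders + 1e-9

    def test_population_mean_f_consistency(self):
        """Mean F over all animals = n_inbred * mean(F | inbred) / n_total."""
        n_total, n_inbred, f_inbred = 520, 54, 0.0408
        f_mean = n_inbred * f_inbred / n_total
        assert 100 * f_mean == pytest.approx(0.42, abs=0.005)
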