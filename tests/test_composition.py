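"""%w/w statistics, ANOVA/Tukey-Kramer and compact letter displays."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camseed import composition as comp
from camseed import synthetic as syn


class TestPercentWW:
    def _table(self, mg_by_analyte, group="g", bio=1, tech=1):
        return pd.DataFrame(
            [
                {"sample_id": "s", "group": group, "bio_rep": bio,
                 "tech_rep": tech, "analyte": a, "mg": m}
                for a, m in mg_by_analyte.items()
            ]
        )

    def test_single_analyte_is_100(self):
        out = comp.percent_ww(self._table({"Lysine": 3.2}))
        assert out["pct_ww"].tolist() == [100.0]

    def test_ratio_2_1_1(self):
        out = comp.percent_ww(self._table({"A": 2.0, "B": 1.0, "C": 1.0}))
        assert sorted(out["pct_ww"]) == [25.0, 25.0, 50.0]

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            comp.percent_ww(self._table({"A": 0.0, "B": 0.0}))

    def test_rows_sum_to_100(self):
        table = syn.gen_aa_table(cv_tech=8.0, seed=2)
        out = comp.percent_ww(table)
        sums = out.groupby(["group", "bio_rep", "tech_rep"])["pct_ww"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)


class TestGroupMean:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([5.81, 5.86, 5.42, 5.55, 5.80, 5.52], 5.66),     # lysine row
            ([17.68, 17.93, 17.89, 18.63, 17.45, 17.98], 17.93),  # Glx row
            ([1.84, 1.77, 1.86, 1.75, 1.85, 2.02], 1.85),     # methionine row
        ],
    )
    def test_published_per_accession_averages(self, values, expected):
        mean, _sd = comp.group_mean(values)
        assert round(mean, 2) == expected

    def test_identical_values_sd_zero(self):
        assert comp.group_mean([4.0, 4.0, 4.0])[1] == 0.0

    def test_single_value_sd_undefined(self):
        mean, sd = comp.group_mean([4.0])
        assert mean == 4.0 and np.isnan(sd)


class TestScalarOps:
    def test_protein_content(self):
        assert comp.protein_content(0.0) == 0.0
        assert comp.protein_content(16.0) == 100.0
        assert comp.protein_content(6.4) == pytest.approx(40.0)

    def test_moisture(self):
        assert comp.moisture_pct(1.0, 1.0) == 0.0
        assert comp.moisture_pct(1.0, 0.9) == pytest.approx(10.0)
        assert comp.moisture_pct(0.700, 0.630) == pytest.approx(10.0)

    def test_moisture_dry_exceeds_wet_errors(self):
        with pytest.raises(ValueError):
            comp.moisture_pct(0.5, 0.6)

    def test_cv_flag(self):
        assert comp.cv_flag([2.0, 2.0, 2.0]) == (0.0, False)
        cv, flagged = comp.cv_flag([1.0, 1.0, 1.5])
        assert cv == pytest.approx(24.7, abs=0.1) and flagged
        cv, flagged = comp.cv_flag([10.0, 10.1, 9.9])
        assert cv == pytest.approx(1.0, abs=0.05) and not flagged


def _brute_force_min_letters(groups, significant):
    """Smallest clique cover of the non-significant graph, by exhaustion."""
    nonsig_pairs = {
        frozenset(p)
        for p in itertools.combinations(groups, 2)
        if frozenset(p) not in significant
    }
    cliques = [
        frozenset(c)
        for r in range(1, len(groups) + 1)
        for c in itertools.combinations(groups, r)
        if all(frozenset(p) in nonsig_pairs
               for p in itertools.combinations(c, 2))
    ]
    for k in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, k):
            verts = set().union(*combo)
            edges = {
                frozenset(p)
                for c in combo
                for p in itertools.combinations(c, 2)
            }
            if verts == set(groups) and nonsig_pairs <= edges:
                return k
    raise AssertionError("unreachable")


def _letters_valid(groups, significant, letters):
    for a, b in itertools.combinations(groups, 2):
        share = bool(set(letters[a]) & set(letters[b]))
        assert share != (frozenset({a, b}) in significant), (a, b, letters)


class TestCompactLetterDisplay:
    def test_no_significance_single_letter(self):
        out = comp.compact_letter_display(["g1", "g2", "g3"], set())
        assert set(out.values()) == {"A"}

    def test_full_separation(self):
        sig = {frozenset(p) for p in itertools.combinations(["g1", "g2", "g3"], 2)}
        out = comp.compact_letter_display(["g1", "g2", "g3"], sig)
        assert sorted(out.values()) == ["A", "B", "C"]

    def test_chain_structure(self):
        out = comp.compact_letter_display(
            ["g1", "g2", "g3"], {frozenset({"g1", "g3"})}
        )
        assert out == {"g1": "A", "g2": "AB", "g3": "B"}

    def test_exhaustive_four_groups_vs_brute_force(self):
        """Valid and minimal for every significant-pair set over 4 groups."""
        groups = ["g1", "g2", "g3", "g4"]
        all_pairs = [frozenset(p) for p in itertools.combinations(groups, 2)]
        for mask in range(2 ** len(all_pairs)):
            sig = {p for i, p in enumerate(all_pairs) if mask >> i & 1}
            letters = comp.compact_letter_display(groups, sig)
            _letters_valid(groups, sig, letters)
            n_letters = len(set("".join(letters.values())))
            assert n_letters == _brute_force_min_letters(groups, sig)

    def test_insert_absorb_fallback_valid(self):
        """The many-group heuristic also satisfies the sharing rule."""
        groups = [f"g{i}" for i in range(8)]
        sig = {frozenset({"g0", "g7"}), frozenset({"g1", "g6"}),
               frozenset({"g0", "g4"}), frozenset({"g2", "g5"})}
        letters = comp.compact_letter_display(groups, sig, exact_max_groups=2)
        _letters_valid(groups, sig, letters)


def _exact_two_group_permutation_p(a, b):
    """Exact permutation p for |mean difference|, all label splits."""
    pooled = np.concatenate([a, b])
    n = len(a)
    observed = abs(np.mean(a) - np.mean(b))
    total = pooled.sum()
    count = 0
    m = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        sa = pooled[list(idx)].sum()
        diff = abs(sa / n - (total - sa) / (len(pooled) - n))
        count += diff >= observed - 1e-12
        m += 1
    return count / m


class TestAnovaTukey:
    def test_identical_groups_share_letter(self):
        vals = [5.0, 5.1, 4.9, 5.0]
        st_ = comp.anova_tukey({"a": vals, "b": vals, "c": vals})
        assert len(set(st_.letters.values())) == 1

    def test_strong_separation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 5)
        b = rng.normal(10, 1, 5)
        st_ = comp.anova_tukey({"a": a, "b": b})
        assert st_.letters["a"] != st_.letters["b"]
        assert list(st_.pairwise_p.values())[0] < 0.001

    def test_degenerate_zero_variance_flagged(self):
        st_ = comp.anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert st_.degenerate
        assert st_.letters["a"] != st_.letters["b"]

    def test_tukey_p_symmetric_under_relabelling(self):
        rng = np.random.default_rng(7)
        groups = {g: rng.normal(i, 1, 5) for i, g in enumerate("abc")}
        st1 = comp.anova_tukey(groups)
        st2 = comp.anova_tukey(dict(reversed(list(groups.items()))))
        for pair, p in st1.pairwise_p.items():
            assert st2.pairwise_p[pair] == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize("shift", [0.7, 1.0, 1.3])
    def test_two_group_p_matches_exact_permutation(self, shift):
        """Tukey p agrees with the exact permutation oracle (moderate p).

        Constructed two-group cases use normal scores (exactly
        normal-shaped samples), where the parametric and permutation
        answers must coincide closely.
        """
        from scipy.stats import norm

        scores = norm.ppf((np.arange(1, 11) - 0.5) / 10)
        a, b = scores, scores + shift
        st_ = comp.anova_tukey({"a": a, "b": b})
        p_tukey = list(st_.pairwise_p.values())[0]
        p_perm = _exact_two_group_permutation_p(a, b)
        assert 0.001 <= p_perm <= 0.2, "constructed case must be in band"
        assert p_tukey == pytest.approx(p_perm, rel=0.10)

    def test_report_runs_end_to_end(self):
        table = syn.gen_aa_table(cv_tech=3.0, seed=1)
        report = comp.composition_report(table)
        assert set(report.columns) == {"analyte", "group", "mean", "sd", "n",
                                       "letters"}
        assert report["n"].eq(3).all()
        # every analyte has all six accession groups
        assert report.groupby("analyte")["group"].count().eq(6).all()
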