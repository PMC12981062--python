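"""Statistical battery: t-tests, ANOVA designs, mixed model, Sidak."""

import numpy as np
import pandas as pd
import pytest

from inhibpipe import anova, sidak_adjust, ttest_unpaired
from oracles import two_way_anova_ss


class TestTtestUnpaired:
    def test_identical_groups(self):
        res = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_textbook_example(self):
        # pooled-variance formula by hand: t = -3/sqrt(2/3) = -3.674
        res = ttest_unpaired([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.p == pytest.approx(0.0214, abs=5e-4)
        assert res.df == (4.0,)
        assert res.effect_direction == -1.0

    def test_joint_label_permutation_preserves_abs_t(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 1, 9)
        fwd = ttest_unpaired(a, b)
        rev = ttest_unpaired(b, a)
        assert abs(fwd.statistic) == pytest.approx(abs(rev.statistic))
        assert fwd.p == pytest.approx(rev.p)

    def test_degenerate_zero_variance(self):
        res = ttest_unpaired([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            ttest_unpaired([1.0], [2.0, 3.0])


class TestAnova:
    def test_one_way_identical_groups_f_near_zero(self):
        table = pd.DataFrame(
            {"value": [1.0, 2.0, 3.0] * 2, "genotype": ["a"] * 3 + ["b"] * 3}
        )
        (res,) = anova(table, "one_way", factors=("genotype",))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_two_way_matches_ss_oracle(self, rng):
        rows = []
        for g in ("Eu", "Ts"):
            for age in ("6w", "8w"):
                for _ in range(6):
                    mu = 100 + 30 * (g == "Ts") + 10 * (age == "8w")
                    rows.append({"genotype": g, "age": age,
                                 "value": mu + rng.normal(0, 15)})
        table = pd.DataFrame(rows)
        results = {r.term: r for r in anova(table, "two_way",
                                            factors=("genotype", "age"))}
        oracle = two_way_anova_ss(table, "value", "genotype", "age")
        mapping = {"C(genotype)": "genotype", "C(age)": "age",
                   "C(genotype):C(age)": "genotype:age"}
        for patsy_term, res in results.items():
            f_expected, df1, df2 = oracle[mapping[patsy_term]]
            assert res.statistic == pytest.approx(f_expected, rel=1e-6)
            assert res.df == (df1, df2)

    def test_mixed_repeated_agrees_with_classical_rm_anova(self, rng):
        """On balanced complete data the random-intercept Wald F for the
        within factor matches pingouin's mixed ANOVA within 1 %."""
        import pingouin as pg

        rows = []
        for ci in range(12):
            geno = "Eu" if ci < 6 else "Ts"
            cell_offset = rng.normal(0, 40)
            for intensity in (10, 20, 30):
                mu = 100 + 5 * intensity + 40 * (geno == "Ts")
                rows.append({"cell_id": f"c{ci}", "genotype": geno,
                             "intensity": intensity,
                             "value": mu + cell_offset + rng.normal(0, 25)})
        table = pd.DataFrame(rows)
        ours = {r.term: r for r in anova(table, "mixed_repeated",
                                         factors=("genotype", "intensity"),
                                         subject="cell_id")}
        ref = pg.mixed_anova(table, dv="value", within="intensity",
                             subject="cell_id", between="genotype")
        f_within_ref = float(ref.loc[ref.Source == "intensity", "F"].iloc[0])
        f_within_ours = ours["C(intensity, Sum)"].statistic
        assert f_within_ours == pytest.approx(f_within_ref, rel=0.01)
        f_between_ref = float(ref.loc[ref.Source == "genotype", "F"].iloc[0])
        assert ours["C(genotype, Sum)"].statistic == pytest.approx(
            f_between_ref, rel=0.01
        )

    def test_mixed_repeated_tolerates_missing_cells(self, rng):
        rows = []
        for ci in range(10):
            geno = "Eu" if ci < 5 else "Ts"
            off = rng.normal(0, 30)
            for intensity in (10, 20, 30):
                if ci == 0 and intensity == 30:
                    continue  # missing cell
                rows.append({"cell_id": f"c{ci}", "genotype": geno,
                             "intensity": intensity,
                             "value": 100 + intensity + off + rng.normal(0, 20)})
        res = anova(pd.DataFrame(rows), "mixed_repeated",
                    factors=("genotype", "intensity"), subject="cell_id")
        assert len(res) == 3
        assert all(0 <= r.p <= 1 for r in res)

    def test_rank_deficient_design_named(self):
        table = pd.DataFrame(
            {"value": [1.0, 2.0, 3.0, 4.0],
             "genotype": ["a", "a", "b", "b"],
             "age": ["x", "x", "y", "y"]}  # age aliased with genotype
        )
        with pytest.raises(ValueError, match="aliased"):
            anova(table, "two_way", factors=("genotype", "age"))

    def test_power_to_detect_planted_io_effect(self, rng):
        """Planted 66 % amplitude increase at study-like sample sizes
        (n = 10 vs 9 cells, intensities 10/20/30) is detected by the
        mixed model in >= 80 % of simulated experiments."""
        n_reps = 150
        hits = 0
        for _ in range(n_reps):
            rows = []
            for ci in range(19):
                geno = "Eu" if ci < 10 else "Ts"
                gain = (1.66 if geno == "Ts" else 1.0) * rng.lognormal(0, 0.35)
                for intensity in (10, 20, 30):
                    mu = 372.5 * gain * intensity / 30
                    rows.append({"cell_id": f"c{ci}", "genotype": geno,
                                 "intensity": intensity,
                                 "value": mu + rng.normal(0, 40)})
            res = {r.term: r for r in anova(pd.DataFrame(rows), "mixed_repeated",
                                            factors=("genotype", "intensity"),
                                            subject="cell_id")}
            if res["C(genotype, Sum)"].p < 0.05:
                hits += 1
        assert hits / n_reps >= 0.8


class TestSidak:
    def test_formula_example(self):
        assert sidak_adjust([0.01], m=3)[0] == pytest.approx(0.029701)

    def test_endpoints(self):
        out = sidak_adjust([0.0, 1.0], m=5)
        assert out[0] == 0.0
        assert out[1] == 1.0

    def test_never_exceeds_bonferroni(self):
        p = np.linspace(0.0, 1.0, 201)
        for m in (1, 2, 3, 5, 10):
            sidak = sidak_adjust(p, m=len(p) if m < len(p) else m)
            # compare elementwise at matched m
            sidak_m = 1 - (1 - p) ** m
            bonf_m = np.clip(p * m, 0, 1)
            assert np.all(sidak_m <= bonf_m + 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust([1.2])
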