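"""Repeated-measures ANOVA: epsilon identities, oracle equality, post hocs."""

import numpy as np
import pandas as pd
import pytest

from sclsettle.anova import (
    RepeatedMeasuresAnova,
    bonferroni,
    gg_epsilon,
    orthonormal_contrast,
    rm_anova,
)
from sclsettle.errors import AnovaDesignError


def long_format(Y, levels=None, groups=None):
    """Subjects x cells matrix -> long DataFrame."""
    n, p = Y.shape
    levels = levels if levels is not None else [f"L{j}" for j in range(p)]
    rows = []
    for s in range(n):
        for j in range(p):
            rows.append(
                dict(
                    eye=f"s{s}",
                    w=levels[j],
                    y=Y[s, j],
                    group=groups[s] if groups is not None else "g0",
                )
            )
    return pd.DataFrame(rows)


class TestEpsilon:
    def test_two_level_factor_has_epsilon_exactly_one(self, rng):
        Y = rng.normal(size=(12, 2))
        res = RepeatedMeasuresAnova(long_format(Y), "y", "eye", ["w"]).fit()
        eps = res.anova_table.set_index("effect").loc["w", "eps"]
        assert eps == 1.0

    def test_epsilon_bounds(self, rng):
        k = 5
        Y = rng.normal(size=(10, k))
        S = np.cov(Y.T)
        C = orthonormal_contrast(k)
        eps = gg_epsilon(S, C)
        assert 1.0 / (k - 1) <= eps <= 1.0


class TestOracle:
    def test_three_by_three_matches_definition_oracle(self):
        # small hand-checkable within-only design
        Y = np.array(
            [[10.0, 12.0, 15.0], [11.0, 14.0, 14.0], [9.0, 13.0, 17.0]]
        )
        res = RepeatedMeasuresAnova(long_format(Y), "y", "eye", ["w"]).fit()
        row = res.anova_table.set_index("effect").loc["w"]

        # oracle: classical cell-mean / subject decomposition from scratch
        n, k = Y.shape
        grand = Y.mean()
        ss_a = n * np.sum((Y.mean(axis=0) - grand) ** 2)
        ss_subj = k * np.sum((Y.mean(axis=1) - grand) ** 2)
        ss_tot = np.sum((Y - grand) ** 2)
        ss_err = ss_tot - ss_a - ss_subj
        F = (ss_a / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        assert row["F"] == pytest.approx(F, rel=1e-10)

        # oracle epsilon straight from the covariance definition
        S = np.cov(Y.T, ddof=1)
        C = orthonormal_contrast(k)
        M = C @ S @ C.T
        eps = np.trace(M) ** 2 / ((k - 1) * np.trace(M @ M))
        assert row["eps"] == pytest.approx(eps, rel=1e-10)

    def test_one_within_factor_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(8, 5)) + np.linspace(0, 2, 5)
        df = long_format(Y)
        ours = RepeatedMeasuresAnova(df, "y", "eye", ["w"]).fit()
        row = ours.anova_table.set_index("effect").loc["w"]
        theirs = pg.rm_anova(data=df, dv="y", within="w", subject="eye",
                             correction=True)
        assert row["F"] == pytest.approx(theirs["F"].iloc[0], rel=1e-8)
        assert row["eps"] == pytest.approx(theirs["eps"].iloc[0], rel=1e-6)
        assert row["p"] == pytest.approx(theirs["p_unc"].iloc[0], rel=1e-8)
        assert row["p_gg"] == pytest.approx(theirs["p_GG_corr"].iloc[0], rel=1e-6)

    def test_mixed_design_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n_per, k = 8, 4
        Y = rng.normal(size=(2 * n_per, k))
        Y[n_per:] += 1.5  # group offset
        groups = ["a"] * n_per + ["b"] * n_per
        df = long_format(Y, groups=groups)
        ours = RepeatedMeasuresAnova(df, "y", "eye", ["w"], between="group").fit()
        tbl = ours.anova_table.set_index("effect")
        theirs = pg.mixed_anova(data=df, dv="y", within="w", subject="eye",
                                between="group").set_index("Source")
        assert tbl.loc["group", "F"] == pytest.approx(
            theirs.loc["group", "F"], rel=1e-8
        )
        assert tbl.loc["w", "F"] == pytest.approx(theirs.loc["w", "F"], rel=1e-8)
        assert tbl.loc["w:group", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-8
        )


class TestInvariances:
    def test_within_effects_invariant_to_constant_shift(self, rng):
        Y = rng.normal(size=(9, 4))
        groups = ["a"] * 5 + ["b"] * 4
        a = RepeatedMeasuresAnova(long_format(Y, groups=groups), "y", "eye",
                                  ["w"], between="group").fit()
        b = RepeatedMeasuresAnova(long_format(Y + 57.0, groups=groups), "y",
                                  "eye", ["w"], between="group").fit()
        for eff in ("w", "w:group"):
            assert a.anova_table.set_index("effect").loc[eff, "F"] == pytest.approx(
                b.anova_table.set_index("effect").loc[eff, "F"], rel=1e-9
            )

    def test_two_within_factor_design_decomposes(self, rng):
        # time (3) x region (4) within, group between; smoke the full table
        times = [0, 120, 240]
        regions = list("ABCD")
        rows = []
        for s in range(10):
            g = "g1" if s < 5 else "g2"
            for ti, t in enumerate(times):
                for ri, r in enumerate(regions):
                    rows.append(
                        dict(eye=f"s{s}", time_min=t, region=r, group=g,
                             mean_um=300 - 20 * ti + 5 * ri
                             + rng.normal(0, 3) + (10 if g == "g2" else 0))
                    )
        res = rm_anova(pd.DataFrame(rows))
        effects = set(res.anova_table["effect"])
        assert {"group", "time_min", "region", "time_min:region",
                "time_min:group", "region:group",
                "time_min:region:group"} <= effects
        tbl = res.anova_table.set_index("effect")
        assert tbl.loc["time_min", "p_gg"] < 1e-6  # strong programmed effect
        assert (res.anova_table["eps"].dropna() <= 1.0 + 1e-12).all()

    def test_incomplete_subjects_dropped_with_count(self, rng):
        Y = rng.normal(size=(6, 3))
        df = long_format(Y)
        df = df[~((df["eye"] == "s0") & (df["w"] == "L1"))]
        res = RepeatedMeasuresAnova(df, "y", "eye", ["w"]).fit()
        assert res.n_dropped == 1 and res.n_subjects == 5

    def test_too_few_subjects_per_group_rejected(self, rng):
        Y = rng.normal(size=(3, 3))
        df = long_format(Y, groups=["a", "a", "b"])
        with pytest.raises(AnovaDesignError):
            RepeatedMeasuresAnova(df, "y", "eye", ["w"], between="group").fit()


class TestPosthoc:
    def test_bonferroni_multiplies_and_caps(self):
        assert bonferroni(0.004, 10) == pytest.approx(0.04)
        assert bonferroni(0.3, 10) == 1.0

    def test_pairwise_within_factor(self, rng):
        Y = rng.normal(size=(10, 3))
        Y[:, 2] += 5.0
        res = RepeatedMeasuresAnova(long_format(Y), "y", "eye", ["w"]).fit()
        pw = res.pairwise("w")
        assert len(pw) == 3
        assert (pw["p_bonf"] >= pw["p_unc"] - 1e-15).all()
        assert (pw["p_bonf"] <= 1.0).all()
        strong = pw[(pw["A"] == "L0") & (pw["B"] == "L2")]
        assert strong["p_bonf"].iloc[0] < 0.01
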