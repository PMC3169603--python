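"""Proportion transform, paired contrasts, and the within-subject ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from perffields.observer import ObserverParams, angular_modulation
from perffields.stats import (
    arcsine_transform,
    inverse_arcsine_transform,
    meridian_contrast,
    paired_t,
    rm_anova_2x2x8,
)

from conftest import LOCATIONS, binomial_cells, make_cells


class TestArcsineTransform:
    def test_endpoints_and_midpoint(self):
        assert arcsine_transform(0.0) == 0.0
        assert arcsine_transform(1.0) == pytest.approx(math.pi)
        assert arcsine_transform(0.5) == pytest.approx(math.pi / 2)

    def test_monotone_bijection_with_inverse(self):
        p = np.linspace(0, 1, 101)
        t = arcsine_transform(p)
        assert np.all(np.diff(t) > 0)
        assert np.allclose(inverse_arcsine_transform(t), p, atol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            arcsine_transform(-0.01)
        with pytest.raises(ValueError):
            arcsine_transform(1.01)


class TestPairedT:
    def test_identical_pairs_give_t_zero_p_one(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.statistic, r.p, r.mean_diff) == (0.0, 1.0, 0.0)
        assert r.df == 2

    def test_constant_nonzero_difference_is_infinite_t_limit(self):
        r = paired_t([1.5, 2.5, 3.5], [1.0, 2.0, 3.0])
        assert math.isinf(r.statistic) and r.statistic > 0
        assert r.p == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_textbook_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert r.df == 7
        d = x - y
        assert r.sem == pytest.approx(d.std(ddof=1) / math.sqrt(8), abs=1e-12)

    def test_rejects_unequal_or_missing(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            paired_t([1.0, np.nan], [0.0, 0.0])


class TestMeridianContrast:
    def test_identical_sets_give_zero(self):
        cells = make_cells(
            {
                (f"o{i}", d): {loc: 1.0 for loc in LOCATIONS}
                for i in range(4)
                for d in (0.0, -45.0)
            }
        )
        r = meridian_contrast(cells, 0.0, "horizontal_vs_vertical")
        assert r.statistic == 0.0 and r.mean_diff == 0.0

    def test_missing_location_raises(self):
        cells = make_cells({("o0", 0.0): {loc: 1.0 for loc in LOCATIONS[:-1]}})
        with pytest.raises(ValueError):
            meridian_contrast(cells, 0.0, "horizontal_vs_vertical")

    def test_unknown_axis_raises(self):
        cells = make_cells({("o0", 0.0): {loc: 1.0 for loc in LOCATIONS}})
        with pytest.raises(ValueError):
            meridian_contrast(cells, 0.0, "diagonal_vs_other")

    def test_simulated_hva_is_positive_upright_and_under_roll(self, rng):
        obs = ObserverParams(hva=0.2, vma=0.07)
        # accuracy proportional to angular modulation around 75%
        for roll in (0.0, 45.0):
            p_by_loc = {
                loc: 0.55 + 0.25 * angular_modulation(obs, a - roll)
                for loc, a in zip(
                    LOCATIONS, (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
                )
            }
            cells = binomial_cells(rng, p_by_loc, n_per_cell=112)
            r = meridian_contrast(cells, roll, "horizontal_vs_vertical")
            assert r.mean_diff > 0
            assert r.p < 0.01

    def test_rotating_field_and_frame_together_relabels_exactly(self):
        # Binomial outcomes are drawn per retinal cell from its own substream,
        # so rolling both the generating field and the analysis frame permutes
        # cell labels and must leave the contrast invariant bit for bit.
        obs = ObserverParams(hva=0.2, vma=0.07)
        angles = dict(zip(LOCATIONS, (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)))

        def simulate(roll):
            rows = []
            for o in range(4):
                for di, d in enumerate((0.0, -45.0)):
                    for loc, a in angles.items():
                        retinal = (a - roll) % 360.0
                        p = 0.55 + 0.25 * float(angular_modulation(obs, retinal))
                        cell_rng = np.random.default_rng(
                            np.random.SeedSequence(99, spawn_key=(o, di, int(retinal)))
                        )
                        k = cell_rng.binomial(56, p)
                        rows.append(
                            {
                                "observer_id": f"o{o}",
                                "distractor_tilt_deg": d,
                                "target_location": loc,
                                "transformed": arcsine_transform(k / 56),
                            }
                        )
            return pd.DataFrame(rows)

        for axis in ("horizontal_vs_vertical", "lower_vs_upper"):
            r0 = meridian_contrast(simulate(0.0), 0.0, axis)
            r45 = meridian_contrast(simulate(45.0), 45.0, axis)
            assert r0 == r45


class TestRmAnova:
    @staticmethod
    def random_design(seed, n_sub=4):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_sub):
            for a in ("upright", "tilted"):
                for b in (0.0, -45.0):
                    for c in LOCATIONS:
                        rows.append(
                            {
                                "observer_id": f"o{s}",
                                "head_posture": a,
                                "distractor_tilt_deg": b,
                                "target_location": c,
                                "transformed": rng.normal(),
                            }
                        )
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_oracles(self, seed):
        df = self.random_design(seed)
        mine = rm_anova_2x2x8(df)
        ref = AnovaRM(
            df,
            "transformed",
            "observer_id",
            within=["head_posture", "distractor_tilt_deg", "target_location"],
        ).fit().anova_table
        for effect in mine.index:
            assert mine.loc[effect, "F"] == pytest.approx(ref.loc[effect, "F Value"], abs=1e-8)
            assert mine.loc[effect, "df_num"] == ref.loc[effect, "Num DF"]
            assert mine.loc[effect, "df_den"] == ref.loc[effect, "Den DF"]
            assert mine.loc[effect, "p"] == pytest.approx(ref.loc[effect, "Pr > F"], abs=1e-8)

    def test_matches_brute_force_cell_means_partition(self):
        # Independent hand computation for the Location main effect.
        df = self.random_design(9)
        mine = rm_anova_2x2x8(df)
        y = (
            df.pivot_table(
                index="observer_id",
                columns=["head_posture", "distractor_tilt_deg", "target_location"],
                values="transformed",
            )
            .to_numpy()
            .reshape(4, 2, 2, 8)
        )
        gm = y.mean()
        loc_means = y.mean(axis=(0, 1, 2))
        ss_c = 4 * 2 * 2 * ((loc_means - gm) ** 2).sum()
        sub_means = y.mean(axis=(1, 2, 3))
        subloc = y.mean(axis=(1, 2))
        ss_cs = 2 * 2 * (
            (subloc - loc_means[None, :] - sub_means[:, None] + gm) ** 2
        ).sum()
        f = (ss_c / 7) / (ss_cs / 21)
        assert mine.loc["target_location", "F"] == pytest.approx(f, abs=1e-8)
        assert mine.loc["target_location", "partial_eta_sq"] == pytest.approx(
            ss_c / (ss_c + ss_cs), abs=1e-10
        )

    def test_constant_data_reports_degenerate_zero_f(self):
        df = self.random_design(0)
        df["transformed"] = 1.3
        tab = rm_anova_2x2x8(df)
        assert (tab["F"] == 0.0).all()
        assert tab["degenerate"].all()

    def test_pure_location_effect_dominates(self, rng):
        rows = []
        bump = {loc: (0.5 if loc in ("E", "W") else 0.0) for loc in LOCATIONS}
        for s in range(4):
            for a in ("upright", "tilted"):
                for b in (0.0, -45.0):
                    for c in LOCATIONS:
                        rows.append(
                            {
                                "observer_id": f"o{s}",
                                "head_posture": a,
                                "distractor_tilt_deg": b,
                                "target_location": c,
                                "transformed": bump[c] + rng.normal(0, 0.05),
                            }
                        )
        tab = rm_anova_2x2x8(pd.DataFrame(rows))
        assert tab["F"].idxmax() == "target_location"
        assert tab.loc["target_location", "p"] < 1e-6

    def test_incomplete_design_raises(self):
        df = self.random_design(0).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova_2x2x8(df)
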