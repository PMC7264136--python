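"""Statistics layer vs independent oracles (R shapiro.test values, pingouin,
direct quadrature of the studentized-range distribution)."""

import numpy as np
import pytest

from marquant.stats import (
    DegenerateSampleError,
    GroupSample,
    IncompleteDesignError,
    compare_conditions,
    games_howell,
    shapiro_wilk,
    welch_anova,
    welch_t_test,
)

from _oracles import studentized_range_sf_oracle

# W and p computed with R 4.3.3 stats::shapiro.test on the samples
# np.random.default_rng(1000 + i).normal(size=20), i = 0..49.
R_SHAPIRO = [
    (0.9323593009, 0.1714180876), (0.9760877602, 0.8743089182),
    (0.9480094509, 0.3378830949), (0.9742583726, 0.8409647808),
    (0.9498460552, 0.3647590203), (0.9384442750, 0.2240466749),
    (0.9414836868, 0.255736152), (0.9538233220, 0.4288684076),
    (0.9830432918, 0.967095356), (0.9573733499, 0.4928037057),
    (0.9364078301, 0.2049154284), (0.9750494735, 0.8557319138),
    (0.9790938038, 0.9218677332), (0.8859474500, 0.02267022871),
    (0.9481060434, 0.3392540771), (0.9864325937, 0.9889639378),
    (0.9586325261, 0.5169059363), (0.9169494571, 0.08656726967),
    (0.9777171985, 0.901341092), (0.9582630541, 0.5097610184),
    (0.9274651870, 0.1379974938), (0.8874052400, 0.02410250232),
    (0.9677572465, 0.7069898032), (0.9614739805, 0.573700115),
    (0.9525341659, 0.4072019876), (0.9654091668, 0.656505249),
    (0.9549728916, 0.448896756), (0.9727801139, 0.8121638582),
    (0.9603194939, 0.5502517586), (0.9575634936, 0.496397765),
    (0.9748566333, 0.852178379), (0.9530961991, 0.4165439127),
    (0.9484397279, 0.3440263471), (0.9696652324, 0.747787805),
    (0.9798724572, 0.9324438008), (0.9489533668, 0.3514821869),
    (0.9598734498, 0.5413239695), (0.9274710407, 0.1380333452),
    (0.9766275399, 0.8835677997), (0.9591562021, 0.5271329366),
    (0.9750794785, 0.8562820468), (0.8911801210, 0.02827118642),
    (0.9810948855, 0.9474392102), (0.9581898220, 0.5083519142),
    (0.9682908383, 0.7184499981), (0.9336561572, 0.181526838),
    (0.9530390323, 0.4155863434), (0.9612272041, 0.5686485206),
    (0.9571888545, 0.4893322534), (0.9548232441, 0.4462521711),
]


def _random_groups(rng, k=4, nmin=5, nmax=25, spread=True):
    groups = []
    for i in range(k):
        n = int(rng.integers(nmin, nmax))
        sd = float(rng.uniform(0.5, 3.0)) if spread else 1.0
        mu = float(rng.uniform(-1, 1))
        groups.append(GroupSample(label=f"g{i}", values=tuple(rng.normal(mu, sd, n))))
    return groups


class TestShapiroWilk:
    def test_matches_r_reference_values(self):
        for i, (w_ref, p_ref) in enumerate(R_SHAPIRO):
            x = np.random.default_rng(1000 + i).normal(size=20)
            res = shapiro_wilk(x)
            assert res.W == pytest.approx(w_ref, abs=1e-6)
            assert res.p_value == pytest.approx(p_ref, abs=1e-6)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=25)
        a = shapiro_wilk(x)
        b = shapiro_wilk(3.7 * x + 11.0)
        assert a.W == pytest.approx(b.W, abs=1e-10)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk([2.0] * 10)

    def test_too_small_sample(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk([1.0, 2.0])

    def test_gate_flag_advisory(self, rng):
        assert shapiro_wilk(rng.normal(size=20)).within_gate
        assert not shapiro_wilk(rng.normal(size=40)).within_gate

    def test_null_p_values_uniform(self):
        """Kolmogorov-Smirnov distance of null p-values from U(0,1) < 0.05."""
        rng = np.random.default_rng(77)
        ps = np.sort([shapiro_wilk(rng.normal(size=20)).p_value for _ in range(2000)])
        grid = (np.arange(1, 2001)) / 2000
        ks = max(np.abs(ps - grid).max(), np.abs(ps - grid + 1 / 2000).max())
        assert ks < 0.05


class TestWelchAnova:
    def test_identical_groups_f_zero(self):
        g = tuple(np.tile([1.0, 2.0, 3.0, 4.0], 2))
        groups = [GroupSample(f"g{i}", g) for i in range(3)]
        res = welch_anova(groups)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_equals_t_squared(self, rng):
        for _ in range(25):
            a, b = _random_groups(rng, k=2)
            f = welch_anova([a, b])
            t = welch_t_test(a, b)
            assert f.F == pytest.approx(t.t**2, abs=1e-9)
            assert f.df2 == pytest.approx(t.df, rel=1e-9)
            assert f.p_value == pytest.approx(t.p_value, abs=1e-9)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(25):
            groups = _random_groups(rng, k=4)
            df = pd.DataFrame(
                [(g.label, v) for g in groups for v in g.values],
                columns=["group", "value"],
            )
            ref = pg.welch_anova(data=df, dv="value", between="group")
            res = welch_anova(groups)
            assert res.F == pytest.approx(float(ref["F"][0]), rel=1e-6)
            assert res.df2 == pytest.approx(float(ref["ddof2"][0]), rel=1e-6)
            assert res.p_value == pytest.approx(float(ref["p_unc"][0]), abs=1e-6)

    def test_zero_variance_group_rejected(self):
        groups = [
            GroupSample("a", (1.0, 1.0, 1.0)),
            GroupSample("b", (1.0, 2.0, 3.0)),
        ]
        with pytest.raises(DegenerateSampleError):
            welch_anova(groups)

    def test_type_i_error_calibrated(self):
        """Null rejection rate at alpha=0.05 within 5% +/- 1% (k=4, unequal n/sd)."""
        rng = np.random.default_rng(12345)
        sizes = (8, 12, 20, 30)
        sds = (0.5, 1.0, 2.0, 4.0)
        n_sims, rejections = 4000, 0
        for _ in range(n_sims):
            groups = [
                GroupSample(f"g{i}", tuple(rng.normal(0.0, sd, n)))
                for i, (n, sd) in enumerate(zip(sizes, sds))
            ]
            if welch_anova(groups).p_value < 0.05:
                rejections += 1
        assert abs(rejections / n_sims - 0.05) <= 0.01


class TestGamesHowell:
    def test_identical_samples_p_one(self):
        g = (1.0, 2.0, 3.0, 4.0, 5.0)
        out = games_howell([GroupSample("a", g), GroupSample("b", g)])
        assert out[0].mean_diff == 0.0
        assert out[0].p_adjusted == pytest.approx(1.0)

    def test_pair_count(self, rng):
        groups = _random_groups(rng, k=4)
        assert len(games_howell(groups)) == 6

    def test_order_swap_symmetry(self, rng):
        a, b = _random_groups(rng, k=2)
        fwd = games_howell([a, b])[0]
        rev = games_howell([b, a])[0]
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff)
        assert rev.p_adjusted == pytest.approx(fwd.p_adjusted, abs=1e-12)

    def test_matches_quadrature_oracle(self, rng):
        for _ in range(8):
            groups = _random_groups(rng, k=3)
            for cmp_ in games_howell(groups):
                ref = studentized_range_sf_oracle(cmp_.q, k=3, df=cmp_.df)
                assert cmp_.p_adjusted == pytest.approx(ref, abs=1e-4)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(10):
            groups = _random_groups(rng, k=3)
            df = pd.DataFrame(
                [(g.label, v) for g in groups for v in g.values],
                columns=["group", "value"],
            )
            ref = pg.pairwise_gameshowell(data=df, dv="value", between="group")
            ours = {frozenset((c.group_a, c.group_b)): c for c in games_howell(groups)}
            for _, row in ref.iterrows():
                c = ours[frozenset((row["A"], row["B"]))]
                assert c.p_adjusted == pytest.approx(float(row["pval"]), abs=1e-6)
                assert c.df == pytest.approx(float(row["df"]), rel=1e-9)


class TestWelchT:
    def test_identical_samples(self):
        g = GroupSample("a", (1.0, 2.0, 3.0))
        res = welch_t_test(g, GroupSample("b", (1.0, 2.0, 3.0)))
        assert res.t == 0.0 and res.p_value == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        a, b = _random_groups(rng, k=2)
        fwd = welch_t_test(a, b)
        rev = welch_t_test(b, a)
        assert rev.t == pytest.approx(-fwd.t)
        assert rev.p_value == pytest.approx(fwd.p_value)

    def test_matches_scipy_reference(self, rng):
        from scipy import stats as sps

        for _ in range(50):
            a, b = _random_groups(rng, k=2)
            res = welch_t_test(a, b)
            ref = sps.ttest_ind(a.values, b.values, equal_var=False)
            assert res.t == pytest.approx(float(ref.statistic), abs=1e-6)
            assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-6)
            assert res.df == pytest.approx(float(ref.df), rel=1e-9)

    def test_pooled_option_matches_student(self, rng):
        from scipy import stats as sps

        a, b = _random_groups(rng, k=2)
        res = welch_t_test(a, b, pooled=True)
        ref = sps.ttest_ind(a.values, b.values, equal_var=True)
        assert res.t == pytest.approx(float(ref.statistic), abs=1e-9)

    def test_both_zero_variance_rejected(self):
        with pytest.raises(DegenerateSampleError):
            welch_t_test(GroupSample("a", (1.0, 1.0)), GroupSample("b", (2.0, 2.0)))


class TestCompareConditions:
    def _table(self, rng, shift_02=0.0):
        return {
            (0.2, 70.0): rng.normal(shift_02, 1, 20),
            (0.2, 100.0): rng.normal(shift_02, 1, 20),
            (0.3, 70.0): rng.normal(0, 1, 20),
            (0.3, 100.0): rng.normal(0, 1, 20),
        }

    def test_full_design_yields_four_tests(self, rng):
        out = compare_conditions(self._table(rng))
        assert len(out) == 4

    def test_identical_cells_nonsignificant(self):
        base = list(np.random.default_rng(5).normal(0, 1, 20))
        table = {(v, k): base for v in (0.2, 0.3) for k in (70.0, 100.0)}
        out = compare_conditions(table)
        assert all(r.p_value == pytest.approx(1.0) for r in out.values())

    def test_voxel_effect_detected_kvp_not(self):
        """0.2-mm cells shifted by 3 sd: voxel margins significant, kVp not."""
        rng = np.random.default_rng(99)
        out = compare_conditions(self._table(rng, shift_02=3.0))
        voxel_tests = [r for name, r in out.items() if "kVp:" in name]
        kvp_tests = [r for name, r in out.items() if name.startswith("voxel")]
        assert all(r.p_value < 0.05 for r in voxel_tests)
        assert all(r.p_value > 0.05 for r in kvp_tests)

    def test_missing_cell_rejected(self, rng):
        table = self._table(rng)
        del table[(0.3, 100.0)]
        with pytest.raises(IncompleteDesignError, match="0.3"):
            compare_conditions(table)
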