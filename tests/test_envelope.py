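"""Envelope thresholds, classification, derivation and agreement maps."""

import numpy as np
import pandas as pd
import pytest

from peatenvelope.envelope import (AGREEMENT_CODES, NARROW, WIDE,
                                   EnvelopeThresholds, agreement_map,
                                   build_environment, classify,
                                   classify_to_mask, derive_thresholds,
                                   env_space_histograms, get_preset)
from peatenvelope.grids import PeatMask
from peatenvelope.evaluation import confusion


def brute_force_classify(env, thr, missing_passes=True):
    """Independent per-cell loop over every bound check."""
    out = []
    for _, rec in env.iterrows():
        ok = True
        for var, (lo, hi) in thr.bounds.items():
            if lo is None and hi is None:
                continue
            v = rec[var]
            if np.isnan(v):
                if not missing_passes:
                    ok = False
                continue
            if lo is not None and v < lo:
                ok = False
            if hi is not None and v > hi:
                ok = False
        out.append(ok)
    return np.array(out, dtype=bool)


def random_env(rng, n):
    return pd.DataFrame({
        "MI": rng.uniform(0, 3, n),
        "MAT": rng.uniform(-10, 10, n),
        "slope": rng.uniform(0, 8, n),
        "ALT": np.where(rng.random(n) < 0.3, np.nan,
                        rng.uniform(0.3, 3.5, n)),
    })


def random_thresholds(rng):
    bounds = {}
    for var, lo_range, hi_range in (("MI", (0, 1.5), (1.5, 3)),
                                    ("MAT", (-8, 0), (0, 8)),
                                    ("slope", (0, 2), (2, 8)),
                                    ("ALT", (0.2, 1.5), (1.5, 3.5))):
        lo = rng.uniform(*lo_range) if rng.random() < 0.7 else None
        hi = rng.uniform(*hi_range) if rng.random() < 0.7 else None
        bounds[var] = (lo, hi)
    if all(lo is None and hi is None for lo, hi in bounds.values()):
        bounds["MI"] = (1.0, None)
    return EnvelopeThresholds(bounds=bounds)


class TestThresholdPresets:
    def test_narrow_matches_published_calibration(self):
        assert NARROW.bounds["MI"] == (1.7, None)
        assert NARROW.bounds["MAT"] == (0.0, 2.0)
        assert NARROW.bounds["slope"] == (None, 2.0)
        assert NARROW.bounds["ALT"] == (None, None)

    def test_wide_matches_published_calibration(self):
        assert WIDE.bounds["MI"] == (0.5, None)
        assert WIDE.bounds["MAT"] == (-5.0, 2.0)
        assert WIDE.bounds["slope"] == (0.0, 5.0)
        assert WIDE.bounds["ALT"] == (None, 2.3)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            get_preset("nonexistent")

    def test_crossed_bounds_rejected(self):
        with pytest.raises(ValueError):
            EnvelopeThresholds(bounds={"MI": (2.0, 1.0)})

    def test_all_nd_rejected(self):
        with pytest.raises(ValueError):
            EnvelopeThresholds(bounds={"MI": (None, None)})

    def test_yaml_round_trip(self, tmp_path):
        NARROW.to_yaml(tmp_path / "t.yaml")
        back = EnvelopeThresholds.from_yaml(tmp_path / "t.yaml")
        assert back.bounds == NARROW.bounds and back.name == "narrow"


class TestBuildEnvironment:
    def test_derived_columns(self, truth_clean):
        env = truth_clean.env
        clim = truth_clean.clim
        r, c = env["row"].to_numpy(), env["col"].to_numpy()
        np.testing.assert_allclose(env["MAT"], clim.tmp.mean(axis=0)[r, c])
        np.testing.assert_allclose(env["MAP"], clim.pre.sum(axis=0)[r, c])
        np.testing.assert_allclose(env["PJJA"],
                                   clim.pre[5:8].sum(axis=0)[r, c])

    def test_constant_inputs_give_constant_predictors(self, small_grid):
        from peatenvelope.grids import MonthlyClimatology, RasterField
        from peatenvelope.radiation import moisture_index_field
        shape = (12, *small_grid.shape)
        clim = MonthlyClimatology(
            grid=small_grid, tmp=np.full(shape, 1.0),
            pre=np.full(shape, 400.0 / 12), sun=np.full(shape, 0.5))
        mi, _ = moisture_index_field(clim)
        slope = RasterField(grid=small_grid,
                            values=np.zeros(small_grid.shape))
        env = build_environment(clim, mi, slope)
        np.testing.assert_allclose(env["MAT"], 1.0)
        np.testing.assert_allclose(env["MAP"], 400.0)

    def test_grid_mismatch_instructs_regrid(self, truth_clean, small_grid):
        from peatenvelope.grids import RasterField
        wrong = RasterField(grid=small_grid,
                            values=np.zeros(small_grid.shape))
        with pytest.raises(ValueError, match="regrid"):
            build_environment(truth_clean.clim, truth_clean.mi, wrong)


class TestClassify:
    def _cell(self, **kw):
        base = {"MI": np.nan, "MAT": np.nan, "slope": np.nan, "ALT": np.nan}
        base.update(kw)
        return pd.DataFrame([base])

    def test_narrow_presence_case(self):
        env = self._cell(MI=1.8, MAT=1.0, slope=1.0)
        assert classify(env, NARROW)[0]

    def test_narrow_rejects_low_mi(self):
        env = self._cell(MI=1.6, MAT=1.0, slope=1.0)
        assert not classify(env, NARROW)[0]

    def test_wide_presence_case(self):
        env = self._cell(MI=0.6, MAT=-4.0, slope=4.0, ALT=2.0)
        assert classify(env, WIDE)[0]

    def test_bounds_inclusive_by_default(self):
        env = self._cell(MI=1.7, MAT=0.0, slope=2.0)
        assert classify(env, NARROW)[0]

    def test_strict_bounds_exclude_boundary(self):
        env = self._cell(MI=1.7, MAT=1.0, slope=1.0)
        assert not classify(env, NARROW, strict_bounds=True)[0]

    def test_missing_alt_passes_by_default(self):
        env = self._cell(MI=0.6, MAT=-4.0, slope=4.0, ALT=np.nan)
        assert classify(env, WIDE)[0]
        assert not classify(env, WIDE, missing_passes=False)[0]

    def test_unknown_variable_in_thresholds(self):
        thr = EnvelopeThresholds(bounds={"GDD": (100.0, None)})
        with pytest.raises(KeyError):
            classify(self._cell(MI=1.0), thr)

    def test_matches_brute_force_oracle(self, rng):
        env = random_env(rng, 400)
        for _ in range(20):
            thr = random_thresholds(rng)
            for mp in (True, False):
                np.testing.assert_array_equal(
                    classify(env, thr, missing_passes=mp),
                    brute_force_classify(env, thr, missing_passes=mp))

    def test_tightening_bound_never_adds_presence(self, rng):
        env = random_env(rng, 500)
        base = EnvelopeThresholds(bounds={"MI": (1.0, None),
                                          "MAT": (-5.0, 5.0)})
        n_base = classify(env, base).sum()
        for tighter in (EnvelopeThresholds(bounds={"MI": (1.5, None),
                                                   "MAT": (-5.0, 5.0)}),
                        EnvelopeThresholds(bounds={"MI": (1.0, None),
                                                   "MAT": (-5.0, 3.0)}),
                        EnvelopeThresholds(bounds={"MI": (1.0, 2.0),
                                                   "MAT": (-5.0, 5.0),
                                                   "slope": (None, 4.0)})):
            assert classify(env, tighter).sum() <= n_base

    def test_order_invariance(self, rng):
        env = random_env(rng, 300)
        perm = rng.permutation(len(env))
        shuffled = env.iloc[perm].reset_index(drop=True)
        np.testing.assert_array_equal(classify(env, WIDE)[perm],
                                      classify(shuffled, WIDE))


class TestDeriveThresholds:
    def test_minmax_on_small_sample(self):
        env = pd.DataFrame({"MI": [1.8, 1.9, 2.0, 1.85, 1.95]})
        thr = derive_thresholds(env, np.ones(5, bool), variables=("MI",))
        assert thr.bounds["MI"] == (1.8, 2.0)

    def test_quantile_q0_equals_minmax(self, rng):
        env = pd.DataFrame({"MI": rng.uniform(1, 3, 50)})
        ones = np.ones(50, bool)
        mm = derive_thresholds(env, ones, ("MI",), method="minmax")
        q0 = derive_thresholds(env, ones, ("MI",), method="quantile", q=0.0)
        assert mm.bounds == q0.bounds

    def test_quantile_tighter_than_minmax(self, rng):
        env = pd.DataFrame({"MI": rng.uniform(1, 3, 500)})
        ones = np.ones(500, bool)
        mm = derive_thresholds(env, ones, ("MI",))
        qt = derive_thresholds(env, ones, ("MI",), method="quantile", q=0.05)
        assert qt.bounds["MI"][0] > mm.bounds["MI"][0]
        assert qt.bounds["MI"][1] < mm.bounds["MI"][1]

    def test_too_few_presence_cells(self):
        env = pd.DataFrame({"MI": [1.8, 1.9, 2.0]})
        with pytest.raises(ValueError, match="at least 5"):
            derive_thresholds(env, np.ones(3, bool), ("MI",))

    def test_invalid_q(self, rng):
        env = pd.DataFrame({"MI": rng.uniform(1, 3, 50)})
        with pytest.raises(ValueError):
            derive_thresholds(env, np.ones(50, bool), ("MI",),
                              method="quantile", q=0.6)

    def test_envelope_covers_its_own_support(self, truth_clean):
        env = truth_clean.env
        presence = truth_clean.envelope_presence
        thr = derive_thresholds(env, presence, ("MI", "MAT", "slope"),
                                nd_variables=("ALT",))
        re_classified = classify(env, thr)
        assert re_classified[presence].all()

    def test_recovers_generating_thresholds_within_bin_width(self,
                                                             truth_clean):
        env = truth_clean.env
        presence = truth_clean.envelope_presence
        thr = derive_thresholds(env, presence, ("MI", "MAT"),
                                nd_variables=("ALT", "slope"))
        # one 30-bin environmental bin width of the pooled variable range
        for var, true_lo in (("MI", 1.7), ("MAT", 0.0)):
            width = (env[var].max() - env[var].min()) / 30.0
            lo, hi = thr.bounds[var]
            assert lo >= true_lo - 1e-9
            assert lo - true_lo <= width


class TestEnvSpaceHistograms:
    def test_small_example(self):
        t = pd.DataFrame({"MI": [0.5, 1.5, 1.5]})
        out = env_space_histograms({"d": t}, variables=("MI",),
                                   edges={"MI": np.array([0.0, 1.0, 2.0])})
        counts = out.sort_values("bin_left")["count"].tolist()
        assert counts == [1, 2]

    def test_counts_conserve_defined_cells(self, truth_clean):
        env = truth_clean.env
        present = truth_clean.envelope_presence
        out = env_space_histograms({"all": env, "peat": env[present]},
                                   variables=("MI", "MAT", "slope"))
        for label, tbl in (("all", env), ("peat", env[present])):
            for var in ("MI", "MAT", "slope"):
                total = out[(out.dataset == label)
                            & (out.variable == var)]["count"].sum()
                assert total == tbl[var].notna().sum()

    def test_matches_brute_force_binning(self, rng):
        a = pd.DataFrame({"MI": rng.uniform(0, 3, 200)})
        b = pd.DataFrame({"MI": rng.uniform(1, 4, 100)})
        edges = np.linspace(0, 4, 9)
        out = env_space_histograms({"a": a, "b": b}, variables=("MI",),
                                   edges={"MI": edges})
        for label, tbl in (("a", a), ("b", b)):
            got = out[out.dataset == label].sort_values("bin_left")
            for (_, row) in got.iterrows():
                v = tbl["MI"].to_numpy()
                if row.bin_right == edges[-1]:
                    expect = ((v >= row.bin_left) & (v <= row.bin_right)).sum()
                else:
                    expect = ((v >= row.bin_left) & (v < row.bin_right)).sum()
                assert row["count"] == expect


class TestAgreementMap:
    def _mask(self, grid, presence):
        return PeatMask(grid=grid, presence=presence)

    def test_perfect_agreement_only_both_and_neither(self, small_grid, rng):
        p = rng.random(small_grid.shape) < 0.4
        am = agreement_map(self._mask(small_grid, p),
                           self._mask(small_grid, p))
        assert am.counts["model_only"] == 0 and am.counts["map_only"] == 0
        assert am.counts["both"] == p.sum()

    def test_all_true_vs_all_false(self, small_grid):
        am = agreement_map(
            self._mask(small_grid, np.ones(small_grid.shape, bool)),
            self._mask(small_grid, np.zeros(small_grid.shape, bool)))
        assert am.counts["model_only"] == np.prod(small_grid.shape)

    def test_counts_reconcile_with_confusion(self, rng):
        from peatenvelope.grids import GridSpec
        grid = GridSpec(lat_min=30.0, lat_max=30.0 + 20 / 6,
                        lon_min=100.0, lon_max=100.0 + 20 / 6)
        p = rng.random(grid.shape) < 0.5
        o = rng.random(grid.shape) < 0.3
        am = agreement_map(self._mask(grid, p), self._mask(grid, o))
        cc = confusion(p, o)
        assert am.counts["both"] == cc.tp
        assert am.counts["model_only"] == cc.fp
        assert am.counts["map_only"] == cc.fn
        assert am.counts["neither"] == cc.tn

    def test_grid_mismatch(self, small_grid, truth_clean):
        with pytest.raises(ValueError):
            agreement_map(
                self._mask(small_grid, np.zeros(small_grid.shape, bool)),
                truth_clean.peat)


def test_classify_to_mask_scatters_onto_grid(truth_clean):
    mask = classify_to_mask(truth_clean.env, truth_clean.true_thresholds,
                            truth_clean.grid)
    r = truth_clean.env["row"].to_numpy()
    c = truth_clean.env["col"].to_numpy()
    np.testing.assert_array_equal(mask.presence[r, c],
                                  truth_clean.envelope_presence)
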