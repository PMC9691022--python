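"""Cross-phase prediction: HC3 regressions, the specification grid, pattern
prediction from beta maps, and pooled beta comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from condrel import (
    BinaryMask,
    PredictionSpec,
    box_roi,
    default_prediction_pairs,
    ols_hc3,
    phase_pattern_prediction,
    pooled_beta_comparison,
    predict_grid,
    simulate_stat_map_pair,
    strength_label,
)


def hc3_bruteforce(x, y):
    """Sandwich (X'X)^-1 X' diag(e^2/(1-h)^2) X (X'X)^-1 with the hat matrix
    computed explicitly."""
    X = np.column_stack([np.ones_like(x, dtype=float), x])
    xtx_inv = np.linalg.inv(X.T @ X)
    H = X @ xtx_inv @ X.T
    beta = xtx_inv @ X.T @ y
    e = y - X @ beta
    omega = np.diag(e ** 2 / (1 - np.diag(H)) ** 2)
    cov = xtx_inv @ X.T @ omega @ X @ xtx_inv
    return beta, cov


def measures_frame(values: dict, timepoint="T0", stimulus="DISC",
                   transform="RAW", ranked=False):
    rows = []
    for code, vals in values.items():
        for i, v in enumerate(vals):
            rows.append({"participant": f"P{i}", "timepoint": timepoint, "code": code,
                         "stimulus": stimulus, "transform": transform,
                         "ranked": ranked, "value": v})
    return pd.DataFrame(rows)


class TestOlsHC3:
    def test_worked_example(self):
        res = ols_hc3([0, 1, 2], [0, 1, 3])
        assert res.slope == pytest.approx(1.5)
        assert res.se == pytest.approx(0.7071, abs=1e-4)
        assert res.beta_std == pytest.approx(0.982, abs=1e-3)
        assert res.se_type == "HC3"

    def test_perfect_fit(self):
        res = ols_hc3([0.0, 1, 2, 3], [0.0, 1, 2, 3])
        assert res.beta_std == pytest.approx(1.0)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_sandwich(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = 0.7 * x + rng.normal(size=n) * (1 + np.abs(x))
            res = ols_hc3(x, y)
            beta, cov = hc3_bruteforce(x, y)
            assert res.slope == pytest.approx(beta[1], abs=1e-10)
            assert res.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_beta_std_is_pearson_r(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            x = rng.normal(size=20)
            y = rng.normal(size=20) + 0.4 * x
            res = ols_hc3(x, y)
            assert res.beta_std == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)

    def test_hc3_close_to_classical_when_homoskedastic(self):
        rng = np.random.default_rng(2)
        n = 10_000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        robust = ols_hc3(x, y)
        classical = stats.linregress(x, y)
        assert robust.se == pytest.approx(classical.stderr, rel=0.02)

    def test_ranked_beta_equals_spearman(self):
        from condrel import rank_transform

        rng = np.random.default_rng(3)
        x = rng.lognormal(size=25)
        y = x ** 2 + rng.normal(size=25)
        res = ols_hc3(rank_transform(x), rank_transform(y))
        assert res.beta_std == pytest.approx(stats.spearmanr(x, y)[0], abs=1e-12)

    def test_leverage_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="leverage"):
            ols_hc3([0, 0, 0, 1], [0, 1, 2, 3])

    def test_zero_criterion_variance_rejected(self):
        with pytest.raises(ValueError, match="criterion"):
            ols_hc3([0, 1, 2, 3], [1, 1, 1, 1])

    @pytest.mark.parametrize("beta, label", [(0.1, "weak"), (-0.39, "weak"),
                                             (0.4, "moderate"), (-0.69, "moderate"),
                                             (0.7, "strong"), (-1.0, "strong")])
    def test_strength_labels(self, beta, label):
        assert strength_label(beta) == label


class TestPredictGrid:
    def test_default_pairs_include_recall_prediction(self):
        assert ("AVE_ACQ", "FIRST_EXT") in default_prediction_pairs()
        assert len(default_prediction_pairs()) == 11

    def test_predictor_must_precede_criterion(self):
        with pytest.raises(ValueError, match="precede"):
            PredictionSpec("FIRST_RITEST", "AVE_ACQ")
        with pytest.raises(ValueError, match="precede"):
            PredictionSpec("AVE_ACQ", "LAST2_ACQ")

    def test_grid_completes_with_per_cell_errors(self):
        m = measures_frame({"AVE_ACQ": [1, 2, 3, 4, 5], "FIRST_EXT": [1, 1, 1, 1, 1]})
        grid = predict_grid(m, [PredictionSpec("AVE_ACQ", "FIRST_EXT")])
        assert len(grid) == 1
        assert grid.iloc[0]["error"] is not None
        assert np.isnan(grid.iloc[0]["beta_std"])

    def test_recovers_known_association(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = x * 0.8 + rng.normal(size=60) * 0.6
        m = measures_frame({"AVE_ACQ": x, "FIRST_EXT": y})
        grid = predict_grid(m, [PredictionSpec("AVE_ACQ", "FIRST_EXT")])
        cell = grid.iloc[0]
        assert cell["beta_std"] == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)
        assert cell["significant"]

    def test_type_one_error_rate_without_coupling(self):
        """Independent predictor/criterion: ~5% of cells flagged significant."""
        rng = np.random.default_rng(42)
        spec = PredictionSpec("AVE_ACQ", "FIRST_EXT")
        hits = 0
        n_sims = 1000
        for _ in range(n_sims):
            m = measures_frame({"AVE_ACQ": rng.normal(size=40),
                                "FIRST_EXT": rng.normal(size=40)})
            hits += bool(predict_grid(m, [spec]).iloc[0]["significant"])
        assert hits / n_sims == pytest.approx(0.05, abs=0.02)


class TestPhasePatternPrediction:
    def test_identity_maps_give_unit_correlation(self):
        maps, _ = zip(*(simulate_stat_map_pair((6, 6, 3), 0.0, seed=s) for s in range(4)))
        regions = {"whole": BinaryMask(np.ones((6, 6, 3), bool))}
        out = phase_pattern_prediction(list(maps), list(maps), regions)
        assert out.mean_r.iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_independent_maps_average_near_zero(self):
        pairs = [simulate_stat_map_pair((12, 12, 6), 0.0, seed=s) for s in range(20)]
        acq = [p[0] for p in pairs]
        ext = [p[1] for p in pairs]
        regions = {"whole": BinaryMask(np.ones((12, 12, 6), bool))}
        out = phase_pattern_prediction(acq, ext, regions)
        assert out.mean_r.iloc[0] == pytest.approx(0.0, abs=0.05)

    def test_single_box_region_reduces_to_scalar_mean(self):
        from condrel import pattern_correlation

        pairs = [simulate_stat_map_pair((10, 10, 5), 0.5, seed=s) for s in range(5)]
        region = box_roi((8, 8, 4), (8, 8, 4), shape=(10, 10, 5))
        out = phase_pattern_prediction([p[0] for p in pairs], [p[1] for p in pairs],
                                       {"box": region})
        zs = [np.arctanh(pattern_correlation(a, b, region)) for a, b in pairs]
        assert out.mean_r.iloc[0] == pytest.approx(np.tanh(np.mean(zs)), abs=1e-12)


class TestPooledBetaComparison:
    def _grid(self, betas_raw, betas_log):
        rows = []
        for i, (br, bl) in enumerate(zip(betas_raw, betas_log)):
            base = {"predictor": "AVE_ACQ", "criterion": "FIRST_EXT",
                    "stimulus": "DISC", "ranked": False}
            rows.append({**base, "transform": "RAW", "beta_std": br})
            rows.append({**base, "transform": "LOG", "beta_std": bl})
            base["predictor"] = f"A{i}"  # make cells distinct
            rows[-2]["predictor"] = rows[-1]["predictor"] = f"A{i}"
        return pd.DataFrame(rows)

    def test_identical_groups_are_null(self):
        b = [0.1, 0.2, 0.3, 0.4]
        res = pooled_beta_comparison(self._grid(b, b), "transform", "RAW", "LOG")
        assert res.statistic == 0.0 and res.cohens_d == 0.0 and res.p == 1.0

    def test_constant_difference_is_degenerate(self):
        res_grid = self._grid([0.1, 0.2, 0.3], list(np.tanh(np.arctanh([0.1, 0.2, 0.3]) + 0.1)))
        with pytest.raises(ValueError, match="degenerate"):
            pooled_beta_comparison(res_grid, "transform", "RAW", "LOG", paired=True)

    def test_paired_requested_on_unmatched_cells_is_an_error(self):
        g = self._grid([0.1, 0.2, 0.3, 0.4], [0.2, 0.3, 0.4, 0.5])
        g = g.drop(index=1)  # break the one-to-one match
        with pytest.raises(ValueError, match="match"):
            pooled_beta_comparison(g, "transform", "RAW", "LOG", paired=True)

    def test_detects_systematic_shift(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0.1, 0.5, 12)
        log = np.tanh(np.arctanh(raw) + rng.normal(0.3, 0.05, 12))
        res = pooled_beta_comparison(self._grid(raw, log), "transform", "RAW", "LOG")
        assert res.method == "paired_t"
        assert res.p < 0.01 and res.statistic < 0
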