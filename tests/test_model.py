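"""Quantity grids, the chi2 machinery, and the proportional R2 model fit."""

import numpy as np
import pandas as pd
import pytest

from iondetail.grids import DEFAULT_P_GRID, QuantityGrid, quality_curves
from iondetail.icsd import TargetGeometry
from iondetail.model import (
    R2CrossSectionModel,
    coefficient_of_determination,
    grid_fit,
    modified_chi2,
    optimal_K,
)
from iondetail.synth import (
    SyntheticStudySpec,
    generate_survival_dataset,
    make_quantity_grid,
    parametric_icsd,
)


class TestChi2AndK:
    def test_perfect_proportionality_is_zero(self):
        assert modified_chi2([(57.0, 1.0), (28.5, 0.5)], 57.0) == 0.0

    def test_hand_sum(self):
        assert modified_chi2([(2.0, 1.0), (4.0, 1.0)], 3.0) == pytest.approx(2.0)

    def test_parabola_vertex_matches_dense_scan(self):
        # calculus oracle: chi2(K) is a parabola with vertex at
        # sum(sigma r) / sum(r^2); compare against a dense K scan
        rng = np.random.default_rng(2)
        pairs = [(float(s), float(r)) for s, r in
                 zip(rng.uniform(1, 80, 25), rng.uniform(0.05, 1, 25))]
        arr = np.array(pairs)
        vertex = float(arr[:, 0] @ arr[:, 1]) / float(arr[:, 1] @ arr[:, 1])
        ks = np.linspace(vertex - 5, vertex + 5, 20001)
        chi = [modified_chi2(pairs, k) for k in ks]
        assert optimal_K(pairs) == pytest.approx(vertex, rel=1e-12)
        assert optimal_K(pairs) == pytest.approx(ks[int(np.argmin(chi))], abs=1e-3)

    def test_least_squares_mean(self):
        assert optimal_K([(2.0, 1.0), (4.0, 1.0)]) == pytest.approx(3.0)

    def test_homogeneity(self):
        pairs = [(2.0, 0.4), (5.0, 0.9)]
        scaled = [(2.0 * 7, 0.4), (5.0 * 7, 0.9)]
        assert optimal_K(scaled) == pytest.approx(7 * optimal_K(pairs))

    def test_grid_mode_agrees_within_one_step(self):
        pairs = [(57.0, 1.0), (28.0, 0.5), (13.0, 0.25)]
        closed = optimal_K(pairs, mode="closed_form")
        gridded = optimal_K(pairs, mode="grid", k_grid=(1.0, 200.0, 1.0))
        assert abs(closed - gridded) <= 1.0

    def test_empty_and_degenerate_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            modified_chi2([], 3.0)
        with pytest.raises(ValueError, match="unidentifiable"):
            optimal_K([(2.0, 0.0)])


class TestCoefficientOfDetermination:
    def test_perfect_model(self):
        assert coefficient_of_determination([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_model_is_zero(self):
        assert coefficient_of_determination([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)

    def test_hand_computation(self):
        # SS_res = 1, SS_tot = 2 -> 0.5
        assert coefficient_of_determination([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            coefficient_of_determination([2, 2], [1, 2])


@pytest.fixture(scope="module")
def grid():
    return make_quantity_grid(
        "4He", TargetGeometry(2.3, 3.4),
        energies_MeV_per_u=np.geomspace(0.3, 300, 12),
    )


class TestQuantityGrid:

    def test_frame_round_trip(self, grid):
        back = QuantityGrid.from_frame(grid.to_frame())
        np.testing.assert_allclose(back.energies, grid.energies)
        np.testing.assert_allclose(back.m1, grid.m1)
        np.testing.assert_allclose(back.r2, grid.r2, atol=1e-15)
        np.testing.assert_allclose(back.p_grid, grid.p_grid)
        for k in grid.fk:
            np.testing.assert_allclose(back.fk[k], grid.fk[k])

    def test_r2_at_grid_nodes_exact(self, grid):
        e = float(grid.energies[4])
        assert grid.r2_at(e, 0.35) == pytest.approx(grid.r2[4, grid.p_index(0.35)])

    def test_p_off_grid_rejected(self, grid):
        with pytest.raises(ValueError, match="not a grid point"):
            grid.p_index(0.355)

    def test_quality_curves_identities(self, grid):
        curves = quality_curves(grid, 1.0)
        # at p = 1 the R2 column is exactly F2
        np.testing.assert_allclose(curves["r2"], grid.fk[2], atol=1e-12)
        # Fk columns ordered F2 >= F3 >= ... >= F7 at every energy
        for k in range(2, 7):
            assert np.all(curves[f"f{k}"] >= curves[f"f{k+1}"] - 1e-15)

    def test_damage_density_has_single_interior_maximum(self):
        # Poisson ICSD family scanned densely in its mean: R2(p)/M1 rises,
        # peaks once, then falls (the RBE-like characteristic curve)
        from iondetail.icsd import r2 as r2_of

        mus = np.geomspace(0.05, 30.0, 120)
        ratio = np.array(
            [r2_of(parametric_icsd("poisson", {"mu": m}), 0.35) / m for m in mus]
        )
        imax = int(ratio.argmax())
        assert 0 < imax < ratio.size - 1
        assert np.all(np.diff(ratio[: imax + 1]) > 0)
        assert np.all(np.diff(ratio[imax:]) < 0)
        # both tails fall well below the peak (the high-mu overkill decay
        # is ~1/mu, so the right tail shrinks slowly but monotonically)
        assert ratio[0] < 0.05 * ratio[imax] and ratio[-1] < 0.5 * ratio[imax]


class TestModelFit:
    def test_noise_free_recovery(self, grid_set, noise_free_records):
        result = R2CrossSectionModel(noise_free_records, grid_set).fit()
        assert result.best_p == pytest.approx(0.35, abs=0.0100001)
        assert result.best_K == pytest.approx(57.0, rel=0.01)
        assert result.best_geometry.diameter_nm == pytest.approx(2.3)
        assert result.rsquared > 0.999

    def test_surface_normalized_to_unit_max(self, grid_set, noise_free_records):
        result = R2CrossSectionModel(noise_free_records, grid_set).fit()
        surface = result.chi2_surface.to_numpy()
        assert np.nanmax(surface) == pytest.approx(1.0, abs=1e-12)
        assert np.all(surface[np.isfinite(surface)] > 0)
        # minimum attained at the reported best point
        i = int(np.argmin(np.abs(result.chi2_surface.index.to_numpy()
                                 - result.best_p)))
        j = list(result.chi2_surface.columns).index(result.best_geometry.label)
        assert surface[i, j] == pytest.approx(np.nanmin(surface))

    def test_valley_runs_from_large_d_small_p_to_small_d_large_p(
        self, grid_set, noise_free_records
    ):
        result = R2CrossSectionModel(noise_free_records, grid_set).fit()
        surface = result.chi2_surface
        diameters = [2.3, 1.6, 1.0]
        best_p_by_d = {}
        for label, d in zip(
            [TargetGeometry(d, round(d * 3.4 / 2.3, 6)).label for d in diameters],
            diameters,
        ):
            col = surface[label].to_numpy()
            best_p_by_d[d] = float(surface.index[int(np.nanargmin(col))])
        assert best_p_by_d[1.0] > best_p_by_d[1.6] > best_p_by_d[2.3]

    def test_k_grid_mode_close_to_closed_form(self, grid_set_true,
                                              noise_free_records):
        model = R2CrossSectionModel(noise_free_records, grid_set_true)
        closed = model.fit(k_mode="closed_form")
        scanned = model.fit(k_mode="grid", k_grid=(1.0, 200.0, 1.0))
        assert abs(closed.best_K - scanned.best_K) <= 1.0

    def test_functional_wrapper_matches_class(self, grid_set_true,
                                              noise_free_records):
        a = grid_fit(noise_free_records, grid_set_true)
        b = R2CrossSectionModel(noise_free_records, grid_set_true).fit()
        assert a.best_p == b.best_p and a.best_K == pytest.approx(b.best_K)

    def test_r2_model_beats_step_models_on_r2_data(self, grid_set_true,
                                                   noise_free_records):
        result = R2CrossSectionModel(noise_free_records, grid_set_true).fit()
        table = result.compare_fk_models().set_index("model")["r_squared"]
        r2_row = table[[i for i in table.index if i.startswith("R2")][0]]
        for k in range(2, 8):
            assert r2_row >= table[f"F{k}"]

    def test_unmatched_particles_excluded_with_reason(self, grid_set_true):
        records = generate_survival_dataset(
            SyntheticStudySpec(n_records=10, seed=3)
        )
        # drop every grid except protons: He/C/Ne records must be excluded
        geometry = next(iter(grid_set_true))
        only_h = {geometry: {"1H": grid_set_true[geometry]["1H"]}}
        model = R2CrossSectionModel(records, only_h)
        assert model.exclusions
        assert {e["reason"] for e in model.exclusions} == {"no_grid_for_particle"}
        result = model.fit()
        assert result.nobs + len(model.exclusions) == len(records)

    def test_all_records_excluded_is_an_error(self, grid_set_true):
        records = generate_survival_dataset(
            SyntheticStudySpec(n_records=4, seed=3, ions=("4He",))
        )
        geometry = next(iter(grid_set_true))
        only_h = {geometry: {"1H": grid_set_true[geometry]["1H"]}}
        with pytest.raises(ValueError, match="failed interpolation"):
            R2CrossSectionModel(records, only_h)

    def test_summary_and_json(self, grid_set_true, noise_free_records, tmp_path):
        result = R2CrossSectionModel(noise_free_records, grid_set_true).fit()
        text = result.summary()
        assert "best lesion probability p" in text and "0.35" in text
        payload = result.to_json(tmp_path / "fit.json")
        assert (tmp_path / "fit.json").exists()
        assert payload["params"]["p"] == pytest.approx(0.35, abs=0.011)
        assert len(payload["residuals"]) == result.nobs
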