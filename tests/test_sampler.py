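"""Latin hypercube stratification, unshared streams and AR(1) machinery."""

import numpy as np
import pytest

from mc2dose.bundle import Individual, ResidenceRecord
from mc2dose.registry import (
    Correlation,
    Dimensioning,
    DistributionSpec,
    Family,
    ParameterRegistry,
    ScopeLevel,
    SharingScope,
    UncertainParameter,
    UncertaintyComponent,
    build_default_registry,
    point_mass,
)
from mc2dose.sampler import (
    apply_autocorrelation,
    sample_empirical,
    sample_shared,
    sample_unshared,
    _draw,
    unshared_generator,
)


def one_param_registry(spec: DistributionSpec, n: int = 1) -> ParameterRegistry:
    return ParameterRegistry(
        parameters=[
            UncertainParameter(
                symbol="R_ratio",
                shared=UncertaintyComponent(
                    spec, SharingScope(ScopeLevel.VILLAGE), (("techa_settlements", n),)
                ),
            )
        ],
        dimensioning=Dimensioning(),
    )


class TestSharedLHS:
    def test_uniform_quartiles(self):
        """With n=4 strata, exactly one sample lands in each quartile."""
        reg = one_param_registry(DistributionSpec(Family.UNIFORM, (0.5, 1.5)))
        table = sample_shared(reg, 4, seed=0)
        vals = np.sort(table.factors["R_ratio"][0])
        edges = [0.5, 0.75, 1.0, 1.25, 1.5]
        for i, v in enumerate(vals):
            assert edges[i] <= v <= edges[i + 1]

    def test_stratification_every_scalar(self):
        """Each shared scalar occupies each equiprobable stratum exactly once."""
        reg = build_default_registry(
            Dimensioning(n_techa_settlements=3, n_eurt_villages=4, n_nuclides=2,
                         n_eurt_nuclides=2, n_organs=2, n_time_slices=5)
        )
        n = 64
        table = sample_shared(reg, n, seed=5)
        for p in reg:
            if p.shared is None:
                continue
            flat = table.factors[p.symbol].reshape(-1, n)
            u = p.shared.spec.cdf(flat)
            strata = np.floor(u * n).astype(int).clip(0, n - 1)
            for row in strata:
                assert sorted(row) == list(range(n)), p.symbol

    def test_determinism(self):
        reg = build_default_registry()
        t1 = sample_shared(reg, 1500, seed=42)
        t2 = sample_shared(reg, 1500, seed=42)
        assert all(
            np.array_equal(t1.factors[k], t2.factors[k]) for k in t1.factors
        )

    def test_lognormal_gsd_recovered(self):
        """Stratified sampling reproduces the target GSD closely."""
        reg = one_param_registry(DistributionSpec(Family.LOGNORMAL, (1.0, 2.0)))
        table = sample_shared(reg, 1500, seed=1)
        vals = table.factors["R_ratio"][0]
        gsd = np.exp(np.log(vals).std())
        assert abs(gsd - 2.0) < 0.1

    def test_strict_raises_below_parameter_count(self):
        reg = build_default_registry()
        with pytest.raises(ValueError):
            sample_shared(reg, 10, seed=0, strict=True)


class TestUnshared:
    def _individual(self, n_moves: int) -> Individual:
        hist = [
            ResidenceRecord("T000", 1950.0 + i, 1951.0 + i) for i in range(n_moves)
        ]
        return Individual(id="X", birth_year=1940, household_id="H", residence_history=hist)

    def test_move_indexed_factors_match_moves(self):
        reg = build_default_registry()
        fac = sample_unshared(reg, self._individual(3), 0, seed_base=9)
        assert fac["G_sr90"].shape == (3,)
        assert fac["R_inout"].shape == (3,)
        fac0 = sample_unshared(reg, self._individual(0), 0, seed_base=9)
        assert fac0["G_sr90"].shape == (0,)

    def test_move_limit_enforced(self):
        reg = build_default_registry()
        with pytest.raises(ValueError):
            sample_unshared(reg, self._individual(21), 0, seed_base=9)

    def test_point_mass_gives_ones(self):
        import dataclasses

        reg = build_default_registry()
        for i, p in enumerate(reg.parameters):
            if p.unshared is not None:
                reg.parameters[i] = dataclasses.replace(
                    p,
                    unshared=dataclasses.replace(p.unshared, spec=point_mass()),
                    nuclide_specific_unshared={},
                )
        fac = sample_unshared(reg, self._individual(2), 0, seed_base=9)
        for sym, arr in fac.items():
            assert np.all(arr == 1.0), sym

    def test_reproducible_and_independent(self):
        reg = build_default_registry()
        a = sample_unshared(reg, self._individual(2), 5, seed_base=9)
        b = sample_unshared(reg, self._individual(2), 5, seed_base=9)
        for sym in a:
            assert np.array_equal(a[sym], b[sym])
        c = sample_unshared(reg, self._individual(2), 6, seed_base=9)
        assert not np.array_equal(a["T1"], c["T1"])

    def test_t1_factor_gsd(self):
        """Large-sample GSD of the riverbank time-fraction multiplier."""
        spec = DistributionSpec(Family.LOGNORMAL, (1.0, 2.7))
        rng = unshared_generator(9, "X", 0, "T1")
        draws = _draw(spec, rng, 100_000)
        gsd = np.exp(np.log(draws).std())
        assert abs(gsd - 2.7) < 0.05


def test_shared_table_round_trip(tmp_path):
    reg = build_default_registry(
        Dimensioning(n_techa_settlements=2, n_eurt_villages=2, n_nuclides=2,
                     n_eurt_nuclides=2, n_organs=2, n_time_slices=3)
    )
    table = sample_shared(reg, 40, seed=3)
    table.save(tmp_path / "t", registry_hash="abc")
    back = type(table).load(tmp_path / "t")
    assert back.seed == table.seed
    assert back.n_realizations == table.n_realizations
    for sym in table.factors:
        np.testing.assert_array_equal(back.factors[sym], table.factors[sym])


def test_registry_dimension_mismatch_flagged():
    import dataclasses

    from mc2dose.registry import validate_registry

    reg = build_default_registry()
    p = reg.get("D_sr90")
    reg.parameters[[q.symbol for q in reg].index("D_sr90")] = dataclasses.replace(
        p, shared=dataclasses.replace(p.shared, index_dims=(("months", 12),))
    )
    report = validate_registry(reg)
    assert any("D_sr90" in v and "dimensioning declares 15" in v for v in report)


class TestAutocorrelation:
    def test_rho_zero_identity(self):
        x = np.random.default_rng(0).standard_normal((5, 11))
        assert np.array_equal(apply_autocorrelation(x, 0.0), x)

    def test_invalid_rho(self):
        x = np.zeros((2, 3))
        with pytest.raises(ValueError):
            apply_autocorrelation(x, 1.0)
        with pytest.raises(ValueError):
            apply_autocorrelation(x, -0.1)

    def test_lag1_correlation_closed_form(self):
        rng = np.random.default_rng(3)
        z = apply_autocorrelation(rng.standard_normal((100_000, 2)), 0.8)
        r = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
        assert abs(r - 0.8) < 0.01

    def test_high_rho_near_constant(self):
        rng = np.random.default_rng(4)
        z = apply_autocorrelation(rng.standard_normal((10_000, 11)), 0.99)
        for k in range(1, 11):
            r = np.corrcoef(z[:, k - 1], z[:, k])[0, 1]
            assert r >= 0.95

    def test_stationary_marginals(self):
        rng = np.random.default_rng(5)
        z = apply_autocorrelation(rng.standard_normal((200_000, 6)), 0.7)
        assert np.allclose(z.std(axis=0), 1.0, atol=0.01)
        assert np.allclose(z.mean(axis=0), 0.0, atol=0.01)


class TestEmpirical:
    GRID = DistributionSpec(
        Family.EMPIRICAL, probs=(0.0, 0.5, 1.0), values=(0.5, 1.0, 2.0)
    )

    def test_exact_grid_point(self):
        assert sample_empirical(self.GRID, 0.5) == pytest.approx(1.0)

    def test_endpoint_clamp(self):
        assert sample_empirical(self.GRID, 0.0) == pytest.approx(0.5)
        assert sample_empirical(self.GRID, 1.0) == pytest.approx(2.0)

    def test_linear_interpolation(self):
        assert sample_empirical(self.GRID, 0.75) == pytest.approx(1.5)

    def test_deviate_out_of_range(self):
        with pytest.raises(ValueError):
            sample_empirical(self.GRID, 1.2)
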