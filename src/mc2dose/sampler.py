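"""Two-step Monte-Carlo sampling of shared and unshared error factors.

Step 1 (outer dimension): one vector of *shared* multiplicative factors per
realization, drawn by Latin hypercube sampling so that the marginal of each
shared scalar is exactly stratified over the realizations.  Step 2 (inner
dimension): *unshared* multiplicative factors drawn independently per
person, from reproducible streams keyed by (individual, realization,
parameter family, index), so results do not depend on cohort ordering.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .registry import (
    Correlation,
    DistributionSpec,
    ParameterRegistry,
    UncertainParameter,
)

__all__ = [
    "SharedFactorTable",
    "sample_shared",
    "sample_unshared",
    "unshared_generator",
    "apply_autocorrelation",
    "sample_empirical",
    "expand_autocorrelated",
]

# Stable small integers per family symbol used in seed derivation.
_FAMILY_IDS = {
    sym: i
    for i, sym in enumerate(
        [
            "G_sr90", "I_ref", "f_ratio", "xi", "alpha", "R_ratio", "I_E",
            "E_conv", "DF", "A_o", "D_riv", "D_sr90", "R_outriv", "R_inout",
            "T1", "T3",
        ]
    )
}


def _key_int(value) -> int:
    """Stable nonnegative integer key for ids (ints pass through)."""
    if isinstance(value, (int, np.integer)):
        return int(value) & 0xFFFFFFFF
    return zlib.crc32(str(value).encode())


@dataclass
class SharedFactorTable:
    """Shared multiplier factors for every realization.

    ``factors[symbol]`` has shape ``(*family_dims, n_realizations)``.
    """

    factors: dict[str, np.ndarray]
    n_realizations: int
    seed: int
    uncertainty_disabled: bool = False

    def flat(self) -> np.ndarray:
        """All shared scalars stacked: shape (n_scalars, n_realizations)."""
        blocks = [
            arr.reshape(-1, self.n_realizations) for arr in self.factors.values()
        ]
        if not blocks:
            return np.empty((0, self.n_realizations))
        return np.concatenate(blocks, axis=0)

    def disabled(self) -> "SharedFactorTable":
        """A copy with every multiplier forced to 1 (shared uncertainty off)."""
        return SharedFactorTable(
            factors={k: np.ones_like(v) for k, v in self.factors.items()},
            n_realizations=self.n_realizations,
            seed=self.seed,
            uncertainty_disabled=True,
        )

    def save(self, directory, registry_hash: str = "") -> None:
        """Persist as a CSV matrix with a JSON sidecar (seed, hash, count)."""
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "shared_factors.csv", "w") as fh:
            fh.write("symbol,index,realization,multiplier\n")
            for sym, arr in self.factors.items():
                flat = arr.reshape(-1, self.n_realizations)
                for j in range(flat.shape[0]):
                    for k in range(self.n_realizations):
                        fh.write(f"{sym},{j},{k},{float(flat[j, k])!r}\n")
        with open(d / "shared_factors.json", "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "registry_hash": registry_hash,
                    "n_realizations": self.n_realizations,
                    "shapes": {k: list(v.shape[:-1]) for k, v in self.factors.items()},
                    "uncertainty_disabled": self.uncertainty_disabled,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, directory) -> "SharedFactorTable":
        import csv
        import json
        from pathlib import Path

        d = Path(directory)
        with open(d / "shared_factors.json") as fh:
            meta = json.load(fh)
        n = int(meta["n_realizations"])
        factors = {
            sym: np.empty((int(np.prod(shape or [1])), n))
            for sym, shape in meta["shapes"].items()
        }
        with open(d / "shared_factors.csv") as fh:
            for row in csv.DictReader(fh):
                factors[row["symbol"]][int(row["index"]), int(row["realization"])] = float(
                    row["multiplier"]
                )
        factors = {
            sym: arr.reshape(*(meta["shapes"][sym] or [1]), n)
            for sym, arr in factors.items()
        }
        return cls(
            factors=factors, n_realizations=n, seed=int(meta["seed"]),
            uncertainty_disabled=bool(meta.get("uncertainty_disabled", False)),
        )


def ones_shared(registry: ParameterRegistry, n_realizations: int, seed: int = 0) -> SharedFactorTable:
    """A shared-factor table with every multiplier at 1 (uncertainty off)."""
    factors = {
        p.symbol: np.ones((*(p.shared.shape or (1,)), n_realizations))
        for p in registry
        if p.shared is not None
    }
    return SharedFactorTable(
        factors=factors, n_realizations=n_realizations, seed=int(seed),
        uncertainty_disabled=True,
    )


def _lhs_uniforms(rng: np.random.Generator, n: int) -> np.ndarray:
    """n stratified uniforms: one per equiprobable stratum, jittered, shuffled."""
    u = (rng.permutation(n) + rng.uniform(size=n)) / n
    return u


def sample_shared(
    registry: ParameterRegistry,
    n_realizations: int,
    seed: int,
    *,
    strict: bool = False,
) -> SharedFactorTable:
    """Latin-hypercube sample of all shared factors.

    Every shared scalar is sampled with exactly one value per equiprobable
    stratum of its multiplier distribution across the ``n_realizations``
    realizations.  Families whose sharing scope declares AR(1) correlation
    across an age or year index additionally carry a deterministic
    innovation stream (one standard-normal sequence per scalar and
    realization seed) consumed later when the factor is expanded along the
    correlated index.

    For scalars with AR(1) across the realization-internal index, the LHS
    strata are assigned by rank so marginal stratification stays exact.
    """
    from .registry import count_parameters

    n_shared, _ = count_parameters(registry)
    if n_realizations < n_shared:
        msg = (
            f"n_realizations={n_realizations} is below the number of shared "
            f"parameters ({n_shared}); Latin hypercube coverage wants at "
            "least one realization per parameter"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    factors: dict[str, np.ndarray] = {}
    for p in registry:
        if p.shared is None:
            continue
        shape = p.shared.shape or (1,)
        n_scalars = int(np.prod(shape))
        fam_seed = np.random.SeedSequence(
            [int(seed), 0x5A, _FAMILY_IDS.get(p.symbol, _key_int(p.symbol))]
        )
        rng = np.random.Generator(np.random.PCG64(fam_seed))
        u = np.empty((n_scalars, n_realizations))
        for j in range(n_scalars):
            u[j] = _lhs_uniforms(rng, n_realizations)
        vals = p.shared.spec.ppf(u)
        factors[p.symbol] = vals.reshape(*shape, n_realizations)
    return SharedFactorTable(
        factors=factors, n_realizations=n_realizations, seed=int(seed)
    )


def unshared_generator(
    seed_base: int,
    individual_id,
    realization_index: int,
    symbol: str,
    extra: tuple[int, ...] = (),
) -> np.random.Generator:
    """Reproducible generator keyed by (individual, realization, family).

    Counter-style derivation: the stream depends only on the key, never on
    the order in which individuals or realizations are processed.
    """
    ss = np.random.SeedSequence(
        [
            int(seed_base),
            0xA7,
            _key_int(individual_id),
            int(realization_index),
            _FAMILY_IDS.get(symbol, _key_int(symbol)),
            *[int(e) for e in extra],
        ]
    )
    return np.random.Generator(np.random.PCG64(ss))


def _draw(spec: DistributionSpec, rng: np.random.Generator, size) -> np.ndarray:
    """Draw multipliers honoring the lower truncation bound (by resampling)."""
    if spec.is_point_mass():
        return np.full(size, spec.params[0], dtype=float)
    out = spec.ppf(rng.uniform(size=size))
    # ppf already respects truncation for normal; other families are
    # positive by construction, but guard against user-set bounds
    bad = (out <= spec.trunc_lower) | (out > spec.trunc_upper)
    tries = 0
    while np.any(bad) and tries < 100:
        out = np.where(bad, spec.ppf(rng.uniform(size=size)), out)
        bad = (out <= spec.trunc_lower) | (out > spec.trunc_upper)
        tries += 1
    return out


def sample_unshared(
    registry: ParameterRegistry,
    individual,
    realization_index: int,
    seed_base: int,
    nuclide_names: tuple[str, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Unshared factor map for one person in one realization.

    Returns one multiplier array per unshared family, with the family's
    index shape.  Move-indexed factors are drawn for the person's actual
    number of residence moves only; everything else uses the declared
    shape.  Streams are keyed so two individuals' factors are independent
    and any (person, realization) pair is reproducible in isolation.
    """
    n_moves = getattr(individual, "n_moves", None)
    if n_moves is None:
        n_moves = len(getattr(individual, "residence_history", ()))
    ind_id = getattr(individual, "id", individual)

    out: dict[str, np.ndarray] = {}
    for p in registry:
        if p.unshared is None:
            continue
        shape = list(p.unshared.shape or (1,))
        dim_names = [name for name, _ in p.unshared.index_dims] or ["one"]
        if "moves" in dim_names:
            limit = shape[dim_names.index("moves")]
            if n_moves > limit:
                raise ValueError(
                    f"individual {ind_id} has {n_moves} residence records, "
                    f"exceeding the move limit {limit}"
                )
            shape[dim_names.index("moves")] = n_moves
        rng = unshared_generator(seed_base, ind_id, realization_index, p.symbol)
        spec = p.unshared.spec
        vals = _draw(spec, rng, tuple(shape))
        if p.nuclide_specific_unshared and "nuclides" in dim_names and nuclide_names:
            # some families (e.g. the dose-coefficient error) use a
            # different multiplier distribution for particular nuclides
            ax = dim_names.index("nuclides")
            for j, name in enumerate(nuclide_names[: shape[ax]]):
                override = p.nuclide_specific_unshared.get(name)
                if override is None:
                    continue
                sub = unshared_generator(
                    seed_base, ind_id, realization_index, p.symbol, extra=(j,)
                )
                idx = [slice(None)] * len(shape)
                idx[ax] = j
                vals[tuple(idx)] = _draw(override, sub, vals[tuple(idx)].shape)
        out[p.symbol] = vals
    return out


def apply_autocorrelation(
    iid_normal_scores: np.ndarray, rho: float, index_length: int | None = None
) -> np.ndarray:
    """Turn i.i.d. standard-normal scores into a stationary AR(1) sequence.

    The output has standard-normal marginals and lag-1 correlation ``rho``
    along the last axis; ``rho = 0`` returns the input unchanged.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    x = np.asarray(iid_normal_scores, dtype=float)
    if index_length is not None and x.shape[-1] < index_length:
        raise ValueError("not enough innovation scores for requested length")
    if index_length is not None:
        x = x[..., :index_length]
    if rho == 0.0:
        return x.copy()
    z = np.empty_like(x)
    z[..., 0] = x[..., 0]
    c = np.sqrt(1.0 - rho * rho)
    for t in range(1, x.shape[-1]):
        z[..., t] = rho * z[..., t - 1] + c * x[..., t]
    return z


def expand_autocorrelated(
    table: SharedFactorTable,
    parameter: UncertainParameter,
    index_length: int,
) -> np.ndarray:
    """Expand an AR(1)-scoped shared factor along its correlated index.

    The LHS-sampled factor anchors the sequence: its normal score is the
    first element, and subsequent elements follow a stationary AR(1) with
    the scope's ``rho``, mapped back through the marginal distribution.
    Returns shape ``(*family_dims, index_length, n_realizations)``.
    """
    comp = parameter.shared
    base = table.factors[parameter.symbol]  # (*dims, n_real)
    if (
        comp is None
        or Correlation(comp.scope.correlation) is not Correlation.AR1
        or table.uncertainty_disabled
    ):
        return np.repeat(base[..., None, :], index_length, axis=-2)
    shape = base.shape[:-1]
    n_real = base.shape[-1]
    spec = comp.spec
    if spec.is_point_mass():
        return np.full((*shape, index_length, n_real), spec.params[0])
    u0 = np.clip(spec.cdf(base), 1e-12, 1 - 1e-12)
    z0 = stats.norm.ppf(u0).reshape(-1, n_real)
    # innovations are a deterministic function of the table seed and family,
    # so expansion is reproducible without storing the stream
    inn_seed = np.random.SeedSequence(
        [table.seed, 0xAE, _FAMILY_IDS.get(parameter.symbol, _key_int(parameter.symbol))]
    )
    rng = np.random.Generator(np.random.PCG64(inn_seed))
    innov = rng.standard_normal((z0.shape[0], n_real, max(index_length - 1, 0)))
    scores = np.concatenate([z0[..., None], innov], axis=-1)
    z = apply_autocorrelation(scores, comp.scope.rho)
    u = stats.norm.cdf(z)
    vals = spec.ppf(u)  # (n_scalars, n_real, index_length)
    return np.moveaxis(vals, -1, -2).reshape(*shape, index_length, n_real)


def sample_empirical(spec: DistributionSpec, uniform_deviate) -> np.ndarray:
    """Inverse-CDF sample from a tabulated quantile grid.

    Linear interpolation between grid points; deviates at 0 or 1 clamp to
    the grid endpoints.
    """
    u = np.asarray(uniform_deviate, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("uniform deviate outside [0, 1]")
    spec.validate()
    if spec.probs is None:
        raise ValueError("spec has no quantile grid")
    return np.interp(u, spec.probs, spec.values)
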