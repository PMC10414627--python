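"""Helpers for building small synthetic ensembles directly from arrays."""

import math

import numpy as np

from mc2dose.dose_engine import DoseRealizationEnsemble


def ensemble_from_finals(final_doses: np.ndarray) -> DoseRealizationEnsemble:
    """Wrap (n_individuals, n_realizations) final doses as a one-year ensemble."""
    n_ind, n_real = final_doses.shape
    doses = np.zeros((n_ind, 1, 1, 4, n_real))
    doses[:, 0, 0, 0, :] = final_doses
    return DoseRealizationEnsemble(
        doses=doses,
        individual_ids=[f"I{i}" for i in range(n_ind)],
        years=np.array([1950]),
        organs=("stomach",),
        seed=0,
    )


def lognormal_ensemble(
    n_ind: int, n_real: int, seed: int, gm: float = 0.1, gsd: float = 2.0
) -> DoseRealizationEnsemble:
    """Each person's realizations drawn lognormal around their own level."""
    rng = np.random.default_rng(seed)
    levels = gm * rng.lognormal(0.0, 0.5, size=(n_ind, 1))
    finals = levels * rng.lognormal(0.0, math.log(gsd), size=(n_ind, n_real))
    return ensemble_from_finals(finals)
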