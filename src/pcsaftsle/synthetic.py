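"""Synthetic DSC-like solubility datasets with known ground truth.

Real drug-polymer solubility datasets are sparse — typically 3-10
(temperature, weight-fraction) points per binary system measured by DSC
stepwise dissolution in the high-concentration region below the drug's
melting onset.  This module emulates such datasets from a known PC-SAFT
parameter set so that the fitting machinery can be exercised end to end
without any experimental download: the generating truth is returned
alongside the data, and the noise-free curve can always be recomputed
bit-identically from it.

The default conditions are 6 evenly spaced temperatures between 0.80 Tm
and 0.98 Tm and multiplicative Gaussian noise on w with a 3 % relative
standard deviation, mimicking typical stepwise-dissolution scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eos import DomainError
from .fitting import (
    DEFAULT_BOUNDS,
    Bounds,
    ParamVectorAH,
    SolubilityDataset,
    SystemTemplate,
    build_system,
)
from .sle import MeltingProperties, SolubilitySolverError, solve_solubility

__all__ = ["GeneratorSpec", "generate_dataset", "perturb_parameters"]


class GenerationError(RuntimeError):
    """The true model could not be solved at one of the grid temperatures."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to generate one synthetic solubility dataset."""

    params: ParamVectorAH
    props: MeltingProperties
    k_ij: float = 0.0
    template: SystemTemplate = field(default_factory=SystemTemplate)
    n_points: int = 6
    t_range: tuple[float, float] = (0.80, 0.98)  # fractions of Tm_onset
    noise_sd: float = 0.03  # relative s.d. of multiplicative Gaussian noise
    seed: int | None = 0
    system_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise DomainError("need at least one grid point")
        lo, hi = self.t_range
        if not 0.0 < lo <= hi < 1.0:
            raise DomainError("t_range must satisfy 0 < lo <= hi < 1 (fractions of Tm)")
        if self.noise_sd < 0:
            raise DomainError("noise s.d. must be non-negative")

    def temperatures(self) -> np.ndarray:
        lo, hi = self.t_range
        tm = self.props.Tm_onset
        return np.linspace(lo * tm, hi * tm, self.n_points)


def generate_dataset(spec: GeneratorSpec) -> tuple[SolubilityDataset, dict]:
    """Solve the true model on the T grid and add multiplicative noise.

    Returns the dataset plus a ground-truth sidecar holding the generating
    parameters, the noise-free weight fractions and the seed — enough to
    recompute the clean curve bit-identically.
    """
    system = build_system(spec.params, spec.template, k_ij=spec.k_ij)
    temps = spec.temperatures()
    w_true = np.empty(spec.n_points)
    x_prev: float | None = None
    for i, T in enumerate(temps):
        try:
            pt = solve_solubility(float(T), system, spec.props, x0=x_prev)
        except Exception as exc:  # noqa: BLE001 - re-raised with the grid T
            raise GenerationError(
                f"true model unsolvable at T={float(T):.3f} K: {exc}"
            ) from exc
        x_prev = pt.x_API
        w_true[i] = pt.w_API

    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(spec.n_points)
    w_noisy = np.clip(w_true * (1.0 + spec.noise_sd * z), 1e-6, 1.0 - 1e-6)

    dataset = SolubilityDataset(
        system=spec.system_id, T=tuple(temps), w=tuple(w_noisy)
    )
    truth = {
        "params": {k: getattr(spec.params, k) for k in "ABCDEFGH"},
        "k_ij": spec.k_ij,
        "T_K": [float(t) for t in temps],
        "w_true": [float(w) for w in w_true],
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "template": {
            "api_Mw": spec.template.api_Mw,
            "polymer_Mw": spec.template.polymer_Mw,
            "api_sites": [spec.template.api_n_donor, spec.template.api_n_acceptor],
            "polymer_sites": [
                spec.template.polymer_n_donor,
                spec.template.polymer_n_acceptor,
            ],
        },
        "melting": {
            "Tm_onset": spec.props.Tm_onset,
            "dfusH": spec.props.dfusH,
            "dfusCp_a": spec.props.dfusCp_a,
            "dfusCp_b": spec.props.dfusCp_b,
        },
    }
    return dataset, truth


def perturb_parameters(
    params: ParamVectorAH,
    relative_fraction: float,
    seed: int | None = None,
    bounds: Bounds = DEFAULT_BOUNDS,
) -> ParamVectorAH:
    """Multiply each parameter by ``(1 + fraction * u)``, u uniform on [-1, 1].

    The result is clamped into ``bounds``; ``fraction = 0`` is the identity.
    """
    if relative_fraction < 0:
        raise DomainError("perturbation fraction must be non-negative")
    if relative_fraction == 0.0:
        return params
    rng = np.random.default_rng(seed)
    u = rng.uniform(-1.0, 1.0, size=8)
    arr = params.as_array() * (1.0 + relative_fraction * u)
    return ParamVectorAH.from_array(bounds.clip(arr))
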