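"""Two-step regression of PC-SAFT parameters to drug-polymer solubility data.

The workflow fits the eight adjustable parameters A-H (five for the API:
m/Mw, sigma, u/kB, eps_assoc/kB, kappa_assoc; three for the polymer: m/Mw,
sigma, u/kB — the polymer association stays fixed at eps = 0, kappa = 0.02)
directly to experimental weight-fraction solubility points:

1. randomized screening — 20 uniform draws inside the parameter bounds, keep
   the lowest objective;
2. a short (5-iteration) Nelder-Mead refinement of the best screen;
3. an extended (50-iteration) Nelder-Mead refinement.

The objective is the root-mean-square relative deviation (RMSRD, in %)
between calculated and experimental weight fractions, plus a quadratic
penalty for bound violations; any state where the equation of state or the
solubility condition cannot be solved contributes a large finite penalty
instead of raising, which keeps the simplex moving.  ``k_ij`` is held at 0
throughout the two-step fit; a separate one-dimensional optimization tunes
``k_ij`` for fixed pure-component parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .eos import AssociationScheme, BinarySystem, Component, DomainError
from .sle import MeltingProperties, solve_solubility

__all__ = [
    "PARAM_NAMES",
    "ParamVectorAH",
    "Bounds",
    "DEFAULT_BOUNDS",
    "SystemTemplate",
    "SolubilityDataset",
    "FitResult",
    "build_system",
    "rmsrd",
    "evaluate_candidate",
    "random_screen",
    "refine",
    "two_step_fit",
    "fit_kij",
    "average_parameters",
]

PARAM_NAMES = ("A", "B", "C", "D", "E", "F", "G", "H")

#: fixed polymer association (weakly associating polymer convention)
POLYMER_EPS_ASSOC = 0.0
POLYMER_KAPPA_ASSOC = 0.02

#: objective value assigned when the model cannot be solved at a candidate
FAILURE_PENALTY = 1.0e6
#: scale of the quadratic out-of-bounds penalty (per unit squared normalized
#: distance outside the bounds)
BOUND_PENALTY_SCALE = 1.0e4


@dataclass(frozen=True)
class ParamVectorAH:
    """The eight adjustable parameters of one API-polymer fit.

    A: API m/Mw (mol/g), B: API sigma (A), C: API u/kB (K),
    D: API eps_assoc/kB (K), E: API kappa_assoc,
    F: polymer m/Mw (mol/g), G: polymer sigma (A), H: polymer u/kB (K).
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float
    G: float
    H: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES])

    @classmethod
    def from_array(cls, arr) -> "ParamVectorAH":
        vals = [float(v) for v in arr]
        if len(vals) != 8:
            raise DomainError("parameter vector must have exactly 8 entries")
        return cls(*vals)


@dataclass(frozen=True)
class Bounds:
    """Per-parameter (low, high) screening/penalty bounds for A-H."""

    low: tuple[float, ...]
    high: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.low) != 8 or len(self.high) != 8:
            raise DomainError("bounds must cover all 8 parameters")
        if any(l > h for l, h in zip(self.low, self.high)):
            raise DomainError("every lower bound must not exceed its upper bound")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.array(self.low), np.array(self.high)

    def clip(self, arr: np.ndarray) -> np.ndarray:
        lo, hi = self.arrays()
        return np.clip(arr, lo, hi)

    def contains(self, arr: np.ndarray) -> bool:
        lo, hi = self.arrays()
        return bool(np.all(arr >= lo) and np.all(arr <= hi))


#: default bounds spanning the ranges of published drug/polymer parameters
DEFAULT_BOUNDS = Bounds(
    low=(0.015, 2.5, 150.0, 0.0, 0.001, 0.030, 2.5, 180.0),
    high=(0.060, 4.5, 500.0, 2500.0, 0.10, 0.060, 3.2, 280.0),
)


@dataclass(frozen=True)
class SystemTemplate:
    """Fixed (non-fitted) description of an API-polymer pair.

    Molar masses and association-site counts are inputs, not fit parameters;
    the default API scheme is 4 sites (2 donors, 2 acceptors), the typical
    convention for small hydrogen-bonding drugs.
    """

    api_name: str = "API"
    api_Mw: float = 384.253
    api_n_donor: int = 2
    api_n_acceptor: int = 2
    polymer_name: str = "polymer"
    polymer_Mw: float = 2500.0
    polymer_n_donor: int = 22
    polymer_n_acceptor: int = 22


@dataclass(frozen=True)
class SolubilityDataset:
    """Ordered (T, w_exp) observations for one binary system."""

    system: str
    T: tuple[float, ...]  # K
    w: tuple[float, ...]  # weight fraction of API

    def __post_init__(self) -> None:
        if len(self.T) != len(self.w) or len(self.T) == 0:
            raise DomainError("dataset needs >= 1 (T, w) pair of equal length")
        if any(not 0.0 < wi < 1.0 for wi in self.w):
            raise DomainError("weight fractions must lie strictly in (0, 1)")
        if any(t <= 0 for t in self.T):
            raise DomainError("temperatures must be positive kelvin")
        object.__setattr__(self, "T", tuple(float(t) for t in self.T))
        object.__setattr__(self, "w", tuple(float(v) for v in self.w))

    @property
    def n(self) -> int:
        return len(self.T)


@dataclass
class FitResult:
    """Outcome of one optimization run."""

    params: ParamVectorAH
    k_ij: float
    rmsrd: float
    w_calc: tuple[float, ...]
    trace: tuple[tuple[str, int, float], ...]  # (stage, eval index, objective)
    seed: int | None
    converged: bool
    n_eval: int = 0
    bounds: Bounds = field(default_factory=lambda: DEFAULT_BOUNDS)
    #: final Nelder-Mead simplex in bound-normalized coordinates (refinements
    #: can be chained without rebuilding the simplex)
    final_simplex: np.ndarray | None = None


def build_system(
    params: ParamVectorAH, template: SystemTemplate, k_ij: float = 0.0
) -> BinarySystem:
    """Materialize a :class:`BinarySystem` from an A-H vector and a template."""
    api = Component(
        template.api_name,
        Mw=template.api_Mw,
        m_over_Mw=params.A,
        sigma=params.B,
        u_kB=params.C,
        assoc=AssociationScheme(
            template.api_n_donor, template.api_n_acceptor, params.D, params.E
        ),
    )
    polymer = Component(
        template.polymer_name,
        Mw=template.polymer_Mw,
        m_over_Mw=params.F,
        sigma=params.G,
        u_kB=params.H,
        assoc=AssociationScheme(
            template.polymer_n_donor,
            template.polymer_n_acceptor,
            POLYMER_EPS_ASSOC,
            POLYMER_KAPPA_ASSOC,
        ),
    )
    return BinarySystem(api, polymer, k_ij=k_ij)


def rmsrd(w_exp, w_calc) -> float:
    """Root-mean-square relative deviation in percent.

    ``sqrt( (1/N) sum_i ((w_exp_i - w_calc_i)/w_exp_i * 100)^2 )``
    """
    we = np.asarray(w_exp, dtype=float)
    wc = np.asarray(w_calc, dtype=float)
    if we.shape != wc.shape or we.ndim != 1 or we.size == 0:
        raise DomainError("w_exp and w_calc must be equal-length 1-d vectors")
    if np.any(we <= 0):
        raise DomainError("experimental weight fractions must be positive")
    rel = (we - wc) / we * 100.0
    return float(np.sqrt(np.mean(rel * rel)))


def _solve_w_calc(
    params: ParamVectorAH,
    k_ij: float,
    dataset: SolubilityDataset,
    props: MeltingProperties,
    template: SystemTemplate,
) -> np.ndarray:
    """Calculated weight fractions at the experimental temperatures.

    Raises on any solver failure; callers translate that into a penalty.
    """
    system = build_system(params, template, k_ij=k_ij)
    w = np.empty(dataset.n)
    x_prev: float | None = None
    for idx in np.argsort(dataset.T):
        pt = solve_solubility(dataset.T[idx], system, props, x0=x_prev)
        x_prev = pt.x_API
        w[idx] = pt.w_API
    return w


def _plain_objective(
    params: ParamVectorAH,
    k_ij: float,
    dataset: SolubilityDataset,
    props: MeltingProperties,
    template: SystemTemplate,
) -> float:
    """RMSRD alone; solver failure maps to the large finite penalty."""
    try:
        w_calc = _solve_w_calc(params, k_ij, dataset, props, template)
    except Exception:
        return FAILURE_PENALTY
    val = rmsrd(dataset.w, w_calc)
    return val if math.isfinite(val) else FAILURE_PENALTY


def evaluate_candidate(
    params: ParamVectorAH,
    k_ij: float,
    dataset: SolubilityDataset,
    props: MeltingProperties,
    template: SystemTemplate | None = None,
    bounds: Bounds = DEFAULT_BOUNDS,
) -> float:
    """Penalized objective for one candidate parameter set.

    RMSRD of the calculated vs experimental weight fractions, plus a
    quadratic penalty on the (bound-width normalized) distance outside the
    bounds; an unsolvable candidate yields a large finite value and never
    raises.
    """
    template = template or SystemTemplate()
    arr = params.as_array()
    lo, hi = bounds.arrays()
    width = np.where(hi > lo, hi - lo, 1.0)
    viol = np.maximum(lo - arr, 0.0) + np.maximum(arr - hi, 0.0)
    penalty = BOUND_PENALTY_SCALE * float(np.sum((viol / width) ** 2))
    return _plain_objective(params, k_ij, dataset, props, template) + penalty


def _random_screen_full(
    bounds: Bounds,
    dataset: SolubilityDataset,
    props: MeltingProperties,
    template: SystemTemplate | None,
    n_sets: int,
    seed: int | None,
    rng: np.random.Generator | None,
) -> tuple[list[ParamVectorAH], list[float]]:
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = bounds.arrays()
    cands: list[ParamVectorAH] = []
    scores: list[float] = []
    for _ in range(n_sets):
        cand = ParamVectorAH.from_array(rng.uniform(lo, hi))
        cands.append(cand)
        scores.append(evaluate_candidate(cand, 0.0, dataset, props, template, bounds))
    return cands, scores


def random_screen(
    bounds: Bounds,
    dataset: SolubilityDataset,
    props: MeltingProperties,
    template: SystemTemplate | None = None,
    n_sets: int = 20,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ParamVectorAH, list[float]]:
    """Uniformly sample ``n_sets`` candidates within bounds; keep the best.

    Ties are broken by draw order (first minimum wins).  A seeded generator
    makes the draw sequence reproducible.
    """
    cands, scores = _random_screen_full(
        bounds, dataset, props, template, n_sets, seed, rng
    )
    best = cands[int(np.argmin(scores))]
    return best, scores


#: initial-simplex edge length as a fraction of each bound width, used when
#: no simplex (e.g. from a screening stage) is supplied
DEFAULT_SIMPLEX_STEP = 0.3


def _norm(bounds: Bounds, arr: np.ndarray) -> np.ndarray:
    lo, hi = bounds.arrays()
    width = np.where(hi > lo, hi - lo, 1.0)
    return (arr - lo) / width


def _denorm(bounds: Bounds, z: np.ndarray) -> np.ndarray:
    lo, hi = bounds.arrays()
    width = np.where(hi > lo, hi - lo, 1.0)
    return lo + z * width


def _default_simplex(z0: np.ndarray, step: float = DEFAULT_SIMPLEX_STEP) -> np.ndarray:
    """Axis-aligned simplex around z0 in the unit box, stepping inward at edges."""
    sim = [z0]
    for i in range(z0.size):
        v = z0.copy()
        v[i] = v[i] + step if v[i] + step <= 1.0 else v[i] - step
        sim.append(v)
    return np.array(sim)


def refine(
    candidate: ParamVectorAH,
    dataset: SolubilityDataset,
    props: MeltingProperties,
    template: SystemTemplate | None = None,
    max_iter: int = 50,
    k_ij: float = 0.0,
    bounds: Bounds = DEFAULT_BOUNDS,
    seed: int | None = None,
    stage: str = "refine",
    initial_simplex: np.ndarray | None = None,
) -> FitResult:
    """Nelder-Mead refinement of a candidate, capped at ``max_iter`` iterations.

    The search runs in bound-normalized coordinates so that all eight
    parameters move on a comparable scale.  ``initial_simplex`` (normalized
    coordinates, shape (9, 8)) lets a caller seed the simplex — e.g. with
    ranked screening candidates, or with the final simplex of a previous
    stage.  The returned objective never exceeds the starting objective;
    ``max_iter = 0`` returns the candidate unchanged.
    """
    template = template or SystemTemplate()
    trace: list[tuple[str, int, float]] = []

    def objective(z: np.ndarray) -> float:
        val = evaluate_candidate(
            ParamVectorAH.from_array(_denorm(bounds, z)),
            k_ij, dataset, props, template, bounds,
        )
        trace.append((stage, len(trace), val))
        return val

    z0 = _norm(bounds, candidate.as_array())
    if max_iter <= 0:
        start = objective(z0)
        return FitResult(
            params=candidate,
            k_ij=k_ij,
            rmsrd=start,
            w_calc=_final_w(candidate, k_ij, dataset, props, template),
            trace=tuple(trace),
            seed=seed,
            converged=start < FAILURE_PENALTY,
            n_eval=len(trace),
            bounds=bounds,
            final_simplex=initial_simplex,
        )

    if initial_simplex is None:
        initial_simplex = _default_simplex(z0)
    res = minimize(
        objective,
        z0,
        method="Nelder-Mead",
        options={
            "maxiter": max_iter,
            "initial_simplex": np.asarray(initial_simplex, dtype=float),
            "xatol": 1e-12,
            "fatol": 1e-12,
        },
    )
    best = ParamVectorAH.from_array(_denorm(bounds, res.x))
    best_val = float(res.fun)
    # Nelder-Mead never loses its best vertex; guard against a start that was
    # better than every vertex of a supplied simplex
    start_val = evaluate_candidate(candidate, k_ij, dataset, props, template, bounds)
    if best_val > start_val:
        best, best_val = candidate, start_val
    return FitResult(
        params=best,
        k_ij=k_ij,
        rmsrd=best_val,
        w_calc=_final_w(best, k_ij, dataset, props, template),
        trace=tuple(trace),
        seed=seed,
        converged=best_val < FAILURE_PENALTY,
        n_eval=len(trace),
        bounds=bounds,
        final_simplex=np.array(res.final_simplex[0]),
    )


def _final_w(
    params: ParamVectorAH,
    k_ij: float,
    dataset: SolubilityDataset,
    props: MeltingProperties,
    template: SystemTemplate,
) -> tuple[float, ...]:
    try:
        return tuple(_solve_w_calc(params, k_ij, dataset, props, template))
    except Exception:
        return tuple(float("nan") for _ in range(dataset.n))


def two_step_fit(
    dataset: SolubilityDataset,
    bounds: Bounds = DEFAULT_BOUNDS,
    props: MeltingProperties | None = None,
    template: SystemTemplate | None = None,
    seed: int | None = None,
    n_sets: int = 20,
    iter_step1: int = 5,
    iter_step2: int = 50,
) -> FitResult:
    """Full pipeline: randomized screen, short refinement, extended refinement.

    ``k_ij = 0`` throughout.  The result is a pure function of
    ``(dataset, bounds, seed)`` for a fixed template and melting properties:
    repeated runs are bit-identical.
    """
    if props is None:
        raise DomainError("melting properties are required")
    template = template or SystemTemplate()
    cands, scores = _random_screen_full(
        bounds, dataset, props, template, n_sets, seed, None
    )
    trace = [("screen", i, s) for i, s in enumerate(scores)]
    order = np.argsort(scores, kind="stable")
    best = cands[int(order[0])]
    # seed the simplex with the nine best-ranked screening draws; with fewer
    # draws fall back to an axis-aligned simplex around the best one
    simplex = None
    if n_sets >= 9:
        simplex = np.array(
            [_norm(bounds, cands[int(i)].as_array()) for i in order[:9]]
        )
    step1 = refine(
        best, dataset, props, template, max_iter=iter_step1,
        bounds=bounds, seed=seed, stage="step1", initial_simplex=simplex,
    )
    trace.extend(step1.trace)
    # the extended stage continues from the contracted simplex of stage 1
    step2 = refine(
        step1.params, dataset, props, template, max_iter=iter_step2,
        bounds=bounds, seed=seed, stage="step2",
        initial_simplex=step1.final_simplex,
    )
    trace.extend(step2.trace)
    return replace(step2, trace=tuple(trace), seed=seed)


def fit_kij(
    params: ParamVectorAH,
    dataset: SolubilityDataset,
    props: MeltingProperties,
    template: SystemTemplate | None = None,
    k_range: tuple[float, float] = (-0.2, 0.2),
    n_grid: int = 41,
    seed: int | None = None,
) -> tuple[float, FitResult]:
    """One-dimensional RMSRD minimization over ``k_ij`` with frozen pure params.

    A 41-point grid pre-scan guards against local minima before a bounded
    Brent polish around the best grid point.  The returned RMSRD never
    exceeds the ``k_ij = 0`` value (the grid contains 0 whenever the range
    does).
    """
    template = template or SystemTemplate()
    lo, hi = k_range
    if not lo < hi:
        raise DomainError("k_ij range must be increasing")

    evals: list[tuple[float, float]] = []

    def objective(k: float) -> float:
        val = _plain_objective(params, float(k), dataset, props, template)
        evals.append((float(k), val))
        return val

    grid = np.linspace(lo, hi, n_grid)
    if lo < 0.0 < hi and not np.any(grid == 0.0):
        grid = np.sort(np.append(grid, 0.0))
    grid_vals = [objective(k) for k in grid]
    ib = int(np.argmin(grid_vals))
    blo = grid[max(ib - 1, 0)]
    bhi = grid[min(ib + 1, len(grid) - 1)]
    if blo < bhi:
        minimize_scalar(
            objective, bounds=(blo, bhi), method="bounded",
            options={"xatol": 1e-7},
        )
    k_best, f_best = min(evals, key=lambda t: t[1])
    result = FitResult(
        params=params,
        k_ij=k_best,
        rmsrd=f_best,
        w_calc=_final_w(params, k_best, dataset, props, template),
        trace=tuple(("kij", i, v) for i, (_, v) in enumerate(evals)),
        seed=seed,
        converged=f_best < FAILURE_PENALTY,
        n_eval=len(evals),
    )
    return k_best, result


def average_parameters(
    results: list[FitResult], subset: str = "polymer"
) -> dict[str, float]:
    """Arithmetic mean of fitted parameters across several systems.

    ``subset='polymer'`` averages F-H (m/Mw, sigma, u/kB) and reports the
    fixed association constants alongside; ``subset='api'`` averages A-E.
    """
    if not results:
        raise DomainError("cannot average an empty result list")
    if subset == "polymer":
        names = ("F", "G", "H")
    elif subset == "api":
        names = ("A", "B", "C", "D", "E")
    else:
        raise DomainError(f"unknown subset {subset!r}")
    out = {
        name: float(np.mean([getattr(r.params, name) for r in results]))
        for name in names
    }
    if subset == "polymer":
        out["eps_assoc_kB"] = POLYMER_EPS_ASSOC
        out["kappa_assoc"] = POLYMER_KAPPA_ASSOC
    return out
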