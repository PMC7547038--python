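"""Simulation-based model comparison on a coarse parameter grid.

For each parameter combination a model's *likelihood* is estimated as the
fraction of simulation iterations whose per-condition mean hits-minus-
false-alarms values fall within a root-mean-square-error window ``E`` of
the empirical condition means.  Averaging these likelihoods over the grid
(a uniform prior) gives a marginal likelihood per model; ratios of
marginals are Bayes factors, and ratios of per-grid maxima are maximum
likelihood ratios.  Posterior predictive checks re-simulate either at the
maximum-likelihood combination or at combinations sampled in proportion to
their likelihood (which, under the uniform prior, is the posterior).

The grid crosses the component-sample size g with index-yoked learning-rate
levels: level i fixes the (dual, single) pair used for L_train and, via a
second index, for L_test.  With g in {2,3,4,5} and three levels each for
training and test this yields the default 36 combinations.  Which member of
a pair applies in a given condition is decided by whether that condition
carries a dual task at training/test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .materials import ItemSet

__all__ = [
    "ParameterGrid",
    "ParameterCombo",
    "Condition",
    "StudySpec",
    "LikelihoodSurface",
    "ComparisonResult",
    "enumerate_grid",
    "rmse",
    "combo_likelihood",
    "build_surface",
    "marginalize_and_compare",
    "sample_posterior_combos",
    "posterior_predictive",
    "compile_experiment",
]

DEFAULT_G_VALUES = (2, 3, 4, 5)
DEFAULT_RATE_LEVELS = ((0.1, 0.8), (0.2, 0.9), (0.3, 1.0))

_EXPERIMENT_CODE = {"standard": 0, "transfer": 1}
_VARIANT_CODE = {v: i for i, v in enumerate(engine.VARIANTS)}


@dataclass(frozen=True)
class ParameterGrid:
    g_values: tuple[int, ...] = DEFAULT_G_VALUES
    rate_levels: tuple[tuple[float, float], ...] = DEFAULT_RATE_LEVELS  # (dual, single)

    def __post_init__(self) -> None:
        if not self.g_values or not self.rate_levels:
            raise ValueError("g_values and rate_levels must be non-empty")


@dataclass(frozen=True)
class ParameterCombo:
    index: int
    g: int
    train_level: tuple[float, float]  # (dual, single)
    test_level: tuple[float, float]

    def L_train(self, dual: bool) -> float:
        return self.train_level[0] if dual else self.train_level[1]

    def L_test(self, dual: bool) -> float:
        return self.test_level[0] if dual else self.test_level[1]


def enumerate_grid(grid: ParameterGrid) -> list[ParameterCombo]:
    """Cartesian product g x train-level x test-level (default 36 combos)."""
    combos = []
    for i, (g, tr, te) in enumerate(
        itertools.product(grid.g_values, grid.rate_levels, grid.rate_levels)
    ):
        combos.append(ParameterCombo(index=i, g=g, train_level=tr, test_level=te))
    return combos


@dataclass(frozen=True)
class Condition:
    """One experimental cell: dual-task placement plus its empirical anchors.

    ``empirical_diff`` is the observed mean hits-minus-false-alarms; leave
    it None for a condition that is simulated but not compared (the
    transfer experiments anchor only three of the four cells).
    """

    name: str
    dual_train: bool
    dual_test: bool
    endorsement_rate: float = 0.5
    empirical_diff: float | None = None


@dataclass(frozen=True)
class StudySpec:
    experiment: str  # standard | transfer
    conditions: tuple[Condition, ...]
    n_participants: int = 20
    n_iterations: int = 100
    error_window: float = 0.02

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENT_CODE:
            raise ValueError("experiment must be 'standard' or 'transfer'")
        if len(self.conditions) != 4:
            raise ValueError("a study simulates four dual-task conditions")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    @property
    def compared(self) -> tuple[int, ...]:
        """Indices of conditions carrying an empirical anchor."""
        idx = tuple(
            i for i, c in enumerate(self.conditions) if c.empirical_diff is not None
        )
        if not idx:
            raise ValueError("no condition has an empirical mean to compare against")
        return idx

    @property
    def scheme(self) -> str:
        return "bigram" if self.experiment == "standard" else "repetition"


def default_conditions(
    endorsement_rate: float = 0.5,
    empirical_diffs: dict[str, float | None] | None = None,
) -> tuple[Condition, ...]:
    """The four dual-task placements, in a fixed order."""
    placements = [
        ("single_single", False, False),
        ("dual_train", True, False),
        ("dual_test", False, True),
        ("dual_both", True, True),
    ]
    empirical_diffs = empirical_diffs or {}
    return tuple(
        Condition(
            name=name,
            dual_train=tr,
            dual_test=te,
            endorsement_rate=endorsement_rate,
            empirical_diff=empirical_diffs.get(name),
        )
        for name, tr, te in placements
    )


def compile_experiment(items: ItemSet, spec: StudySpec) -> engine.CompiledMaterials:
    """Compile an item set under the experiment's representational scheme."""
    return engine.compile_materials(list(items.train), list(items.test), spec.scheme)


def rmse(predicted, empirical) -> float:
    predicted = np.asarray(predicted, dtype=float)
    empirical = np.asarray(empirical, dtype=float)
    if predicted.shape != empirical.shape or predicted.size == 0:
        raise ValueError("predicted and empirical must have equal nonzero length")
    return float(np.sqrt(np.mean((predicted - empirical) ** 2)))


@dataclass(frozen=True)
class ComboResult:
    likelihood: float
    mean_diffs: np.ndarray  # across-iteration mean predicted diff per condition
    iteration_rmse: np.ndarray  # (n_iterations,)


def _condition_seed(
    seed: int, variant: str, experiment: str, combo_index: int, cond_index: int
) -> np.random.Generator:
    """Documented counter scheme: one child stream per condition run."""
    ss = np.random.SeedSequence(
        entropy=seed,
        spawn_key=(
            _VARIANT_CODE[variant],
            _EXPERIMENT_CODE[experiment],
            combo_index,
            cond_index,
        ),
    )
    return np.random.default_rng(ss)


def _simulate_condition_means(
    compiled, variant, combo, cond, spec, rng, n_iterations
) -> np.ndarray:
    """Per-iteration mean diff for one condition: shape (n_iterations,)."""
    out = engine.simulate_participants(
        compiled,
        variant,
        L_train=combo.L_train(cond.dual_train),
        L_test=combo.L_test(cond.dual_test),
        g=combo.g,
        rate=cond.endorsement_rate,
        n_participants=n_iterations * spec.n_participants,
        rng=rng,
    )
    return out["diff"].reshape(n_iterations, spec.n_participants).mean(axis=1)


def combo_likelihood(
    variant: str,
    combo: ParameterCombo,
    spec: StudySpec,
    compiled: engine.CompiledMaterials,
    seed: int,
    simulate=None,
) -> ComboResult:
    """Windowed-RMSE likelihood of one parameter combination.

    Each iteration simulates ``n_participants`` fresh participants per
    condition and records the per-condition mean diff; the iteration counts
    as reproducing the data if the RMSE of those means against the
    empirical means (over anchored conditions) does not exceed the window
    ``E``.  The likelihood is the fraction of reproducing iterations.

    ``simulate`` may override the per-condition simulation (signature
    ``(variant, combo, cond, spec, rng) -> per-iteration means``); used for
    plumbing checks.
    """
    compared = spec.compared
    empirical = np.array([spec.conditions[i].empirical_diff for i in compared])

    means = np.empty((spec.n_iterations, len(spec.conditions)))
    for j, cond in enumerate(spec.conditions):
        rng = _condition_seed(seed, variant, spec.experiment, combo.index, j)
        if simulate is not None:
            means[:, j] = simulate(variant, combo, cond, spec, rng)
        else:
            means[:, j] = _simulate_condition_means(
                compiled, variant, combo, cond, spec, rng, spec.n_iterations
            )
    deviations = means[:, list(compared)] - empirical
    iteration_rmse = np.sqrt(np.mean(deviations**2, axis=1))
    likelihood = float(np.mean(iteration_rmse <= spec.error_window))
    return ComboResult(
        likelihood=likelihood,
        mean_diffs=means.mean(axis=0),
        iteration_rmse=iteration_rmse,
    )


@dataclass(frozen=True)
class LikelihoodSurface:
    variant: str
    experiment: str
    combos: tuple[ParameterCombo, ...]
    likelihoods: np.ndarray  # (n_combos,)
    mean_diffs: np.ndarray  # (n_combos, n_conditions)
    seed: int

    def argmax_combo(self) -> ParameterCombo:
        """Maximum-likelihood combination; ties go to enumeration order."""
        return self.combos[int(np.argmax(self.likelihoods))]


def build_surface(
    variant: str,
    grid: ParameterGrid,
    spec: StudySpec,
    items: ItemSet,
    seed: int,
    progress=None,
) -> LikelihoodSurface:
    """Likelihood for every combination of the grid (exactly reproducible)."""
    compiled = compile_experiment(items, spec)
    combos = tuple(enumerate_grid(grid))
    likelihoods = np.empty(len(combos))
    mean_diffs = np.empty((len(combos), len(spec.conditions)))
    for i, combo in enumerate(combos):
        res = combo_likelihood(variant, combo, spec, compiled, seed)
        likelihoods[i] = res.likelihood
        mean_diffs[i] = res.mean_diffs
        if progress is not None:
            progress(variant, combo, res.likelihood)
    return LikelihoodSurface(
        variant=variant,
        experiment=spec.experiment,
        combos=combos,
        likelihoods=likelihoods,
        mean_diffs=mean_diffs,
        seed=seed,
    )


@dataclass(frozen=True)
class ComparisonResult:
    marginals: dict[str, float]
    max_likelihoods: dict[str, float]
    argmax_combos: dict[str, ParameterCombo]
    bayes_factors: dict[tuple[str, str], float | None]  # None = undefined
    max_likelihood_ratios: dict[tuple[str, str], float | None]
    undefined_pairs: tuple[tuple[str, str], ...]


def marginalize_and_compare(
    surfaces: dict[str, LikelihoodSurface],
) -> ComparisonResult:
    """Grid-averaged marginals, pairwise Bayes factors and max-likelihood ratios.

    Pairs whose denominator marginal (or maximum) is zero are flagged as
    undefined rather than computed.
    """
    variants = list(surfaces)
    ref = surfaces[variants[0]].combos
    for s in surfaces.values():
        if tuple(c.index for c in s.combos) != tuple(c.index for c in ref):
            raise ValueError("all surfaces must share one grid")
    marginals = {v: float(np.mean(surfaces[v].likelihoods)) for v in variants}
    maxima = {v: float(np.max(surfaces[v].likelihoods)) for v in variants}
    argmax = {v: surfaces[v].argmax_combo() for v in variants}
    bfs: dict[tuple[str, str], float | None] = {}
    mlrs: dict[tuple[str, str], float | None] = {}
    undefined = []
    for a, b in itertools.permutations(variants, 2):
        bfs[(a, b)] = marginals[a] / marginals[b] if marginals[b] > 0 else None
        mlrs[(a, b)] = maxima[a] / maxima[b] if maxima[b] > 0 else None
        if bfs[(a, b)] is None or mlrs[(a, b)] is None:
            undefined.append((a, b))
    return ComparisonResult(
        marginals=marginals,
        max_likelihoods=maxima,
        argmax_combos=argmax,
        bayes_factors=bfs,
        max_likelihood_ratios=mlrs,
        undefined_pairs=tuple(undefined),
    )


def sample_posterior_combos(
    surface: LikelihoodSurface, n_draws: int, rng: np.random.Generator
) -> list[ParameterCombo]:
    """Sample combinations with probability proportional to likelihood."""
    total = surface.likelihoods.sum()
    if total <= 0:
        raise ValueError("no posterior mass: all likelihoods are zero")
    p = surface.likelihoods / total
    idx = rng.choice(len(surface.combos), size=n_draws, p=p)
    return [surface.combos[i] for i in idx]


def posterior_predictive(
    variant: str,
    surface: LikelihoodSurface,
    spec: StudySpec,
    items: ItemSet,
    mode: str = "posterior",
    n_draws: int = 100,
    rng: np.random.Generator | None = None,
) -> dict:
    """Re-simulate condition means under the posterior or the ML estimate.

    ``posterior`` mode draws combinations in proportion to their likelihood
    (the posterior under the uniform prior) and simulates one iteration per
    draw; ``max_likelihood`` mode simulates ``n_draws`` iterations at the
    argmax combination.  Returns per-condition mean and sd across draws.
    """
    if mode not in ("posterior", "max_likelihood"):
        raise ValueError("mode must be 'posterior' or 'max_likelihood'")
    if rng is None:
        rng = np.random.default_rng(surface.seed)
    compiled = compile_experiment(items, spec)
    if mode == "posterior":
        combos = sample_posterior_combos(surface, n_draws, rng)
    else:
        combos = [surface.argmax_combo()] * n_draws

    draws = np.empty((n_draws, len(spec.conditions)))
    # group identical combos so each group simulates its draws in one batch
    by_combo: dict[int, list[int]] = {}
    for d, combo in enumerate(combos):
        by_combo.setdefault(combo.index, []).append(d)
    combo_of = {c.index: c for c in combos}
    for cindex, rows in by_combo.items():
        combo = combo_of[cindex]
        for j, cond in enumerate(spec.conditions):
            means = _simulate_condition_means(
                compiled, variant, combo, cond, spec, rng, len(rows)
            )
            draws[rows, j] = means
    return {
        "mode": mode,
        "conditions": [c.name for c in spec.conditions],
        "mean": draws.mean(axis=0),
        "sd": draws.std(axis=0, ddof=1) if n_draws > 1 else np.zeros(len(spec.conditions)),
        "n_draws": n_draws,
        "argmax_combo": surface.argmax_combo(),
    }
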