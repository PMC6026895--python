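"""Optimization and analysis procedures layered over the process simulator.

Four procedures are provided, all treating a process scenario as a black
box mapping operational parameter values to cost/productivity metrics:

* a two-round semi-exhaustive grid search (coarse full-factorial grid,
  then a refined grid spanning one third of each original range centred
  on the incumbent);
* a one-at-a-time local sensitivity analysis using elasticity-style
  sensitivities ``S = (dC/C) / (dV/V)`` at +/-1% perturbations;
* a full-factorial pairwise-interaction scan analysed by multiple linear
  regression on z-score-normalized predictors, with Bonferroni-adjusted
  p-values for the 10 pairwise products;
* a phage-dosing case study using the fixed-parameter delayed infection
  model, plus the production-time arithmetic built on steady-state
  productivity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dde import simulate_batch_dde
from .economics import CostModel, CycleEconomics, economics_summary
from .kinetics import DiscretizedInfection, KineticParameters
from .process import ProcessSpec, ReactorSpec, simulate_process

__all__ = [
    "SearchParameter",
    "SearchSpace",
    "GridResult",
    "SensitivityReport",
    "InteractionReport",
    "semi_exhaustive_search",
    "local_sensitivity",
    "interaction_scan",
    "dosing_simulation",
    "find_minimum_dose",
    "production_time",
    "OPERATIONAL_PARAMETERS",
    "apply_operational_parameters",
    "make_process_objective",
]

Objective = Callable[[Mapping[str, float]], float]


@dataclass(frozen=True)
class SearchParameter:
    """One axis of the search space.

    ``scale='log'`` places grid levels uniformly in log10; use it for
    quantities spanning decades (e.g. influent substrate concentration
    over 1-1000 ug/mL).
    """

    name: str
    lower: float
    upper: float
    scale: str = "linear"
    levels: int = 4

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be below upper bound")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"{self.name}: scale must be 'linear' or 'log'")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log scale requires positive bounds")
        if self.levels < 2:
            raise ValueError(f"{self.name}: need at least 2 levels")

    def grid(self, lower: float | None = None, upper: float | None = None) -> np.ndarray:
        lo = self.lower if lower is None else lower
        hi = self.upper if upper is None else upper
        if self.scale == "log":
            return np.geomspace(lo, hi, self.levels)
        return np.linspace(lo, hi, self.levels)

    def refined_bounds(self, center: float, shrink: float = 3.0) -> tuple[float, float]:
        """Bounds of a range 1/shrink of the original, centred on ``center``
        (in log space for log-scaled axes), clipped to the original box."""
        if self.scale == "log":
            span = (math.log10(self.upper) - math.log10(self.lower)) / shrink
            lo = 10 ** (math.log10(center) - span / 2)
            hi = 10 ** (math.log10(center) + span / 2)
        else:
            span = (self.upper - self.lower) / shrink
            lo, hi = center - span / 2, center + span / 2
        return max(lo, self.lower), min(hi, self.upper)


@dataclass(frozen=True)
class SearchSpace:
    parameters: tuple[SearchParameter, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.parameters]


@dataclass
class GridResult:
    """All evaluated grid points with the best (lowest-objective) incumbent."""

    evaluations: pd.DataFrame  # columns: round, <parameter names...>, objective
    incumbent: dict[str, float]
    incumbent_objective: float
    n_evaluations: int


def semi_exhaustive_search(
    space: SearchSpace, objective: Objective, rounds: int = 2
) -> GridResult:
    """Two-round full-factorial minimization of ``objective``.

    Round 1 evaluates the full ``levels**n_params`` grid over the stated
    bounds.  Each later round re-grids a range one third the size of the
    previous round's, centred per-parameter on the incumbent and clipped
    to the original bounds, and evaluates the full grid again.  Scenarios
    whose objective is non-finite (e.g. no phage harvested) rank as
    infinitely costly rather than aborting the search.
    """
    rows: list[dict] = []
    incumbent: dict[str, float] | None = None
    best = math.inf
    bounds = {p.name: (p.lower, p.upper) for p in space.parameters}

    for rnd in range(1, rounds + 1):
        axes = [p.grid(*bounds[p.name]) for p in space.parameters]
        for values in itertools.product(*axes):
            point = dict(zip(space.names, (float(v) for v in values)))
            try:
                score = float(objective(point))
            except (ArithmeticError, RuntimeError):
                score = math.inf
            if math.isnan(score):
                score = math.inf
            rows.append({"round": rnd, **point, "objective": score})
            if score < best:
                best, incumbent = score, point
        if incumbent is None:
            raise RuntimeError("every grid point was infeasible")
        shrink = 3.0 ** rnd
        bounds = {
            p.name: p.refined_bounds(incumbent[p.name], shrink=shrink)
            for p in space.parameters
        }

    frame = pd.DataFrame(rows)
    return GridResult(
        evaluations=frame,
        incumbent=dict(incumbent),
        incumbent_objective=best,
        n_evaluations=len(frame),
    )


@dataclass
class SensitivityReport:
    """Elasticity-style sensitivities per parameter and per metric.

    ``sensitivities[metric][parameter]`` is the average of the two
    one-sided estimates of ``(dC/C)/(dV/V)`` at the stated perturbation.
    ``n_evaluations`` counts the perturbed scenario evaluations (the
    mid-point evaluation is shared).
    """

    sensitivities: dict[str, dict[str, float]]
    delta: float
    baseline: dict[str, float]
    n_evaluations: int
    flags: list[str] = field(default_factory=list)


def local_sensitivity(
    point: Mapping[str, float],
    objective: Callable[[Mapping[str, float]], Mapping[str, float]],
    delta: float = 0.01,
) -> SensitivityReport:
    """One-at-a-time relative sensitivities around ``point``.

    ``objective`` returns one or more named metrics per scenario so a
    single simulation serves every metric (e.g. cost per phage and phage
    productivity).  Each parameter is perturbed to ``(1 +/- delta)`` of
    its value; with 5 parameters this schedules 10 perturbed evaluations.
    """
    base = dict(objective(point))
    flags: list[str] = []
    sens: dict[str, dict[str, float]] = {m: {} for m in base}
    n_eval = 0
    for name in point:
        plus = dict(point)
        minus = dict(point)
        plus[name] = point[name] * (1 + delta)
        minus[name] = point[name] * (1 - delta)
        up = objective(plus)
        down = objective(minus)
        n_eval += 2
        for metric, c0 in base.items():
            if not (math.isfinite(c0) and c0 != 0):
                sens[metric][name] = math.nan
                flag = f"{metric}: mid-point value {c0} — sensitivity undefined"
                if flag not in flags:
                    flags.append(flag)
                continue
            s_plus = ((up[metric] - c0) / c0) / delta
            s_minus = ((down[metric] - c0) / c0) / (-delta)
            sens[metric][name] = 0.5 * (s_plus + s_minus)
    return SensitivityReport(
        sensitivities=sens, delta=delta, baseline=base, n_evaluations=n_eval, flags=flags
    )


@dataclass
class InteractionReport:
    """Pairwise-interaction regression around an operating point.

    ``table`` holds one row per pairwise product term with its estimated
    coefficient (on z-score-normalized data), raw p-value and
    Bonferroni-adjusted p-value (raw times the number of pairwise terms,
    capped at 1).  ``main_effects`` holds the first-order coefficients.
    ``design`` describes the factorial actually evaluated.
    """

    table: pd.DataFrame
    main_effects: pd.DataFrame
    design: str
    n_evaluations: int

    def significant(self, alpha: float = 0.05, min_effect: float = 1e-8) -> pd.DataFrame:
        """Interaction terms with adjusted p below ``alpha``.

        Coefficients below ``min_effect`` on the normalized scale are
        excluded: when the linear model fits the response essentially
        exactly, residual variance collapses to rounding error and t-based
        p-values become meaningless for coefficients of machine-epsilon
        size.
        """
        table = self.table
        return table[(table["p_adjusted"] < alpha) & (table["coefficient"].abs() > min_effect)]


def interaction_scan(
    point: Mapping[str, float],
    objective: Objective,
    deltas: Sequence[float] = (-0.02, -0.01, 0.0, 0.01, 0.02),
) -> InteractionReport:
    """Full-factorial scan of relative perturbations with OLS analysis.

    Every combination of the relative perturbations in ``deltas`` applied
    to every parameter is evaluated (5 levels x 5 parameters = 3125 runs).
    Predictors and response are z-score-normalized; a linear model with
    all main effects and all pairwise products is fitted by least squares,
    and interaction p-values are Bonferroni-adjusted by the number of
    pairwise terms.
    """
    import statsmodels.api as sm

    names = list(point)
    rows = []
    for combo in itertools.product(deltas, repeat=len(names)):
        scenario = {n: point[n] * (1 + d) for n, d in zip(names, combo)}
        rows.append({**{n: scenario[n] for n in names}, "response": float(objective(scenario))})
    frame = pd.DataFrame(rows)
    if not np.isfinite(frame["response"]).all():
        raise RuntimeError("objective was non-finite inside the perturbation design")

    def zscore(col: pd.Series) -> pd.Series:
        sd = col.std(ddof=0)
        if sd == 0:
            return col * 0.0
        return (col - col.mean()) / sd

    Z = frame[names].apply(zscore)
    y = zscore(frame["response"])
    X = Z.copy()
    pairs = list(itertools.combinations(names, 2))
    for a, b in pairs:
        X[f"{a}:{b}"] = Z[a] * Z[b]
    X = sm.add_constant(X)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the error message
        bad = []
        cols = X.to_numpy()
        base_rank = 0
        kept: list[int] = []
        for j, name in enumerate(X.columns):
            r = np.linalg.matrix_rank(cols[:, kept + [j]])
            if r > base_rank:
                kept.append(j)
                base_rank = r
            else:
                bad.append(name)
        raise RuntimeError(f"design matrix is rank deficient; collinear terms: {bad}")

    fit = sm.OLS(y, X).fit()
    n_pairs = len(pairs)
    inter_rows = []
    for a, b in pairs:
        key = f"{a}:{b}"
        raw = float(fit.pvalues[key])
        inter_rows.append(
            {
                "term": key,
                "coefficient": float(fit.params[key]),
                "p_raw": raw,
                "p_adjusted": min(1.0, raw * n_pairs),
            }
        )
    main_rows = [
        {"term": n, "coefficient": float(fit.params[n]), "p_raw": float(fit.pvalues[n])}
        for n in names
    ]
    design = f"{len(deltas)}-level full factorial in {len(names)} parameters"
    return InteractionReport(
        table=pd.DataFrame(inter_rows),
        main_effects=pd.DataFrame(main_rows),
        design=design,
        n_evaluations=len(frame),
    )


def dosing_simulation(
    cell_conc: float,
    dose: float,
    ki: float = 1e-7,
    latent: float = 0.5,
    burst: float = 67.5,
    duration: float = 1.0,
    *,
    substrate: float = 0.0,
    params: KineticParameters | None = None,
) -> float:
    """Fraction of an initial bacterial population eradicated by a phage dose.

    Runs the fixed-parameter delayed batch model from ``XS(0) = cell_conc``
    and ``P(0) = dose`` (both per mL) and returns
    ``1 - XS(duration)/XS(0)``, counting infected cells as eradicated and
    clamping at zero when net growth outpaces infection.  The default burst
    size is the value of the reference burst-size curve at the growth rate
    whose latent period equals the 0.5 h used here; the default substrate
    of zero models the nutrient-exhausted environments (e.g. stagnant
    pipeline water) this kind of dosing targets, where the hosts are
    static targets rather than a growing culture.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if cell_conc <= 0:
        raise ValueError(f"cell concentration must be positive, got {cell_conc}")
    params = params or KineticParameters()
    traj = simulate_batch_dde(
        (substrate, cell_conc, 0.0, dose),
        ki,
        latent,
        burst,
        params,
        duration,
        t_eval=np.array([duration]),
    )
    return max(0.0, 1.0 - float(traj.XS[-1]) / cell_conc)


def find_minimum_dose(
    cell_conc: float,
    target_fraction: float = 0.9,
    doses: Sequence[float] | None = None,
    **kwargs,
) -> tuple[float | None, pd.DataFrame]:
    """Smallest dose on a grid reaching a target eradication fraction.

    The default grid is powers of ten from 1e4 to 1e10 particles/mL.
    Returns ``(dose, table)`` where ``dose`` is ``None`` if no grid point
    reaches the target; ``table`` lists every evaluated dose.
    """
    if doses is None:
        doses = [10.0 ** k for k in range(4, 11)]
    rows = [
        {"dose": d, "eradicated_fraction": dosing_simulation(cell_conc, d, **kwargs)}
        for d in doses
    ]
    table = pd.DataFrame(rows)
    hits = table[table["eradicated_fraction"] >= target_fraction]
    dose = float(hits["dose"].iloc[0]) if len(hits) else None
    return dose, table


#: The five operational parameters exposed to the search/sensitivity layer:
#: growth-vessel low level and influent substrate, infection-vessel mid
#: level and influent substrate, and the cycling time.
OPERATIONAL_PARAMETERS = ("LLS_SCF", "MLS_SCI", "cycle_time", "S_in_SCF", "S_in_SCI")


def apply_operational_parameters(spec: ProcessSpec, point: Mapping[str, float]) -> ProcessSpec:
    """Return a copy of ``spec`` with named operational parameters replaced."""
    unknown = set(point) - set(OPERATIONAL_PARAMETERS)
    if unknown:
        raise ValueError(
            f"unknown operational parameter(s) {sorted(unknown)}; "
            f"known: {list(OPERATIONAL_PARAMETERS)}"
        )
    scf = ReactorSpec(
        hls=spec.scf.hls,
        lls=float(point.get("LLS_SCF", spec.scf.lls)),
        influent_substrate=float(point.get("S_in_SCF", spec.scf.influent_substrate)),
    )
    sci = ReactorSpec(
        hls=spec.sci.hls,
        lls=spec.sci.lls,
        mls=float(point.get("MLS_SCI", spec.sci.mls)),
        influent_substrate=float(point.get("S_in_SCI", spec.sci.influent_substrate)),
    )
    return ProcessSpec(
        scf=scf,
        sci=sci,
        cycle_time=float(point.get("cycle_time", spec.cycle_time)),
        n_cycles=spec.n_cycles,
        initial_inoculum=spec.initial_inoculum,
        initial_phage=spec.initial_phage,
    )


def make_process_objective(
    spec: ProcessSpec,
    params: KineticParameters,
    disc: DiscretizedInfection,
    costs: CostModel,
    *,
    metrics: Sequence[str] = ("cost_per_phage", "phages_per_hour"),
    rtol: float = 1e-8,
    atol: float = 1e-2,
) -> Callable[[Mapping[str, float]], dict[str, float]]:
    """Build the scenario evaluator used by the experiment procedures.

    The returned callable maps a dict of operational parameter values to
    steady-state economics metrics by running a full multi-cycle process
    simulation.  Degenerate scenarios (no phage harvested) yield infinite
    cost per phage and zero productivity, so grid searches rank them as
    maximally unfavourable instead of failing.
    """
    import warnings

    def evaluate(point: Mapping[str, float]) -> dict[str, float]:
        scenario = apply_operational_parameters(spec, point)
        result = simulate_process(scenario, params, disc, rtol=rtol, atol=atol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eco = economics_summary(result.records, scenario, costs)
        return {m: getattr(eco, m) for m in metrics}

    return evaluate


def production_time(total_phages_needed: float, steady_state: CycleEconomics) -> float:
    """Hours of steady-state operation needed to produce a phage quantity."""
    if steady_state.phages_per_hour <= 0:
        raise ValueError("steady-state productivity is zero; production time undefined")
    return total_phages_needed / steady_state.phages_per_hour
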