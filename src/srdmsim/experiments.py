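"""The four analysis protocols and their statistical post-processing.

* ecological  - trajectory tables (abundance, mating rate, prevalence) over
  100 generations at chosen transmission rates and environment scenarios;
* sensitivity - Latin Hypercube sampling over (gamma, S, theta), 100
  replicates of 50 generations per scenario; a binomial GLM for extinction
  and an ordinary linear model for mean prevalence;
* mechanistic - per-generation growth rate ``log N_{t+1} - log N_t`` against
  abundance and operational sex ratio at gamma = 0.9, smoothed with a
  4th-degree polynomial least-squares fit;
* evolutionary - the summed generation-to-generation change in mean
  phenotype over 50 generations across scenario x gamma cells.

Replicate ``i`` (1-based) of any protocol uses seed ``base_seed + i``; the
parameter-sampling stage uses ``base_seed`` itself.  Seeds are recorded in
every output table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import qmc

from .core import EnvironmentConfig, SimulationParams
from .simulate import Trajectory, run_simulation

__all__ = [
    "TABLE1_RANGES",
    "FitSummary",
    "lhs_sample",
    "sensitivity_experiment",
    "mechanistic_experiment",
    "evolutionary_rate",
    "evolutionary_experiment",
    "ecological_experiment",
    "fit_polynomial_smoother",
    "polynomial_slope_band",
    "polynomial_average_slope",
    "fit_extinction_glm",
    "fit_prevalence_lm",
]

#: Sampling ranges for the sensitivity analysis (transmission rate, infected
#: survival benefit, male dispersal parameter).
TABLE1_RANGES: dict[str, tuple[float, float]] = {
    "gamma": (0.5, 1.0),
    "S": (0.0, 0.5),
    "theta": (0.05, 5.0),
}


@dataclass
class FitSummary:
    """Coefficients, standard errors and prediction curves for one model fit.

    ``prediction_curves`` maps each varying parameter to a DataFrame with the
    parameter swept over its range and the other parameters held at their
    range midpoints.  ``separation`` flags a Firth bias-reduced fallback fit
    after (quasi-)complete separation; ``degenerate`` flags a response with
    no variation, for which no model is fitted.
    """

    kind: str
    params: dict[str, float] = field(default_factory=dict)
    bse: dict[str, float] = field(default_factory=dict)
    prediction_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    separation: bool = False
    degenerate: bool = False
    note: str = ""


def lhs_sample(
    n: int,
    ranges: Mapping[str, tuple[float, float]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Latin Hypercube sample of ``n`` points over a named parameter box.

    Each varying dimension is split into ``n`` equal strata with exactly one
    point per stratum, paired across dimensions by independent random
    permutations (scipy's LatinHypercube engine).  A range with ``lo == hi``
    is treated as a held-fixed parameter and filled with the constant.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(ranges)
    lows = np.array([ranges[k][0] for k in names], dtype=float)
    highs = np.array([ranges[k][1] for k in names], dtype=float)
    if np.any(lows > highs):
        raise ValueError("each range must satisfy lo <= hi")
    varying = lows < highs
    out = np.tile(lows, (n, 1))
    d = int(varying.sum())
    if d:
        unit = qmc.LatinHypercube(d=d, seed=rng).random(n)
        out[:, varying] = qmc.scale(unit, lows[varying], highs[varying])
    return pd.DataFrame(out, columns=names)


def _midpoints(ranges: Mapping[str, tuple[float, float]]) -> dict[str, float]:
    return {k: 0.5 * (lo + hi) for k, (lo, hi) in ranges.items()}


def _prediction_curves(
    predict,
    ranges: Mapping[str, tuple[float, float]],
    n_points: int = 41,
) -> dict[str, pd.DataFrame]:
    """Sweep each varying parameter over its range, others at midpoints."""
    mids = _midpoints(ranges)
    curves: dict[str, pd.DataFrame] = {}
    for name, (lo, hi) in ranges.items():
        if lo == hi:
            continue
        grid = np.linspace(lo, hi, n_points)
        X = pd.DataFrame({k: np.full(n_points, mids[k]) for k in ranges})
        X[name] = grid
        curves[name] = pd.DataFrame({name: grid, "predicted": predict(X)})
    return curves


def _design_matrix(df: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    X = df[list(names)].astype(float)
    return sm.add_constant(X, has_constant="add")


def _firth_logit(
    y: np.ndarray, X: np.ndarray, max_iter: int = 500, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    Newton iterations on the penalised score ``X'(y - p + h (1/2 - p))``
    where ``h`` is the hat-matrix diagonal; estimates stay finite under
    complete separation.  Returns (coefficients, standard errors).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    info_inv = np.linalg.pinv(X.T @ X / 4.0)
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        w = p * (1.0 - p)
        XW = X * w[:, None]
        info_inv = np.linalg.pinv(X.T @ XW)
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        step = info_inv @ (X.T @ (y - p + h * (0.5 - p)))
        while np.max(np.abs(step)) > 5.0:  # damp early oversized steps
            step /= 2.0
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta, np.sqrt(np.diag(info_inv))


def fit_extinction_glm(
    rows: pd.DataFrame,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> FitSummary:
    """Binomial (logit) GLM of extinction on gamma, S and theta.

    Held-fixed parameters (constant columns) are dropped from the design.
    Complete or quasi-complete separation (diverging maximum-likelihood
    estimates) triggers a Firth bias-reduced refit, flagged via
    ``separation``; an all-extinct or never-extinct response is flagged
    ``degenerate`` and left unfitted.
    """
    ranges = dict(ranges or TABLE1_RANGES)
    y = rows["extinct"].astype(float)
    names = [k for k, (lo, hi) in ranges.items() if lo < hi]
    if y.nunique() < 2:
        return FitSummary(
            kind="binomial-glm",
            degenerate=True,
            note=f"extinction response constant at {y.iloc[0]:.0f}; no model fitted",
        )
    X = _design_matrix(rows, names)
    separation = False
    note = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            ok = np.all(np.isfinite(res.bse)) and np.all(np.abs(res.bse) < 1e3)
            params, bse_arr = np.asarray(res.params), np.asarray(res.bse)
        except Exception:
            ok = False
        if not ok:
            separation = True
            note = "separation detected; Firth bias-reduced fit"
            params, bse_arr = _firth_logit(y.to_numpy(), X.to_numpy())
    coef = dict(zip(X.columns, params.astype(float)))
    bse = dict(zip(X.columns, bse_arr.astype(float)))

    def predict(grid: pd.DataFrame) -> np.ndarray:
        Xg = sm.add_constant(grid[names].astype(float), has_constant="add")
        eta = Xg.to_numpy() @ np.array([coef[c] for c in Xg.columns])
        return 1.0 / (1.0 + np.exp(-eta))

    return FitSummary(
        kind="binomial-glm",
        params=coef,
        bse=bse,
        prediction_curves=_prediction_curves(predict, {k: ranges[k] for k in names}),
        separation=separation,
        note=note,
    )


def fit_prevalence_lm(
    rows: pd.DataFrame,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> FitSummary:
    """Ordinary least squares of replicate mean prevalence on gamma, S, theta."""
    ranges = dict(ranges or TABLE1_RANGES)
    names = [k for k, (lo, hi) in ranges.items() if lo < hi]
    y = rows["mean_prevalence"].astype(float)
    X = _design_matrix(rows, names)
    res = sm.OLS(y, X).fit()
    coef = dict(zip(X.columns, np.asarray(res.params, dtype=float)))

    def predict(grid: pd.DataFrame) -> np.ndarray:
        Xg = sm.add_constant(grid[names].astype(float), has_constant="add")
        return Xg.to_numpy() @ np.array([coef[c] for c in Xg.columns])

    return FitSummary(
        kind="ols",
        params=coef,
        bse=dict(zip(X.columns, np.asarray(res.bse, dtype=float))),
        prediction_curves=_prediction_curves(predict, {k: ranges[k] for k in names}),
    )


def sensitivity_experiment(
    scenario: str,
    mode: str = "cyclical",
    n_reps: int = 100,
    n_generations: int = 50,
    base_seed: int = 0,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    params: Optional[SimulationParams] = None,
    fit: bool = True,
) -> tuple[pd.DataFrame, FitSummary, FitSummary]:
    """LHS sensitivity protocol for one environment scenario.

    One Latin Hypercube draw of (gamma, S, theta) per replicate; each
    replicate runs up to ``n_generations`` and contributes whether it went
    extinct and its mean prevalence over the generations it realised.
    Returns the per-replicate table plus the extinction GLM and prevalence
    LM summaries (empty summaries when ``fit=False``).

    Pass a scalar range, e.g. ``ranges={"gamma": (0.0, 0.0), ...}``, to hold
    a parameter fixed (used for the uninfected control).
    """
    ranges = dict(ranges or TABLE1_RANGES)
    base = params or SimulationParams()
    base = replace(base, n_generations=n_generations)
    env = EnvironmentConfig.from_scenario(scenario, mode=mode)
    samples = lhs_sample(n_reps, ranges, np.random.default_rng(base_seed))

    rows = []
    for i in range(n_reps):
        seed = base_seed + 1 + i
        p = replace(
            base,
            gamma=float(samples.at[i, "gamma"]),
            S=float(samples.at[i, "S"]),
            theta=float(samples.at[i, "theta"]),
        )
        traj = run_simulation(p, env, np.random.default_rng(seed))
        prev = traj.prevalence
        rows.append(
            {
                "replicate": i + 1,
                "seed": seed,
                "scenario": scenario,
                "mode": mode,
                "gamma": p.gamma,
                "S": p.S,
                "theta": p.theta,
                "extinct": bool(traj.extinct),
                "extinction_generation": traj.extinction_generation,
                "n_generations_realised": len(traj),
                "mean_prevalence": float(prev.mean()) if prev.size else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    if not fit:
        empty = FitSummary(kind="none", note="fitting skipped")
        return df, empty, empty
    return df, fit_extinction_glm(df, ranges), fit_prevalence_lm(df, ranges)


def fit_polynomial_smoother(x: np.ndarray, y: np.ndarray, degree: int = 4):
    """Least-squares polynomial smoother (global 4th-degree curve by default).

    Returns a :class:`numpy.polynomial.Polynomial` fitted on a scaled domain
    for numerical stability; use ``poly(x)`` to predict and
    ``poly.deriv()(x)`` for the local slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size <= degree:
        raise ValueError(f"need more than {degree} points to fit degree {degree}")
    return np.polynomial.Polynomial.fit(x, y, degree)


def polynomial_slope_band(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    degree: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Local slope of the polynomial smoother with its standard error.

    Fits the degree-``degree`` least-squares polynomial of ``y`` on ``x``
    (on a standardised abscissa for conditioning) and returns the fitted
    derivative and its pointwise standard error over ``grid`` via the OLS
    coefficient covariance.  Used to ask whether an apparent slope region is
    distinguishable from smoother noise (e.g. the Allee-effect check: is any
    low-abundance slope significantly positive?).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    mu, sd = x.mean(), x.std()
    if sd == 0:
        raise ValueError("x has no variation")
    z = (x - mu) / sd
    V = np.vander(z, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    resid = y - V @ coef
    dof = y.size - (degree + 1)
    if dof < 1:
        raise ValueError("not enough points for a slope standard error")
    cov = (resid @ resid / dof) * np.linalg.inv(V.T @ V)
    zg = (grid - mu) / sd
    G = np.zeros((grid.size, degree + 1))
    for k in range(1, degree + 1):
        G[:, k] = k * zg ** (k - 1) / sd
    slope = G @ coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", G, cov, G))
    return slope, se


def polynomial_average_slope(
    x: np.ndarray,
    y: np.ndarray,
    a: float,
    b: float,
    degree: int = 4,
) -> tuple[float, float]:
    """Average slope of the polynomial smoother over ``[a, b]`` with its SE.

    The mean derivative of the fitted curve over the window,
    ``(f(b) - f(a)) / (b - a)``, which is a linear functional of the OLS
    coefficients, so its standard error follows from the coefficient
    covariance.  This is the trend statistic for questions like the Allee
    check — is growth rising, on average, across the low-abundance range? —
    where local wiggles of a global polynomial are smoother noise rather
    than signal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not b > a:
        raise ValueError("window must satisfy b > a")
    mu, sd = x.mean(), x.std()
    if sd == 0:
        raise ValueError("x has no variation")
    z = (x - mu) / sd
    V = np.vander(z, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    resid = y - V @ coef
    dof = y.size - (degree + 1)
    if dof < 1:
        raise ValueError("not enough points for a slope standard error")
    cov = (resid @ resid / dof) * np.linalg.inv(V.T @ V)
    za, zb = (a - mu) / sd, (b - mu) / sd
    powers = np.arange(degree + 1)
    g = (zb**powers - za**powers) / (b - a)
    return float(g @ coef), float(np.sqrt(g @ cov @ g))


def mechanistic_experiment(
    scenario: str,
    mode: str = "cyclical",
    n_reps: int = 100,
    n_generations: int = 100,
    gamma: float = 0.9,
    base_seed: int = 0,
    params: Optional[SimulationParams] = None,
) -> tuple[pd.DataFrame, dict, int]:
    """Growth-rate mechanism protocol at high transmission (gamma = 0.9).

    Pools consecutive-generation pairs across replicates and fits 4th-degree
    polynomial smoothers of growth rate ``log N_{t+1} - log N_t`` against
    ``log N_t`` and against the operational sex ratio (females per male) at
    emergence.  Pairs adjacent to an extinction (next-generation N of zero)
    are excluded from the fits; the number excluded is returned.
    """
    base = params or SimulationParams()
    base = replace(base, gamma=gamma, n_generations=n_generations)
    env = EnvironmentConfig.from_scenario(scenario, mode=mode)

    rows = []
    n_excluded = 0
    for i in range(n_reps):
        seed = base_seed + 1 + i
        traj = run_simulation(base, env, np.random.default_rng(seed))
        N = traj.n_adults
        osr = traj.osr
        if traj.extinct:
            n_excluded += 1  # the pair leading into N = 0 cannot be logged
        for t in range(len(N) - 1):
            rows.append(
                {
                    "replicate": i + 1,
                    "seed": seed,
                    "scenario": scenario,
                    "generation": t,
                    "N": N[t],
                    "log_N": np.log(N[t]),
                    "osr": osr[t],
                    "growth": np.log(N[t + 1]) - np.log(N[t]),
                }
            )
    df = pd.DataFrame(rows)
    fits = {}
    if len(df) > 4:
        fits["log_N"] = fit_polynomial_smoother(df["log_N"], df["growth"])
        fits["osr"] = fit_polynomial_smoother(df["osr"], df["growth"])
    return df, fits, n_excluded


def evolutionary_rate(trajectory: Trajectory | Sequence[float]) -> float:
    """Total generation-to-generation change in mean phenotype.

    ``sum_i |Pbar_i - Pbar_{i+1}|`` over the recorded generations; zero iff
    the mean phenotype never moves.  Accepts a Trajectory or a bare sequence
    of per-generation means; fewer than two generations is undefined.
    """
    pbar = (
        trajectory.mean_phenotype
        if isinstance(trajectory, Trajectory)
        else np.asarray(trajectory, dtype=float)
    )
    if pbar.size < 2:
        raise ValueError("evolutionary rate needs at least two generations")
    return float(np.abs(np.diff(pbar)).sum())


def evolutionary_experiment(
    scenarios: Sequence[str] = ("constant", "moderate", "high"),
    gammas: Sequence[float] = (0.2, 0.5, 0.8),
    mode: str = "cyclical",
    n_reps: int = 100,
    n_generations: int = 50,
    base_seed: int = 0,
    params: Optional[SimulationParams] = None,
) -> pd.DataFrame:
    """Mean +/- sd of the evolutionary rate per (scenario, gamma) cell.

    Replicates that go extinct before completing the run are excluded from
    the cell mean and counted in ``n_excluded`` rather than silently
    averaged; a cell with no usable replicate reports NaN.
    """
    base = params or SimulationParams()
    base = replace(base, n_generations=n_generations)
    out = []
    cell = 0
    for scenario in scenarios:
        env = EnvironmentConfig.from_scenario(scenario, mode=mode)
        for gamma in gammas:
            cell_seed = base_seed + 100_000 * cell
            rates = []
            n_excluded = 0
            for i in range(n_reps):
                p = replace(base, gamma=float(gamma))
                traj = run_simulation(p, env, np.random.default_rng(cell_seed + 1 + i))
                if traj.extinct or len(traj) < 2:
                    n_excluded += 1
                    continue
                rates.append(evolutionary_rate(traj))
            rates_arr = np.asarray(rates, dtype=float)
            out.append(
                {
                    "scenario": scenario,
                    "gamma": float(gamma),
                    "mean_rate": float(rates_arr.mean()) if rates_arr.size else float("nan"),
                    "sd_rate": float(rates_arr.std(ddof=1)) if rates_arr.size > 1 else float("nan"),
                    "n_used": int(rates_arr.size),
                    "n_excluded": n_excluded,
                    "base_seed": cell_seed,
                }
            )
            cell += 1
    return pd.DataFrame(out)


def ecological_experiment(
    gammas: Sequence[float] = (0.0, 0.5, 0.9),
    scenarios: Sequence[str] = ("constant", "moderate", "high"),
    mode: str = "cyclical",
    n_generations: int = 100,
    n_reps: int = 20,
    base_seed: int = 0,
    params: Optional[SimulationParams] = None,
) -> pd.DataFrame:
    """Tidy per-generation trajectories for graphical ecological checks.

    One row per (scenario, gamma, replicate, generation) with abundance,
    mating rate (matings per female per season), prevalence and mean
    phenotype; no statistical fitting is applied.
    """
    base = params or SimulationParams()
    base = replace(base, n_generations=n_generations)
    frames = []
    cell = 0
    for scenario in scenarios:
        env = EnvironmentConfig.from_scenario(scenario, mode=mode)
        for gamma in gammas:
            cell_seed = base_seed + 100_000 * cell
            for i in range(n_reps):
                seed = cell_seed + 1 + i
                p = replace(base, gamma=float(gamma))
                traj = run_simulation(p, env, np.random.default_rng(seed))
                df = traj.to_dataframe()
                df.insert(0, "scenario", scenario)
                df.insert(1, "gamma", float(gamma))
                df.insert(2, "replicate", i + 1)
                df.insert(3, "seed", seed)
                df["extinct"] = traj.extinct
                frames.append(df)
            cell += 1
    return pd.concat(frames, ignore_index=True)
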