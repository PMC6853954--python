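"""Design-build-test-learn campaign orchestration and simulation benchmarks.

A campaign alternates acquisition (propose a batch of designs), evaluation
(assay them, in silico against a synthetic landscape or in the lab via
ingested result files) and learning (refit the GP surrogate on all
replicate-mean observations).  The canonical lycopene campaign runs 3 rounds
of batch 46 with the mid-ladder control ``(12,12,12)`` re-built every round:
46 + 45 + 45 = 136 distinct designs, under 1% of the 13,824-point grid.

The module also houses the desk-scale benchmark harnesses: the fully
sequential search used to measure evaluations-to-maximum over random
Gaussian-mixture landscapes at 0/10/20% assay error, the batch-size study,
and the random-screening / resampled-maximum baselines a library screen
would give.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .gridspace import DesignPoint, DesignSpace, ValidationError, make_design_space
from .landscapes import (
    GMMGeneratorParams,
    Landscape,
    NoiseModel,
    Observation,
    evaluate_point,
    sample_gmm_landscape,
    success_checks,
)
from .gp import (
    FitConfig,
    GPModel,
    _solve_model,
    fit_gp,
    fit_gp_arrays,
    observations_to_arrays,
    posterior,
)
from .acquisition import (
    AcquisitionConfig,
    BatchProposal,
    expected_improvement,
    initial_design,
    select_batch,
)

__all__ = [
    "CampaignConfig",
    "CampaignState",
    "BenchmarkTable",
    "SearchResult",
    "MissingResultsError",
    "run_campaign",
    "run_sequential_max_search",
    "benchmark_error_robustness",
    "batch_size_study",
    "random_screen",
    "resampled_max_stats",
]


class MissingResultsError(RuntimeError):
    """Lab-mode ingestion is missing assay results for proposed designs."""

    def __init__(self, missing: Sequence[DesignPoint]):
        self.missing = list(missing)
        super().__init__(
            "missing assay results for proposed designs: "
            + ", ".join(str(tuple(p.coords)) for p in self.missing)
        )


@dataclass(frozen=True)
class CampaignConfig:
    """Settings of one optimization campaign.

    Defaults mirror the lycopene experiment: 3 rounds of batch 46 with 4
    biological replicates and the ``(12,12,12)`` control in every round.
    """

    rounds: int = 3
    batch_size: int = 46
    replicates: int = 4
    control_point: DesignPoint | None = DesignPoint((12, 12, 12))
    max_evaluations: int = 400
    noise: NoiseModel = NoiseModel(0.0)
    seed: int = 0
    mode: str = "simulate"
    n_fantasies: int = 10
    fit_restarts: int = 10

    def __post_init__(self):
        if self.rounds < 1 or self.batch_size < 1 or self.replicates < 1:
            raise ValidationError("rounds, batch_size and replicates must be >= 1")
        if self.max_evaluations < self.batch_size:
            raise ValidationError("max_evaluations must be >= batch_size")
        if self.mode not in ("simulate", "lab"):
            raise ValidationError(f"unknown mode {self.mode!r}")


@dataclass
class CampaignState:
    """Everything accumulated over a campaign; JSON-serializable and resumable."""

    space: DesignSpace
    round_index: int = 0
    observations: list[Observation] = field(default_factory=list)
    evaluated: list[DesignPoint] = field(default_factory=list)  # order preserved
    best_trajectory: list[dict] = field(default_factory=list)
    model_snapshots: list[dict] = field(default_factory=list)
    pending: list[DesignPoint] = field(default_factory=list)
    rng_descriptor: str = ""

    def evaluated_set(self) -> set[DesignPoint]:
        return set(self.evaluated)

    def best_observation(self) -> Observation | None:
        if not self.observations:
            return None
        return max(self.observations, key=lambda o: o.mean_value)

    def record_round(self, new_obs: Sequence[Observation]) -> None:
        for obs in new_obs:
            self.observations.append(obs)
            if obs.point not in self.evaluated_set():
                self.evaluated.append(obs.point)
        best = self.best_observation()
        entry = {
            "round": self.round_index,
            "best_point": list(best.point.coords),
            "best_mean": best.mean_value,
        }
        if self.best_trajectory and entry["best_mean"] < self.best_trajectory[-1]["best_mean"]:
            # cumulative best can never decrease; guard against bookkeeping bugs
            raise RuntimeError("best-so-far trajectory decreased")
        self.best_trajectory.append(entry)
        self.round_index += 1
        self.pending = []

    def to_json(self) -> str:
        return json.dumps({
            "space": {
                "n_factors": self.space.n_factors,
                "levels_per_factor": list(self.space.levels_per_factor),
                "factor_names": list(self.space.factor_names),
            },
            "round_index": self.round_index,
            "observations": [
                {"point": list(o.point.coords),
                 "replicates": list(o.replicate_values),
                 "mean": o.mean_value, "round": o.round_index}
                for o in self.observations
            ],
            "evaluated": [list(p.coords) for p in self.evaluated],
            "best_trajectory": self.best_trajectory,
            "model_snapshots": self.model_snapshots,
            "pending": [list(p.coords) for p in self.pending],
            "rng_descriptor": self.rng_descriptor,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CampaignState":
        d = json.loads(text)
        space = make_design_space(
            d["space"]["n_factors"], d["space"]["levels_per_factor"],
            d["space"].get("factor_names"),
        )
        state = cls(space=space, round_index=d["round_index"],
                    best_trajectory=d["best_trajectory"],
                    model_snapshots=d.get("model_snapshots", []),
                    rng_descriptor=d.get("rng_descriptor", ""))
        state.observations = [
            Observation(point=DesignPoint(o["point"]),
                        replicate_values=tuple(o["replicates"]),
                        mean_value=o["mean"], round_index=o["round"])
            for o in d["observations"]
        ]
        state.evaluated = [DesignPoint(p) for p in d["evaluated"]]
        state.pending = [DesignPoint(p) for p in d.get("pending", [])]
        return state

    def observations_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.observations:
            row = {f"level_{name}": c
                   for name, c in zip(self.space.factor_names, o.point.coords)}
            row.update({"mean": o.mean_value, "round": o.round_index,
                        "replicates": len(o.replicate_values)})
            for i, v in enumerate(o.replicate_values, start=1):
                row[f"rep{i}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Round-wise proposal / ingestion (shared by simulate and lab modes)
# ---------------------------------------------------------------------------

def propose_round(state: CampaignState, config: CampaignConfig,
                  fit_config: FitConfig | None = None) -> BatchProposal:
    """Propose the next batch: uniform design in round 1, model-driven after.

    The proposal is stored on the state as ``pending``; lab-mode ingestion
    checks results against it.
    """
    space = state.space
    round_seed_root = np.random.SeedSequence(config.seed, spawn_key=(state.round_index,))
    if state.round_index == 0:
        n_model = config.batch_size - (1 if config.control_point else 0)
        points = initial_design(space, n_model, seed=round_seed_root)
        if config.control_point and config.control_point not in points:
            points.append(config.control_point)
        elif config.control_point:
            # control collided with a designed point; add one more random point
            points = initial_design(space, n_model + 1, seed=round_seed_root)
            if config.control_point not in points:
                points = points[:n_model] + [config.control_point]
        proposal = BatchProposal(points=tuple(points),
                                 ei_at_selection=(math.nan,) * len(points),
                                 contains_control=config.control_point is not None)
    else:
        fc = fit_config or FitConfig(restarts=config.fit_restarts, seed=config.seed)
        model = fit_gp(state.observations, space, fc)
        state.model_snapshots.append({
            "round": state.round_index,
            "hyperparams": json.loads(model.to_json())["hyperparams"],
            "n_train": model.n_train(),
        })
        acq = AcquisitionConfig(
            batch_size=config.batch_size,
            n_fantasies=config.n_fantasies,
            control_point=config.control_point,
            seed=int(round_seed_root.generate_state(1)[0] % (2**31)),
        )
        proposal = select_batch(model, space, state.evaluated_set(), acq)
    state.pending = list(proposal.points)
    return proposal


def ingest_round(state: CampaignState, observations: Sequence[Observation]) -> None:
    """Record a round's assay results; every pending design must be present."""
    got = {o.point for o in observations}
    missing = [p for p in state.pending if p not in got]
    if missing:
        raise MissingResultsError(missing)
    state.record_round(list(observations))


def _simulate_evaluator(landscape: Landscape, config: CampaignConfig,
                        seed_seq: np.random.SeedSequence) -> Callable:
    rng = np.random.default_rng(seed_seq)

    def evaluate(points: Sequence[DesignPoint], round_index: int) -> list[Observation]:
        return [
            evaluate_point(landscape, p, config.noise, config.replicates,
                           rng, round_index=round_index)
            for p in points
        ]

    return evaluate


def run_campaign(landscape: Landscape | None, config: CampaignConfig,
                 evaluator: Callable | None = None,
                 state_path: str | Path | None = None) -> CampaignState:
    """Run a full multi-round campaign.

    In ``simulate`` mode, designs are assayed against ``landscape`` with the
    configured noise and replicates.  In ``lab`` mode an ``evaluator``
    callback must supply observations for each proposed batch (file-mediated
    workflows use :func:`propose_round` / :func:`ingest_round` directly).
    When ``state_path`` is given the state is serialized after every round.
    """
    if config.mode == "simulate":
        if landscape is None:
            raise ValidationError("simulate mode requires a landscape")
        space = landscape.space
        evaluator = _simulate_evaluator(
            landscape, config, np.random.SeedSequence(config.seed, spawn_key=(9999,)))
    else:
        if evaluator is None:
            raise ValidationError("lab mode requires an evaluator callback")
        if landscape is not None:
            space = landscape.space
        else:
            raise ValidationError("run_campaign needs a space-bearing landscape; "
                                  "use propose_round/ingest_round for file-driven runs")

    if config.rounds * config.batch_size > space.size():
        raise ValidationError("campaign would exceed the design space")

    state = CampaignState(space=space, rng_descriptor=f"seed={config.seed}")
    for _ in range(config.rounds):
        # new designs this round: the control is only new in round 1
        n_new = config.batch_size - (
            1 if config.control_point and state.round_index > 0 else 0)
        if len(state.evaluated) + n_new > config.max_evaluations:
            break
        proposal = propose_round(state, config)
        obs = evaluator(proposal.points, state.round_index)
        ingest_round(state, obs)
        if state_path is not None:
            Path(state_path).write_text(state.to_json())
    return state


# ---------------------------------------------------------------------------
# Sequential benchmark harness (evaluations-to-maximum)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchResult:
    """Outcome of one sequential max search on one landscape."""

    found_max: bool
    found_95: bool
    n_to_max: int | None
    n_to_95: int | None
    n_evaluated: int
    evaluated: tuple[DesignPoint, ...] = ()


def run_sequential_max_search(
    landscape: Landscape,
    noise: NoiseModel = NoiseModel(0.0),
    cap: int = 400,
    seed: int | np.random.SeedSequence | None = None,
    fit_restarts: int = 2,
    refit_every: int | None = None,
    n_init: int | None = None,
) -> SearchResult:
    """Fully sequential GP-EI search until the true argmax is evaluated.

    Starts from a seeded space-filling design of ``d`` points, then
    repeatedly refits the surrogate and evaluates the EI-argmax among
    unevaluated grid points (single noisy read per design, batch of one, no
    control).  Evaluation counts include the initial design.  Hyperparameters
    are refit with a warm start every ``refit_every`` iterations (by default
    every iteration while fewer than 40 points, then every 5th).
    """
    if cap < 1:
        raise ValidationError("cap must be >= 1")
    space = landscape.space
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        0 if seed is None else seed)
    ss_design, ss_noise, ss_fit = ss.spawn(3)
    rng = np.random.default_rng(ss_noise)
    fit_seed = int(ss_fit.generate_state(1)[0] % (2**31))

    d = space.n_factors
    # minimal space-filling prefix: one point per dimension (hyperparameters
    # stay at prior defaults below 2d observations regardless)
    n_init = min(n_init if n_init is not None else max(d, 2), cap)
    evaluated: list[DesignPoint] = []
    observations: list[Observation] = []

    grid_units = space.all_unit_coords()
    argmax_idx = space.index_of(landscape.argmax)
    taken = np.zeros(space.size(), dtype=bool)

    def observe(p: DesignPoint) -> None:
        obs = evaluate_point(landscape, p, noise, replicates=1, rng=rng)
        observations.append(obs)
        evaluated.append(p)
        taken[space.index_of(p)] = True

    for p in initial_design(space, n_init, seed=ss_design):
        observe(p)

    model: GPModel | None = None
    warm = None
    since_fit = 0
    while not taken[argmax_idx] and len(evaluated) < cap:
        X, y = observations_to_arrays(observations, space)
        # hyperparameters stabilize as data accumulate: refit every step
        # early on, then on a fixed cadence (warm-started)
        cadence = refit_every if refit_every is not None else (
            1 if len(y) < 40 else 5)
        if model is None or since_fit >= cadence:
            fc = FitConfig(restarts=fit_restarts, seed=fit_seed, warm_start=warm)
            model = fit_gp_arrays(X, y, fc)
            warm = model.hyperparams
            since_fit = 0
        else:
            # reuse hyperparameters, refresh the solved state with new data
            y_mean, y_sd = float(y.mean()), float(y.std()) or 1.0
            model = _solve_model(warm, X, (y - y_mean) / y_sd, y_mean, y_sd,
                                 model.kernel_kind)
        since_fit += 1
        avail = np.nonzero(~taken)[0]
        means, variances = posterior(model, grid_units[avail])
        best = max(o.mean_value for o in observations)
        ei = expected_improvement(means, np.sqrt(variances), best)
        observe(space.point_at(int(avail[int(np.argmax(ei))])))

    checks = success_checks(evaluated, landscape)
    return SearchResult(
        found_max=checks["found_max"], found_95=checks["found_95"],
        n_to_max=checks["n_to_max"], n_to_95=checks["n_to_95"],
        n_evaluated=len(evaluated), evaluated=tuple(evaluated),
    )


# ---------------------------------------------------------------------------
# Error-robustness benchmark (the 0/10/20% table)
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkTable:
    """Aggregated error-robustness results, one row per error rate.

    ``mean_points_before_*`` average over the runs where the criterion was
    met; percentages are over all runs.
    """

    rows: pd.DataFrame
    runs: pd.DataFrame  # per-(landscape, rate) detail

    def __post_init__(self):
        pct = self.rows[["pct_max_found", "pct_95_found"]].to_numpy()
        if np.any(pct < 0) or np.any(pct > 100):
            raise ValidationError("percentages must lie in [0, 100]")

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _benchmark_landscapes(n_landscapes: int, seed: int,
                          space: DesignSpace | None,
                          gen_params: GMMGeneratorParams):
    space = space or make_design_space(3, [24, 24, 24], ["crtE", "crtB", "crtI"])
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_landscapes)
    for i, child in enumerate(children):
        ss_land, ss_runs = child.spawn(2)
        yield i, sample_gmm_landscape(space, gen_params, seed=ss_land), ss_runs


def benchmark_error_robustness(
    error_rates: Sequence[float],
    n_landscapes: int = 100,
    cap: int = 400,
    seed: int = 0,
    space: DesignSpace | None = None,
    gen_params: GMMGeneratorParams = GMMGeneratorParams(),
    fit_restarts: int = 2,
    refit_every: int = 1,
) -> BenchmarkTable:
    """Sequential-search success statistics across assay error rates.

    Paired design: the same seeded landscapes are reused at every error
    rate, so rate effects are within-landscape comparisons.
    """
    if n_landscapes < 1:
        raise ValidationError("n_landscapes must be >= 1")
    if any(r < 0 for r in error_rates):
        raise ValidationError("error rates must be >= 0")
    records = []
    for i, landscape, ss_runs in _benchmark_landscapes(
            n_landscapes, seed, space, gen_params):
        rate_seeds = ss_runs.spawn(len(error_rates))
        for rate, ss_rate in zip(error_rates, rate_seeds):
            res = run_sequential_max_search(
                landscape, NoiseModel(rate), cap=cap, seed=ss_rate,
                fit_restarts=fit_restarts, refit_every=refit_every)
            records.append({
                "landscape": i, "error_rate": rate,
                "found_max": res.found_max, "found_95": res.found_95,
                "n_to_max": res.n_to_max, "n_to_95": res.n_to_95,
                "n_evaluated": res.n_evaluated,
            })
    runs = pd.DataFrame(records)
    rows = []
    for rate in error_rates:
        sub = runs[runs["error_rate"] == rate]
        rows.append({
            "error_rate": rate,
            "mean_points_before_max": sub.loc[sub["found_max"], "n_to_max"].mean(),
            "mean_points_before_95": sub.loc[sub["found_95"], "n_to_95"].mean(),
            "pct_max_found": 100.0 * sub["found_max"].mean(),
            "pct_95_found": 100.0 * sub["found_95"].mean(),
            "n_landscapes": len(sub),
            "cap": cap,
        })
    return BenchmarkTable(rows=pd.DataFrame(rows), runs=runs)


# ---------------------------------------------------------------------------
# Batch-size study
# ---------------------------------------------------------------------------

def _batched_search_rounds_to_95(landscape: Landscape, batch_size: int,
                                 noise: NoiseModel, cap: int,
                                 seed_seq: np.random.SeedSequence,
                                 fit_restarts: int = 2) -> int | None:
    """Rounds until a >=95%-of-max design is evaluated; None if cap reached.

    Round 0 is a shared d-point seeded design (so batch size 1 reduces
    exactly to the sequential search); subsequent rounds are fantasy batches.
    """
    space = landscape.space
    ss_design, ss_noise, ss_fit, ss_acq = seed_seq.spawn(4)
    rng = np.random.default_rng(ss_noise)
    fit_seed = int(ss_fit.generate_state(1)[0] % (2**31))
    threshold = 0.95 * landscape.f_max

    evaluated: list[DesignPoint] = []
    observations: list[Observation] = []

    def assay(points, round_index):
        for p in points:
            observations.append(
                evaluate_point(landscape, p, noise, replicates=1, rng=rng,
                               round_index=round_index))
            evaluated.append(p)

    init = initial_design(space, min(max(space.n_factors, 2), cap), seed=ss_design)
    assay(init, 0)
    round_index = 0
    warm = None
    while len(evaluated) < cap:
        if any(landscape.value_at(p) >= threshold for p in evaluated):
            return round_index
        round_index += 1
        fc = FitConfig(restarts=fit_restarts, seed=fit_seed, warm_start=warm)
        model = fit_gp(observations, space, fc)
        warm = model.hyperparams
        b = min(batch_size, cap - len(evaluated), space.size() - len(evaluated))
        if b < 1:
            break
        acq = AcquisitionConfig(
            batch_size=b, control_point=None,
            seed=int(ss_acq.generate_state(1)[0] % (2**31)) + round_index)
        proposal = select_batch(model, space, set(evaluated), acq)
        assay(proposal.points, round_index)
    if any(landscape.value_at(p) >= threshold for p in evaluated):
        return round_index
    return None


def batch_size_study(
    sizes: Sequence[int],
    n_landscapes: int = 10,
    noise: NoiseModel = NoiseModel(0.10),
    cap: int = 400,
    seed: int = 0,
    space: DesignSpace | None = None,
    gen_params: GMMGeneratorParams = GMMGeneratorParams(),
) -> pd.DataFrame:
    """Mean rounds-to-95%-of-max as a function of batch size (paired seeds)."""
    if any(s < 1 for s in sizes):
        raise ValidationError("batch sizes must be >= 1")
    records = []
    for i, landscape, ss_runs in _benchmark_landscapes(
            n_landscapes, seed, space, gen_params):
        size_seeds = ss_runs.spawn(len(sizes))
        for size, ss_size in zip(sizes, size_seeds):
            rounds = _batched_search_rounds_to_95(landscape, size, noise, cap, ss_size)
            records.append({"landscape": i, "batch_size": size,
                            "rounds_to_95": rounds})
    runs = pd.DataFrame(records)
    out = (
        runs.dropna(subset=["rounds_to_95"])
        .groupby("batch_size")["rounds_to_95"].mean()
        .reset_index().rename(columns={"rounds_to_95": "mean_rounds_to_95"})
    )
    out["n_landscapes"] = n_landscapes
    return out


# ---------------------------------------------------------------------------
# Random-screening and resampled-maximum baselines
# ---------------------------------------------------------------------------

def random_screen(landscape: Landscape, n: int,
                  noise: NoiseModel = NoiseModel(0.0), replicates: int = 4,
                  seed: int | np.random.SeedSequence | None = None) -> dict:
    """Uniform-random library screen of ``n`` distinct designs.

    Uses the same noise/replicate model as campaigns so comparisons are
    like-for-like.  Returns the best observed mean and the best true value
    among the screened designs.
    """
    space = landscape.space
    if n > space.size():
        raise ValidationError("cannot screen more designs than the space holds")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        0 if seed is None else seed)
    ss_pick, ss_noise = ss.spawn(2)
    rng_pick = np.random.default_rng(ss_pick)
    rng_noise = np.random.default_rng(ss_noise)
    idx = rng_pick.choice(space.size(), size=n, replace=False)
    points = [space.point_at(int(i)) for i in idx]
    observations = [
        evaluate_point(landscape, p, noise, replicates, rng_noise) for p in points
    ]
    best_obs = max(observations, key=lambda o: o.mean_value)
    best_true = max(landscape.value_at(p) for p in points)
    return {"points": points, "observations": observations,
            "best_mean": best_obs.mean_value, "best_point": best_obs.point,
            "best_true": best_true}


def resampled_max_stats(sample_mean: float, sample_sd: float,
                        n_draw: int = 136, reps: int = 1000,
                        seed: int | None = None) -> dict:
    """Expected best-of-``n_draw`` under a normal model of screened titers.

    Models what the maximum of a random library screen "should" look like:
    draw ``n_draw`` values from Normal(sample_mean, sample_sd^2), record the
    maximum, repeat ``reps`` times, and summarize the maxima.
    """
    if sample_sd < 0:
        raise ValidationError("sample_sd must be >= 0")
    if n_draw < 1 or reps < 1:
        raise ValidationError("n_draw and reps must be >= 1")
    if sample_sd == 0:
        return {"mean_of_maxima": float(sample_mean), "sd_of_maxima": 0.0}
    rng = np.random.default_rng(seed)
    maxima = rng.normal(sample_mean, sample_sd, size=(reps, n_draw)).max(axis=1)
    return {"mean_of_maxima": float(maxima.mean()),
            "sd_of_maxima": float(maxima.std(ddof=1))}
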