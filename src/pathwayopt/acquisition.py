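"""Expected Improvement acquisition and parallel batch selection.

EI scores each unevaluated grid point by how much improvement over the
current best observation is expected under the GP posterior,
``EI = E[max(Y - best, 0)]``, which trades off exploitation (high posterior
mean) against exploration (high posterior variance) in closed form.

Batches are assembled greedily with Monte-Carlo *fantasies* for pending
points: after each slot is chosen, plausible outcomes at that point are
drawn from the posterior and their mean is appended as a pretend
observation (hyperparameters frozen), so later slots account for what the
pending experiments are likely to reveal instead of piling onto one peak.
The first round of a campaign bypasses the model entirely and uses a
space-filling (Latin-hypercube-on-grid) design, since nothing is known yet;
a designated control construct can occupy the last slot of every batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gridspace import DesignPoint, DesignSpace, ValidationError
from .gp import GPModel, augment_model, posterior

__all__ = [
    "AcquisitionConfig",
    "BatchProposal",
    "expected_improvement",
    "initial_design",
    "select_batch",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Batch-selection settings.

    ``batch_size`` counts all slots including the control; ``n_fantasies``
    posterior draws are averaged into each pending point's fantasy value;
    ``xi`` is an optional exploration jitter subtracted from the incumbent
    (default 0).
    """

    batch_size: int = 46
    n_fantasies: int = 10
    xi: float = 0.0
    exclude_evaluated: bool = True
    control_point: DesignPoint | None = None
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.n_fantasies < 1:
            raise ValidationError("n_fantasies must be >= 1")
        if self.xi < 0:
            raise ValidationError("xi must be >= 0")


@dataclass(frozen=True)
class BatchProposal:
    """An ordered batch of distinct design points with their EI at selection."""

    points: tuple[DesignPoint, ...]
    ei_at_selection: tuple[float, ...]
    contains_control: bool = False

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self, space: DesignSpace) -> "pd.DataFrame":
        """Tabular export: slot, one level column per factor, EI, control flag."""
        import pandas as pd

        rows = []
        n = len(self.points)
        for slot, (p, ei) in enumerate(zip(self.points, self.ei_at_selection),
                                       start=1):
            row = {"slot": slot}
            row.update({f"level_{name}": c
                        for name, c in zip(space.factor_names, p.coords)})
            row["ei_value"] = ei
            row["is_control"] = bool(self.contains_control and slot == n)
            rows.append(row)
        return pd.DataFrame(rows)


def expected_improvement(mean, sd, best: float, xi: float = 0.0):
    """Closed-form EI of a Gaussian posterior over an incumbent ``best``.

    ``EI = (mean - best - xi) * Phi(z) + sd * phi(z)`` with
    ``z = (mean - best - xi) / sd``; the ``sd = 0`` limit is
    ``max(mean - best - xi, 0)``.  Vectorized over ``mean``/``sd``.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValidationError("sd must be nonnegative")
    delta = mean - best - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, delta / np.where(sd > 0, sd, 1.0), 0.0)
        ei = np.where(
            sd > 0,
            delta * stats.norm.cdf(z) + sd * stats.norm.pdf(z),
            np.maximum(delta, 0.0),
        )
    return np.maximum(ei, 0.0) if ei.ndim else float(max(ei, 0.0))


def initial_design(space: DesignSpace, n: int,
                   seed: int | np.random.SeedSequence | None = None) -> list[DesignPoint]:
    """Space-filling first-round design: Latin-hypercube levels on the grid.

    Each factor's ``n`` levels are drawn one per stratum of [0, 1] and
    rounded to the grid, then independently permuted; duplicate points are
    replaced by uniform-random unvisited points.  Seeded and reproducible.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if n > space.size():
        raise ValidationError(f"cannot place {n} distinct points in a "
                              f"{space.size()}-point space")
    rng = np.random.default_rng(seed)
    cols = []
    for lv in space.levels_per_factor:
        # one sample per stratum, mapped to levels 1..lv
        u = (np.arange(n) + rng.uniform(size=n)) / n
        levels = np.minimum((u * lv).astype(int) + 1, lv)
        cols.append(rng.permutation(levels))
    candidates = [DesignPoint(tuple(int(c[i]) for c in cols)) for i in range(n)]
    seen: set[DesignPoint] = set()
    design: list[DesignPoint] = []
    for p in candidates:
        if p not in seen:
            seen.add(p)
            design.append(p)
    # top up collisions with uniform-random unvisited grid points
    size = space.size()
    while len(design) < n:
        p = space.point_at(int(rng.integers(size)))
        if p not in seen:
            seen.add(p)
            design.append(p)
    return design


def _grid_and_candidates(space: DesignSpace, evaluated, config: AcquisitionConfig):
    grid_units = space.all_unit_coords()
    if config.exclude_evaluated and evaluated:
        excluded = np.fromiter(
            (space.index_of(p) for p in evaluated), dtype=np.int64
        )
        mask = np.ones(space.size(), dtype=bool)
        mask[excluded] = False
    else:
        mask = np.ones(space.size(), dtype=bool)
    cand_idx = np.nonzero(mask)[0]  # enumeration order => argmax ties break low
    return grid_units, cand_idx


def select_batch(model: GPModel, space: DesignSpace, evaluated,
                 config: AcquisitionConfig) -> BatchProposal:
    """Greedy fantasy-based parallel EI batch.

    For each slot the EI landscape is recomputed under the current
    fantasy-augmented model; the incumbent is the best observed (or fantasy)
    value so far.  Ties break toward the lowest enumeration index.  If a
    control point is configured it takes the final slot (without consuming a
    fantasy) and is exempt from the evaluated-point exclusion.
    """
    evaluated = set(evaluated)
    rng = np.random.default_rng(config.seed)
    grid_units, cand_idx = _grid_and_candidates(space, evaluated, config)

    control = config.control_point
    n_model_slots = config.batch_size
    if control is not None:
        space.validate_point(control)
        n_model_slots -= 1
        control_idx = space.index_of(control)
        cand_idx = cand_idx[cand_idx != control_idx]
    if len(cand_idx) < n_model_slots:
        raise ValidationError(
            f"batch_size {config.batch_size} exceeds the {len(cand_idx)} "
            "available candidates"
        )
    if n_model_slots > 0 and len(cand_idx) == 0:
        raise RuntimeError("no candidates left to select from")

    current = model
    # incumbent: best observed mean (training data are replicate means)
    best = float(
        (current.y_mean + current.y_sd * current.train_values).max()
    )
    chosen: list[DesignPoint] = []
    chosen_ei: list[float] = []
    taken = np.zeros(space.size(), dtype=bool)

    for _ in range(n_model_slots):
        avail = cand_idx[~taken[cand_idx]]
        means, variances = posterior(current, grid_units[avail])
        ei = expected_improvement(means, np.sqrt(variances), best, config.xi)
        pick = int(np.argmax(ei))  # first max => lowest enumeration index
        idx = int(avail[pick])
        point = space.point_at(idx)
        chosen.append(point)
        chosen_ei.append(float(ei[pick]))
        taken[idx] = True
        # fantasy: mean of posterior draws at the pending point, frozen theta
        mu, var = posterior(current, grid_units[idx][None, :])
        draws = rng.normal(mu[0], np.sqrt(var[0]), size=config.n_fantasies)
        fantasy = float(draws.mean())
        current = augment_model(current, grid_units[idx][None, :], [fantasy])
        best = max(best, fantasy)

    contains_control = False
    if control is not None:
        chosen.append(control)
        mu, var = posterior(current, grid_units[space.index_of(control)][None, :])
        chosen_ei.append(float(expected_improvement(
            mu[0], float(np.sqrt(var[0])), best, config.xi)))
        contains_control = True

    return BatchProposal(points=tuple(chosen), ei_at_selection=tuple(chosen_ei),
                         contains_control=contains_control)
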