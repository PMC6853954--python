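"""Discrete combinatorial design spaces for pathway expression tuning.

A design space is the Cartesian grid of expression levels for each tunable
gene: a point ``(x_1, ..., x_d)`` with ``x_j`` a 1-based level index selects
one promoter/RBS bundle per gene.  The canonical instance is the 3-gene
lycopene pathway (crtE, crtB, crtI) with 24 ordered expression levels per
gene, a grid of 24**3 = 13,824 candidate constructs.

Levels are 1-based integers, matching how grid points are written in the
field (the mid-ladder control construct is literally ``(12, 12, 12)``).  For
kernel computations each factor is affinely mapped onto [0, 1] by
:func:`to_unit_coords`; level order is assumed to be the strength-ranked
order of the promoter/RBS ladder, which is what makes a smooth surrogate
prior over the grid sensible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpace",
    "DesignPoint",
    "PartBundle",
    "PartsLibrary",
    "make_design_space",
    "to_unit_coords",
    "parts_for_point",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class DesignPoint:
    """A single grid point: one 1-based expression level per factor.

    Equality and hashing are by coordinate vector, so points can be kept in
    visited-sets during a campaign.
    """

    coords: tuple[int, ...]

    def __init__(self, coords: Sequence[int]):
        object.__setattr__(self, "coords", tuple(int(c) for c in coords))

    def __iter__(self) -> Iterator[int]:
        return iter(self.coords)

    def __len__(self) -> int:
        return len(self.coords)

    def __repr__(self) -> str:
        return f"DesignPoint{self.coords}"


@dataclass(frozen=True)
class DesignSpace:
    """The full factorial grid of expression levels.

    Parameters
    ----------
    n_factors
        Number of tunable genes (dimensions), ``d``.
    levels_per_factor
        Number of ordered expression levels for each gene.
    factor_names
        Optional labels (e.g. ``("crtE", "crtB", "crtI")``).
    """

    n_factors: int
    levels_per_factor: tuple[int, ...]
    factor_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.n_factors < 1:
            raise ValidationError("n_factors must be >= 1")
        if len(self.levels_per_factor) != self.n_factors:
            raise ValidationError(
                f"levels_per_factor has length {len(self.levels_per_factor)}, "
                f"expected {self.n_factors}"
            )
        if any(lv < 1 for lv in self.levels_per_factor):
            raise ValidationError("every factor needs at least one level")
        if not self.factor_names:
            object.__setattr__(
                self,
                "factor_names",
                tuple(f"factor{j + 1}" for j in range(self.n_factors)),
            )
        elif len(self.factor_names) != self.n_factors:
            raise ValidationError("factor_names length must equal n_factors")

    def size(self) -> int:
        return int(np.prod(self.levels_per_factor, dtype=np.int64))

    def contains(self, point: DesignPoint) -> bool:
        return len(point) == self.n_factors and all(
            1 <= c <= lv for c, lv in zip(point.coords, self.levels_per_factor)
        )

    def validate_point(self, point: DesignPoint) -> None:
        if not self.contains(point):
            raise ValidationError(
                f"{point!r} is outside the grid with levels {self.levels_per_factor}"
            )

    def enumerate_points(self) -> Iterator[DesignPoint]:
        """Lexicographic enumeration, factor 1 slowest: (1,1),(1,2),...,(2,1),..."""
        for coords in itertools.product(
            *(range(1, lv + 1) for lv in self.levels_per_factor)
        ):
            yield DesignPoint(coords)

    def index_of(self, point: DesignPoint) -> int:
        """0-based lexicographic enumeration index of a point."""
        self.validate_point(point)
        idx = 0
        for c, lv in zip(point.coords, self.levels_per_factor):
            idx = idx * lv + (c - 1)
        return idx

    def point_at(self, index: int) -> DesignPoint:
        if not 0 <= index < self.size():
            raise ValidationError(f"index {index} out of range for size {self.size()}")
        coords = []
        for lv in reversed(self.levels_per_factor):
            coords.append(index % lv + 1)
            index //= lv
        return DesignPoint(tuple(reversed(coords)))

    def all_levels(self) -> np.ndarray:
        """Integer level matrix of the whole grid, shape (size, d), enumeration order."""
        grids = np.meshgrid(
            *(np.arange(1, lv + 1) for lv in self.levels_per_factor), indexing="ij"
        )
        return np.stack([g.ravel() for g in grids], axis=1)

    def all_unit_coords(self) -> np.ndarray:
        """Unit-coordinate matrix of the whole grid, shape (size, d), enumeration order."""
        return levels_to_unit(self.all_levels(), self)


def make_design_space(n_factors: int, levels: Sequence[int],
                      factor_names: Sequence[str] | None = None) -> DesignSpace:
    """Build the factorial design space of per-gene expression levels."""
    return DesignSpace(
        n_factors=int(n_factors),
        levels_per_factor=tuple(int(lv) for lv in levels),
        factor_names=tuple(factor_names) if factor_names else (),
    )


def levels_to_unit(levels: np.ndarray, space: DesignSpace) -> np.ndarray:
    """Vectorized affine map of integer level arrays onto [0, 1] per factor.

    Level 1 maps to 0 and level L to 1; a single-level factor maps to 0.
    """
    levels = np.asarray(levels, dtype=float)
    denom = np.maximum(np.asarray(space.levels_per_factor, dtype=float) - 1.0, 1.0)
    return (levels - 1.0) / denom


def to_unit_coords(point: DesignPoint, space: DesignSpace) -> np.ndarray:
    """Map a grid point onto the unit hypercube used by the kernel."""
    space.validate_point(point)
    return levels_to_unit(np.asarray(point.coords), space)


# ---------------------------------------------------------------------------
# Parts library: level index -> promoter/RBS bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartBundle:
    """The regulatory parts realizing one expression level of one gene."""

    promoter_id: str
    rbs_id: str
    relative_strength: float | None = None


@dataclass(frozen=True)
class PartsLibrary:
    """Ordered per-factor map from level index to promoter/RBS bundle.

    The level order is the strength-ranked order of the promoter/RBS ladder
    (12 promoters x 2 RBSs = 24 levels per gene in the lycopene instance);
    when ``relative_strength`` is given it must be nondecreasing in level.
    """

    bundles: tuple[tuple[PartBundle, ...], ...]  # bundles[factor][level-1]

    def __post_init__(self):
        for j, ladder in enumerate(self.bundles):
            strengths = [b.relative_strength for b in ladder]
            if all(s is not None for s in strengths) and len(strengths) > 1:
                arr = np.asarray(strengths, dtype=float)
                if np.any(arr < 0):
                    raise ValidationError(
                        f"factor {j + 1}: relative_strength must be nonnegative"
                    )
                if np.any(np.diff(arr) < 0):
                    raise ValidationError(
                        f"factor {j + 1}: levels must be ordered by "
                        "nondecreasing relative_strength"
                    )

    def n_levels(self, factor: int) -> int:
        return len(self.bundles[factor])

    def lookup(self, factor: int, level: int) -> PartBundle:
        """0-based factor, 1-based level."""
        ladder = self.bundles[factor]
        if not 1 <= level <= len(ladder):
            raise LookupError(
                f"factor {factor + 1} has no level {level} "
                f"(library holds {len(ladder)} levels)"
            )
        return ladder[level - 1]

    def covers(self, space: DesignSpace) -> bool:
        return len(self.bundles) == space.n_factors and all(
            len(self.bundles[j]) == space.levels_per_factor[j]
            for j in range(space.n_factors)
        )


def parts_for_point(point: DesignPoint, library: PartsLibrary) -> list[PartBundle]:
    """Resolve a grid point to the promoter/RBS bundle of each gene."""
    if len(point) > len(library.bundles):
        raise LookupError(
            f"library covers {len(library.bundles)} factors, point has {len(point)}"
        )
    return [library.lookup(j, c) for j, c in enumerate(point.coords)]


def load_parts_library(path) -> PartsLibrary:
    """Read a parts library CSV with columns factor,level,promoter_id,rbs_id[,relative_strength].

    ``factor`` is 1-based and rows for each factor must cover levels 1..L
    exactly once; the file must be pre-sorted so strengths form a ladder.
    """
    df = pd.read_csv(path)
    required = {"factor", "level", "promoter_id", "rbs_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"parts library missing columns: {sorted(missing)}")
    has_strength = "relative_strength" in df.columns
    factors = sorted(df["factor"].unique())
    if factors != list(range(1, len(factors) + 1)):
        raise ValidationError(f"factor column must be 1..n, got {factors}")
    ladders = []
    for f in factors:
        sub = df[df["factor"] == f].sort_values("level")
        levels = sub["level"].tolist()
        if levels != list(range(1, len(levels) + 1)):
            raise ValidationError(
                f"factor {f}: levels must cover 1..L exactly once, got {levels}"
            )
        ladders.append(
            tuple(
                PartBundle(
                    promoter_id=str(r.promoter_id),
                    rbs_id=str(r.rbs_id),
                    relative_strength=float(r.relative_strength) if has_strength else None,
                )
                for r in sub.itertuples()
            )
        )
    return PartsLibrary(bundles=tuple(ladders))


def synthetic_parts_library(space: DesignSpace, fold_range: float = 1000.0) -> PartsLibrary:
    """Construct a synthetic promoter/RBS ladder covering ``space``.

    Strengths are log-spaced over ``fold_range`` (a ~1000-fold dynamic range
    is typical for a mutagenized T7 promoter x RBS ladder); promoter/RBS ids
    follow the 12-promoter x 2-RBS pattern when the level count is even.
    Synthetic stand-in for a measured library; useful for tests and demos.
    """
    ladders = []
    for j, n_lv in enumerate(space.levels_per_factor):
        strengths = np.logspace(0.0, np.log10(fold_range), n_lv)
        ladder = []
        for lv in range(1, n_lv + 1):
            if n_lv % 2 == 0:
                promoter = f"T7p{(lv + 1) // 2:02d}"
                rbs = "rbsW" if lv % 2 == 1 else "rbsS"
            else:
                promoter, rbs = f"T7p{lv:02d}", "rbsW"
            ladder.append(
                PartBundle(promoter_id=promoter, rbs_id=rbs,
                           relative_strength=float(strengths[lv - 1]))
            )
        ladders.append(tuple(ladder))
    return PartsLibrary(bundles=tuple(ladders))


def library_to_frame(library: PartsLibrary) -> pd.DataFrame:
    """Tabular view of a parts library (the CSV serialization)."""
    rows = []
    for j, ladder in enumerate(library.bundles):
        for lv, b in enumerate(ladder, start=1):
            rows.append(
                {"factor": j + 1, "level": lv, "promoter_id": b.promoter_id,
                 "rbs_id": b.rbs_id, "relative_strength": b.relative_strength}
            )
    return pd.DataFrame(rows)
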