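"""Worlds, demographic scenarios and sampling schemes.

A world is a rectangular lattice of demes (cells), possibly with water cells,
connected by a 4-neighborhood (stepping-stone topology).  Scenarios combine a
world with per-generation parameter schedules (carrying capacity K, emigration
rate m), logistic growth, a mutation model and a serial sampling scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ConfigurationError",
    "LatticeWorld",
    "ScheduledValue",
    "SamplingGroup",
    "SamplingScheme",
    "ScenarioConfig",
    "build_square_world",
    "load_world_raster",
    "world_from_mask",
    "serial_sampling",
    "heterogeneity_scheme",
]


class ConfigurationError(ValueError):
    """Invalid world, scenario or sampling configuration."""


@dataclass(frozen=True)
class LatticeWorld:
    """A grid of demes with a land mask and 4-neighborhood adjacency.

    Attributes
    ----------
    n_rows, n_cols : int
        Grid dimensions.
    land_mask : ndarray of bool, shape (n_rows, n_cols)
        True for land demes.
    origin : tuple of int
        (row, col) of the deme where the expansion starts; must be land.
    deme_id : ndarray of int, shape (n_rows, n_cols)
        Dense index 0..D-1 for land demes (row-major order), -1 for water.
    positions : ndarray of int, shape (D, 2)
        (row, col) of each land deme.
    neighbors : ndarray of int, shape (D, 4)
        Land-deme indices of the N/S/E/W neighbors, -1 where absent.
    degree : ndarray of int, shape (D,)
        Number of land neighbors per deme.
    geo : tuple of float or None
        Optional (lat0, lon0, cell_km) georeference of cell (0, 0), used to
        map latitude/longitude metadata onto demes for raster worlds.
    """

    n_rows: int
    n_cols: int
    land_mask: np.ndarray
    origin: tuple[int, int]
    deme_id: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)
    neighbors: np.ndarray = field(repr=False)
    degree: np.ndarray = field(repr=False)
    geo: tuple[float, float, float] | None = None

    @property
    def D(self) -> int:
        """Number of land demes."""
        return int(self.positions.shape[0])

    @property
    def origin_id(self) -> int:
        return int(self.deme_id[self.origin])

    def is_land(self, row: int, col: int) -> bool:
        return (
            0 <= row < self.n_rows
            and 0 <= col < self.n_cols
            and bool(self.land_mask[row, col])
        )

    def id_of(self, deme: tuple[int, int]) -> int:
        """Dense index of a land deme given as (row, col)."""
        row, col = deme
        if not self.is_land(row, col):
            raise ConfigurationError(f"deme ({row}, {col}) is not a land deme")
        return int(self.deme_id[row, col])

    def neighbor_demes(self, deme: tuple[int, int]) -> list[tuple[int, int]]:
        """(row, col) of the land neighbors of a land deme."""
        i = self.id_of(deme)
        out = []
        for j in self.neighbors[i]:
            if j >= 0:
                out.append(tuple(int(x) for x in self.positions[j]))
        return out

    def nearest_land_deme(
        self, row: int, col: int, max_cells: int = 1
    ) -> tuple[int, int]:
        """Snap a cell to the nearest land deme within ``max_cells`` (Chebyshev)."""
        if self.is_land(row, col):
            return (row, col)
        best = None
        best_d2 = None
        for dr in range(-max_cells, max_cells + 1):
            for dc in range(-max_cells, max_cells + 1):
                r, c = row + dr, col + dc
                if self.is_land(r, c):
                    d2 = dr * dr + dc * dc
                    if best_d2 is None or d2 < best_d2:
                        best, best_d2 = (r, c), d2
        if best is None:
            raise ConfigurationError(
                f"cell ({row}, {col}) has no land deme within {max_cells} cell(s)"
            )
        return best


def world_from_mask(
    land_mask: np.ndarray,
    origin: tuple[int, int],
    geo: tuple[float, float, float] | None = None,
) -> LatticeWorld:
    """Build a :class:`LatticeWorld` from a boolean land mask and an origin cell."""
    mask = np.asarray(land_mask, dtype=bool)
    if mask.ndim != 2:
        raise ConfigurationError("land mask must be two-dimensional")
    n_rows, n_cols = mask.shape
    if not mask.any():
        raise ConfigurationError("world has no land demes")
    orow, ocol = int(origin[0]), int(origin[1])
    if not (0 <= orow < n_rows and 0 <= ocol < n_cols) or not mask[orow, ocol]:
        raise ConfigurationError(f"origin ({orow}, {ocol}) is not a land deme")

    deme_id = np.full((n_rows, n_cols), -1, dtype=np.int32)
    positions = np.argwhere(mask).astype(np.int32)
    deme_id[positions[:, 0], positions[:, 1]] = np.arange(
        positions.shape[0], dtype=np.int32
    )
    D = positions.shape[0]
    neighbors = np.full((D, 4), -1, dtype=np.int32)
    offsets = ((-1, 0), (1, 0), (0, 1), (0, -1))  # N, S, E, W
    for i in range(D):
        r, c = positions[i]
        for k, (dr, dc) in enumerate(offsets):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and mask[rr, cc]:
                neighbors[i, k] = deme_id[rr, cc]
    degree = (neighbors >= 0).sum(axis=1).astype(np.int32)
    return LatticeWorld(
        n_rows=n_rows,
        n_cols=n_cols,
        land_mask=mask,
        origin=(orow, ocol),
        deme_id=deme_id,
        positions=positions,
        neighbors=neighbors,
        degree=degree,
        geo=geo,
    )


def build_square_world(size: int) -> LatticeWorld:
    """All-land square world of ``size`` x ``size`` demes.

    The expansion origin is the central deme (floor(size/2), floor(size/2)).
    """
    size = int(size)
    if size < 1:
        raise ConfigurationError("size must be >= 1")
    mask = np.ones((size, size), dtype=bool)
    return world_from_mask(mask, (size // 2, size // 2))


def load_world_raster(path: str | Path) -> LatticeWorld:
    """Load a plain-text 0/1 raster world.

    Format: a header line ``origin ROW COL``, an optional line
    ``geo LAT0 LON0 CELL_KM``, then one line of whitespace-separated 0/1
    values per grid row (1 = land).
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("origin"):
        raise ConfigurationError(f"{path}: first line must be 'origin ROW COL'")
    parts = lines[0].split()
    if len(parts) != 3:
        raise ConfigurationError(f"{path}: malformed origin header: {lines[0]!r}")
    origin = (int(parts[1]), int(parts[2]))
    geo = None
    body = lines[1:]
    if body and body[0].startswith("geo"):
        gp = body[0].split()
        if len(gp) != 4:
            raise ConfigurationError(f"{path}: malformed geo header: {body[0]!r}")
        geo = (float(gp[1]), float(gp[2]), float(gp[3]))
        body = body[1:]
    if not body:
        raise ConfigurationError(f"{path}: raster body is empty")
    rows = []
    width = None
    for ln in body:
        vals = ln.split()
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise ConfigurationError(f"{path}: ragged raster row: {ln!r}")
        try:
            row = [int(v) for v in vals]
        except ValueError as exc:
            raise ConfigurationError(f"{path}: non-integer raster cell") from exc
        if any(v not in (0, 1) for v in row):
            raise ConfigurationError(f"{path}: raster cells must be 0 or 1")
        rows.append(row)
    mask = np.array(rows, dtype=bool)
    return world_from_mask(mask, origin, geo=geo)


@dataclass(frozen=True)
class ScheduledValue:
    """A piecewise-constant parameter over forward generations.

    ``values[i]`` applies from ``breakpoints[i]`` (inclusive) up to the next
    breakpoint (exclusive).  The first breakpoint must be 0.
    """

    breakpoints: tuple[int, ...]
    values: tuple[float, ...]

    def __init__(self, breakpoints, values):
        bps = tuple(int(b) for b in breakpoints)
        vals = tuple(float(v) for v in values)
        if len(bps) != len(vals) or not bps:
            raise ConfigurationError("schedule needs one value per breakpoint")
        if bps[0] != 0:
            raise ConfigurationError("first schedule breakpoint must be 0")
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ConfigurationError("schedule breakpoints must be strictly ascending")
        if any(v < 0 for v in vals):
            raise ConfigurationError("scheduled values must be non-negative")
        object.__setattr__(self, "breakpoints", bps)
        object.__setattr__(self, "values", vals)

    @classmethod
    def constant(cls, value: float) -> "ScheduledValue":
        return cls((0,), (value,))

    def value_at(self, generation: int) -> float:
        """Value applying at a forward generation."""
        if generation < 0:
            raise ConfigurationError("generation must be >= 0")
        idx = int(np.searchsorted(self.breakpoints, generation, side="right")) - 1
        return self.values[idx]

    def per_generation(self, T: int) -> np.ndarray:
        """Expand to an array indexed by forward generation 0..T."""
        gens = np.arange(T + 1)
        idx = np.searchsorted(self.breakpoints, gens, side="right") - 1
        return np.asarray(self.values, dtype=np.float64)[idx]


@dataclass(frozen=True)
class SamplingGroup:
    """One group of lineages sampled in a deme at a given age (generations BP)."""

    deme: tuple[int, int]
    age: int
    count: int
    label: str

    def __post_init__(self):
        object.__setattr__(self, "deme", (int(self.deme[0]), int(self.deme[1])))
        object.__setattr__(self, "age", int(self.age))
        object.__setattr__(self, "count", int(self.count))
        if self.age < 0:
            raise ConfigurationError("sampling age must be >= 0 (generations BP)")
        if self.count < 1:
            raise ConfigurationError("sampling count must be >= 1")
        if self.label not in ("modern", "ancient"):
            raise ConfigurationError("sample_label must be 'modern' or 'ancient'")


@dataclass(frozen=True)
class SamplingScheme:
    """Serial sampling design: groups of lineages with deme, age and label."""

    groups: tuple[SamplingGroup, ...]

    def __init__(self, groups):
        object.__setattr__(self, "groups", tuple(groups))

    def total_count(self, label: str | None = None) -> int:
        return sum(g.count for g in self.groups if label is None or g.label == label)

    def validate(self, world: LatticeWorld, T: int) -> None:
        for g in self.groups:
            if not world.is_land(*g.deme):
                raise ConfigurationError(f"sampling deme {g.deme} is not land")
            if g.age >= T:
                raise ConfigurationError(
                    f"sampling age {g.age} BP must be < T = {T} generations"
                )
        for label in ("modern", "ancient"):
            if self.total_count(label) and self.total_count(label) < 2:
                raise ConfigurationError(f"{label} sample needs >= 2 lineages")


def serial_sampling(
    deme: tuple[int, int],
    n_modern: int = 30,
    n_ancient: int = 30,
    ancient_age: int = 400,
) -> SamplingScheme:
    """The standard design: modern and ancient samples from one deme."""
    return SamplingScheme(
        (
            SamplingGroup(deme, 0, n_modern, "modern"),
            SamplingGroup(deme, ancient_age, n_ancient, "ancient"),
        )
    )


def heterogeneity_scheme(
    kind: str,
    level: int | None,
    base_age: int,
    world: LatticeWorld | None = None,
    delta: int = 25,
) -> SamplingScheme:
    """Heterogeneous ancient-sampling designs on a square world.

    ``spatial`` (levels 1..7): five groups of 5 ancient lineages, one at the
    origin and four at diagonal offsets (+-level, +-level), all at ``base_age``.
    ``temporal`` (levels 1..4): five groups of 5 at the origin with ages
    base_age + {-2, -1, 0, +1, +2} * delta * level.
    ``homogeneous``: one group of 25 at the origin at ``base_age``.
    A modern group of 25 at the origin (age 0) is always appended.
    """
    if world is None:
        world = build_square_world(50)
    orow, ocol = world.origin
    groups: list[SamplingGroup] = []
    if kind == "spatial":
        if level is None or not 1 <= level <= 7:
            raise ConfigurationError("spatial heterogeneity level must be 1..7")
        demes = [(orow, ocol)] + [
            (orow + sr * level, ocol + sc * level)
            for sr, sc in ((-1, -1), (-1, 1), (1, -1), (1, 1))
        ]
        for d in demes:
            if not world.is_land(*d):
                raise ConfigurationError(f"spatial offset leaves the grid: {d}")
            groups.append(SamplingGroup(d, base_age, 5, "ancient"))
    elif kind == "temporal":
        if level is None or not 1 <= level <= 4:
            raise ConfigurationError("temporal heterogeneity level must be 1..4")
        ages = [base_age + k * delta * level for k in (-2, -1, 0, 1, 2)]
        if ages[0] < 0:
            raise ConfigurationError("temporal offsets produce a negative age")
        for a in ages:
            groups.append(SamplingGroup((orow, ocol), a, 5, "ancient"))
    elif kind == "homogeneous":
        groups.append(SamplingGroup((orow, ocol), base_age, 25, "ancient"))
    else:
        raise ConfigurationError(f"unknown heterogeneity kind: {kind!r}")
    groups.append(SamplingGroup((orow, ocol), 0, 25, "modern"))
    return SamplingScheme(groups)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of a continuity scenario.

    Parameters
    ----------
    world : LatticeWorld
    T : int
        Total forward generations of the demographic simulation.
    N0 : int
        Founding haploid population size at the origin deme.
    r : float
        Per-generation logistic growth rate.
    m_schedule : ScheduledValue
        Per-capita emigration probability per generation, in [0, 1].
    K_schedule : ScheduledValue
        Haploid carrying capacity per deme.
    mu : float
        Mutation rate per generation; per site if ``mu_per_site`` else per
        sequence.
    L : int
        Sequence length (bp).
    sampling : SamplingScheme
    label : str
    """

    world: LatticeWorld
    T: int
    N0: int
    r: float
    m_schedule: ScheduledValue
    K_schedule: ScheduledValue
    mu: float
    L: int
    sampling: SamplingScheme
    label: str = ""
    mu_per_site: bool = True

    def __post_init__(self):
        if self.T < 1:
            raise ConfigurationError("T must be >= 1")
        if self.N0 < 1:
            raise ConfigurationError("N0 must be >= 1")
        if self.r < 0:
            raise ConfigurationError("r must be >= 0")
        if self.mu < 0:
            raise ConfigurationError("mu must be >= 0")
        if self.L < 1:
            raise ConfigurationError("L must be >= 1")
        if any(not 0.0 <= v <= 1.0 for v in self.m_schedule.values):
            raise ConfigurationError("all m values must lie in [0, 1]")
        if any(v < 1.0 for v in self.K_schedule.values):
            raise ConfigurationError("all K values must be >= 1")
        self.sampling.validate(self.world, self.T)

    def Nm(self, generation: int) -> float:
        """Migrants per deme per generation, K(g) * m(g)."""
        return self.K_schedule.value_at(generation) * self.m_schedule.value_at(
            generation
        )

    @property
    def mu_per_sequence(self) -> float:
        """Total mutation rate per sequence per generation."""
        return self.mu * self.L if self.mu_per_site else self.mu
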