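"""Scenario configuration files (YAML) and observed-data input.

A scenario file declares the world (square size or raster path), the
demographic parameters and schedules, the mutation model and the sampling
groups.  Bundled scenario fixtures live in the ``serialcoal.scenarios``
package directory and are addressable by name.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .world import (
    ConfigurationError,
    LatticeWorld,
    SamplingGroup,
    SamplingScheme,
    ScenarioConfig,
    ScheduledValue,
    build_square_world,
    load_world_raster,
)

__all__ = [
    "parse_scenario_file",
    "scenario_to_dict",
    "write_scenario_file",
    "bundled_scenario_path",
    "load_bundled_scenario",
    "list_bundled_scenarios",
    "read_alignment",
]

_KNOWN_KEYS = {
    "label",
    "world",
    "T",
    "N0",
    "r",
    "m_schedule",
    "K_schedule",
    "mu",
    "mu_per_site",
    "L",
    "sampling",
}


def _parse_schedule(raw, key: str) -> ScheduledValue:
    if isinstance(raw, (int, float)):
        return ScheduledValue.constant(float(raw))
    if not isinstance(raw, dict) or set(raw) != {"breakpoints", "values"}:
        raise ConfigurationError(
            f"{key}: expected a number or {{breakpoints, values}} block"
        )
    return ScheduledValue(raw["breakpoints"], raw["values"])


def _parse_world(raw, base_dir: Path) -> LatticeWorld:
    if not isinstance(raw, dict) or "type" not in raw:
        raise ConfigurationError("world: expected a block with a 'type' key")
    if raw["type"] == "square":
        return build_square_world(int(raw["size"]))
    if raw["type"] == "raster":
        return load_world_raster(base_dir / raw["path"])
    raise ConfigurationError(f"world.type must be 'square' or 'raster', got {raw['type']!r}")


def parse_scenario_file(path: str | Path) -> ScenarioConfig:
    """Parse and validate a scenario YAML file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: scenario file must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys: {sorted(unknown)}")
    missing = _KNOWN_KEYS - {"label", "mu_per_site"} - set(raw)
    if missing:
        raise ConfigurationError(f"{path}: missing keys: {sorted(missing)}")
    world = _parse_world(raw["world"], path.parent)
    groups = []
    for g in raw["sampling"]:
        groups.append(
            SamplingGroup(
                deme=tuple(g["deme"]),
                age=g["age"],
                count=g["count"],
                label=g["label"],
            )
        )
    try:
        return ScenarioConfig(
            world=world,
            T=int(raw["T"]),
            N0=int(raw["N0"]),
            r=float(raw["r"]),
            m_schedule=_parse_schedule(raw["m_schedule"], "m_schedule"),
            K_schedule=_parse_schedule(raw["K_schedule"], "K_schedule"),
            mu=float(raw["mu"]),
            mu_per_site=bool(raw.get("mu_per_site", True)),
            L=int(raw["L"]),
            sampling=SamplingScheme(groups),
            label=str(raw.get("label", path.stem)),
        )
    except ConfigurationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def scenario_to_dict(scenario: ScenarioConfig, world_entry: dict | None = None) -> dict:
    """Serializable mapping for a scenario (inverse of parse, square worlds)."""
    if world_entry is None:
        w = scenario.world
        if w.n_rows != w.n_cols or not w.land_mask.all():
            raise ConfigurationError(
                "non-square or raster worlds need an explicit world entry"
            )
        world_entry = {"type": "square", "size": w.n_rows}
    return {
        "label": scenario.label,
        "world": world_entry,
        "T": scenario.T,
        "N0": scenario.N0,
        "r": scenario.r,
        "m_schedule": {
            "breakpoints": list(scenario.m_schedule.breakpoints),
            "values": list(scenario.m_schedule.values),
        },
        "K_schedule": {
            "breakpoints": list(scenario.K_schedule.breakpoints),
            "values": list(scenario.K_schedule.values),
        },
        "mu": scenario.mu,
        "mu_per_site": scenario.mu_per_site,
        "L": scenario.L,
        "sampling": [
            {
                "deme": [g.deme[0], g.deme[1]],
                "age": g.age,
                "count": g.count,
                "label": g.label,
            }
            for g in scenario.sampling.groups
        ],
    }


def write_scenario_file(scenario: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False)
    )


def bundled_scenario_path(name: str) -> Path:
    """Filesystem path of a bundled scenario file (``name`` without extension)."""
    base = resources.files("serialcoal") / "scenarios"
    p = Path(str(base / f"{name}.yaml"))
    if not p.exists():
        raise ConfigurationError(
            f"no bundled scenario {name!r}; available: {list_bundled_scenarios()}"
        )
    return p


def load_bundled_scenario(name: str) -> ScenarioConfig:
    return parse_scenario_file(bundled_scenario_path(name))


def list_bundled_scenarios() -> list[str]:
    base = Path(str(resources.files("serialcoal") / "scenarios"))
    return sorted(p.stem for p in base.glob("*.yaml"))


def read_alignment(
    fasta_path: str | Path,
    metadata_path: str | Path,
    world: LatticeWorld | None = None,
):
    """Load an observed alignment with sample metadata.

    The metadata TSV needs columns ``id``, ``sample_label``, ``age`` and either
    ``deme_row``/``deme_col`` or ``latitude``/``longitude`` (the latter mapped
    to the nearest land deme of ``world``, which must carry a georeference).
    Returns (codes array, metadata frame with deme_row/deme_col resolved).
    """
    import pandas as pd
    from Bio import SeqIO

    from .stats import _as_codes

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ConfigurationError(f"{fasta_path}: no sequences found")
    meta = pd.read_csv(metadata_path, sep="\t")
    required = {"id", "sample_label", "age"}
    if not required <= set(meta.columns):
        raise ConfigurationError(
            f"{metadata_path}: metadata needs columns {sorted(required)}"
        )
    meta = meta.set_index("id", drop=False)
    missing = [r.id for r in records if r.id not in meta.index]
    if missing:
        raise ConfigurationError(f"sequence ids absent from metadata: {missing}")
    meta = meta.loc[[r.id for r in records]].reset_index(drop=True)

    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ConfigurationError("sequences must all have the same length")
    codes = _as_codes([str(r.seq) for r in records])

    if {"deme_row", "deme_col"} <= set(meta.columns):
        pass
    elif {"latitude", "longitude"} <= set(meta.columns):
        if world is None or world.geo is None:
            raise ConfigurationError(
                "latitude/longitude metadata needs a georeferenced world"
            )
        lat0, lon0, cell_km = world.geo
        rows, cols = [], []
        for lat, lon in zip(meta["latitude"], meta["longitude"]):
            # equirectangular approximation around the raster's reference cell
            row = int(round((lat0 - lat) * 111.32 / cell_km))
            col = int(
                round((lon - lon0) * 111.32 * np.cos(np.radians(lat)) / cell_km)
            )
            r, c = world.nearest_land_deme(row, col, max_cells=1)
            rows.append(r)
            cols.append(c)
        meta["deme_row"] = rows
        meta["deme_col"] = cols
    else:
        raise ConfigurationError(
            "metadata needs deme_row/deme_col or latitude/longitude columns"
        )
    if world is not None:
        for r, c in zip(meta["deme_row"], meta["deme_col"]):
            if not world.is_land(int(r), int(c)):
                raise ConfigurationError(f"metadata deme ({r}, {c}) is not land")
    return codes, meta
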