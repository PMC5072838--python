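"""Run configuration, table I/O and provenance headers.

Configuration is a JSON document validated against a strict schema (unknown
keys are rejected, defaults mirror the experimental cycle: 11.5 h growth,
30 min capillary, 2048-fold dilution, 150 cycles).  Tables are UTF-8 TSV
with ``#``-prefixed comment/provenance lines, ``.`` decimal separator and
empty fields for missing values; the writer emits a deterministic column
order so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from chemoscape.competition import CompetitionParams
from chemoscape.landscape import LandscapeGrid
from chemoscape.simulator import (
    CyclePlan,
    Genotype,
    MutationModel,
    SimulationConfig,
    TradeoffModel,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "SchemaError",
    "load_config",
    "save_config",
    "read_table",
    "write_table",
]


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


class SchemaError(ValueError):
    """A table is missing required columns."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    c_min: float = -1.0
    c_max: float = 8.0
    c_step: float = 0.2
    r_min: float = -0.2
    r_max: float = 0.3
    r_step: float = 0.025

    def to_grid(self) -> LandscapeGrid:
        return LandscapeGrid(**self.model_dump())


class IntegratorConfig(_Strict):
    rtol: float = 1e-8
    atol: float = 1e-12


class ModelConfig(_Strict):
    """Competition-model block: baseline strains and cycle timing."""

    r_w: float = 1.0
    m0: float = 1.0 / 4000.0
    w0: float = 1.0 / 4000.0
    k: float = 1.0
    t_growth: float = 11.5
    capillary_hours: float = 0.5
    convention: str = "gradient"
    normalization_hours: float | None = None
    grid: GridConfig = GridConfig()
    integrator: IntegratorConfig = IntegratorConfig()

    def baseline(self) -> CompetitionParams:
        return CompetitionParams(
            r_m=self.r_w,
            r_w=self.r_w,
            m0=self.m0,
            w0=self.w0,
            k=self.k,
            t_growth=self.t_growth,
        )


class MutationConfig(_Strict):
    rate_per_cycle: float = 1.0
    step_sd: float = 0.5
    free_step_sd: float = 0.9
    p_plasticity: float = 0.1
    r_step_sd: float = 0.0


class TradeoffConfig(_Strict):
    gamma: float = 0.25
    c_max: float = 2.4
    c_free_max: float = 2.7


class SimulatorConfig(_Strict):
    """Simulator block: cycle plan, trade-off, mutation and sampling."""

    t_growth: float = 11.5
    capillary_hours: float = 0.5
    dilution_factor: float = 2048.0
    cycles_total: int = 150
    cycles_per_week: int = 14
    census: float | None = 1e5
    convention: str = "gradient"
    isolates_per_week: int = 6
    noise_r: float = 0.01
    noise_c: float = 0.15
    tradeoff: TradeoffConfig = TradeoffConfig()
    mutation: MutationConfig = MutationConfig()

    def to_simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            plan=CyclePlan(
                t_growth=self.t_growth,
                capillary_hours=self.capillary_hours,
                dilution_factor=self.dilution_factor,
                cycles_total=self.cycles_total,
                cycles_per_week=self.cycles_per_week,
            ),
            tradeoff=TradeoffModel(**self.tradeoff.model_dump()),
            mutation=MutationModel(**self.mutation.model_dump()),
            ancestor=Genotype(),
            census=self.census,
            convention=self.convention,
            isolates_per_week=self.isolates_per_week,
            noise_r=self.noise_r,
            noise_c=self.noise_c,
        )


class SyntheticConfig(_Strict):
    """Synthetic-data block: noise magnitudes and panel layout."""

    growth_n0: float = 1000.0
    capillary_depth: int = 5000
    speeds_n_cells: int = 400
    panel_weeks: int = 11
    panel_isolates_per_week: int = 6
    panel_noise_sd_r: float = 0.005
    panel_noise_sd_c: float = 0.3


class RunConfig(_Strict):
    """Top-level run configuration (all keys optional, schema-validated)."""

    model: ModelConfig = ModelConfig()
    simulator: SimulatorConfig = SimulatorConfig()
    synthetic: SyntheticConfig = SyntheticConfig()
    outdir: str = "results"
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration.

    An empty (or whitespace-only) file yields all defaults.  Unknown keys
    raise :class:`ConfigError` naming the offending key.
    """
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        data = {}
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        keys = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid configuration at: {keys}") from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration as JSON; round-trips through load_config."""
    Path(path).write_text(
        json.dumps(config.model_dump(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_table(
    path: str | Path, required_columns: tuple[str, ...] | list[str] = ()
) -> pd.DataFrame:
    """Read a TSV table, skipping '#' comment lines, and check its schema.

    Column names (not order) must cover ``required_columns``.  An empty data
    section returns an empty frame with the header's columns.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing columns {missing}; found {list(df.columns)}"
        )
    return df


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    provenance: str | None = None,
    columns: tuple[str, ...] | list[str] | None = None,
) -> None:
    """Write a TSV table with an optional '# generator:' provenance header.

    Column order is taken from ``columns`` when given, else sorted, so output
    is deterministic regardless of frame construction order.
    """
    path = Path(path)
    cols = list(columns) if columns is not None else sorted(df.columns)
    out = df.loc[:, cols]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if provenance:
            fh.write(f"# generator: {provenance}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="")
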