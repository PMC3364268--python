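"""Environmental summaries, run configuration and report rendering."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .hydrology import PulseWindow
from .subsidy import SubsidyEstimate

logger = logging.getLogger(__name__)

__all__ = [
    "ENV_VARIABLES",
    "EnvSummary",
    "RunConfig",
    "load_config",
    "summarize_environment",
    "env_summary_frame",
    "render_report",
]

#: sample-table column -> display name and unit
ENV_VARIABLES = {
    "salinity_psu": ("Salinity", "psu"),
    "do_ppm": ("Dissolved Oxygen", "ppm"),
    "temp_c": ("Water Temperature", "°C"),
    "turbidity_ntu": ("Turbidity", "NTU"),
}


@dataclass(frozen=True)
class EnvSummary:
    pulse_id: str
    variable: str
    mean: float
    se: float
    min: float
    max: float
    n: int

    def __post_init__(self) -> None:
        # tolerance absorbs float roundoff when all values are identical
        if not (self.min - 1e-9 <= self.mean <= self.max + 1e-9):
            raise ValueError("mean outside [min, max]")

    def render(self) -> str:
        """``mean±SE (min−max)`` at the report's precision."""
        return (f"{self.mean:.1f}±{self.se:.2f} "
                f"({self.min:.1f}−{self.max:.1f})")


@dataclass
class RunConfig:
    """Everything one end-to-end run needs, loadable from a YAML file."""

    seed: int = 0
    alpha: float = 0.05
    error_rule: str = "quadrature"
    included_species: Optional[List[str]] = None
    datum_offsets: Dict[str, float] = field(default_factory=dict)
    out_dir: str = "marshpulse_out"
    pulse_windows: Optional[List[Dict[str, str]]] = None
    hydro: Dict[str, object] = field(default_factory=dict)
    community: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        return {
            "seed": self.seed, "alpha": self.alpha,
            "error_rule": self.error_rule,
            "included_species": self.included_species,
            "datum_offsets": dict(self.datum_offsets),
            "out_dir": self.out_dir,
            "pulse_windows": self.pulse_windows,
            "hydro": dict(self.hydro), "community": dict(self.community),
        }

    def windows(self) -> Optional[List[PulseWindow]]:
        if self.pulse_windows is None:
            return None
        return [PulseWindow(w["pulse_id"], pd.Timestamp(w["start"]),
                            pd.Timestamp(w["end"]))
                for w in self.pulse_windows]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def summarize_environment(samples: pd.DataFrame,
                          pulse: PulseWindow) -> List[EnvSummary]:
    """Mean, SE and range of each environmental variable in one pulse."""
    sub = samples[samples["pulse_id"] == pulse.pulse_id]
    if len(sub) == 0:
        raise ValueError(f"no samples in pulse {pulse.pulse_id}")
    out = []
    for col in ENV_VARIABLES:
        vals = sub[col].to_numpy(dtype=float)
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 \
            else 0.0
        out.append(EnvSummary(pulse.pulse_id, col, float(vals.mean()), se,
                              float(vals.min()), float(vals.max()),
                              len(vals)))
    return out


def env_summary_frame(summaries: Sequence[EnvSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pulse_id": s.pulse_id, "variable": s.variable, "mean": s.mean,
        "se": s.se, "min": s.min, "max": s.max, "n": s.n,
    } for s in summaries])


def _fmt(x: Optional[float], nd: int = 1) -> str:
    return "–" if x is None else f"{x:.{nd}f}"


def render_report(
    *,
    config: Mapping[str, object],
    seed: int,
    config_digest: str,
    env_summaries: Sequence[EnvSummary],
    flooded: Mapping[str, Mapping[str, float]],
    subsidized_counts: Mapping[str, tuple],
    species_stock: pd.DataFrame,
    estimates: Sequence[SubsidyEstimate],
    record_counts: Mapping[str, int],
) -> str:
    """Render the run's results as one deterministic markdown document.

    ``flooded`` maps pulse -> {area: percent}; ``subsidized_counts`` maps
    pulse -> (n_subsidized, n_total); ``species_stock`` has per-pulse
    per-species mean/SE density and energy columns.
    """
    lines: List[str] = []
    lines.append("# marshpulse run report")
    lines.append("")
    lines.append(f"- seed: {seed}")
    lines.append(f"- config hash: {config_digest}")
    for stage, n in record_counts.items():
        lines.append(f"- {stage}: {n} records")
    lines.append("")

    lines.append("## Hydrology")
    lines.append("")
    lines.append("| Pulse | Inflow flooded (%) | Reference flooded (%) | "
                 "Subsidized samples |")
    lines.append("|---|---|---|---|")
    for pulse, areas in flooded.items():
        n_sub, n_tot = subsidized_counts.get(pulse, (0, 0))
        pct = 100.0 * n_sub / n_tot if n_tot else 0.0
        lines.append(f"| {pulse} | {areas.get('inflow', float('nan')):.0f} | "
                     f"{areas.get('reference', float('nan')):.0f} | "
                     f"{pct:.0f}% (n = {n_sub}/{n_tot}) |")
    lines.append("")

    lines.append("## Environmental characteristics (per pulse)")
    lines.append("")
    lines.append("| Pulse | Variable | mean±SE (range) | n |")
    lines.append("|---|---|---|---|")
    for s in env_summaries:
        name, unit = ENV_VARIABLES[s.variable]
        lines.append(f"| {s.pulse_id} | {name} ({unit}) | {s.render()} "
                     f"| {s.n} |")
    lines.append("")

    lines.append("## Standing stock by species (per pulse)")
    lines.append("")
    if len(species_stock):
        lines.append("| Pulse | Species | Density (ind m⁻²) | "
                     "Energy (cal m⁻²) |")
        lines.append("|---|---|---|---|")
        for r in species_stock.itertuples(index=False):
            lines.append(
                f"| {r.pulse_id} | {r.species} | "
                f"{r.density_mean:.1f}±{r.density_se:.1f} | "
                f"{r.energy_mean:.1f}±{r.energy_se:.1f} |")
    else:
        lines.append("(no catch records)")
    lines.append("")

    lines.append("## Subsidy estimates")
    lines.append("")
    lines.append("| Metric | Inflow mean (SE) | Subsidized % (SE) | "
                 "Subsidy (SE) |")
    lines.append("|---|---|---|---|")
    for e in estimates:
        lines.append(
            f"| {e.metric} | {_fmt(e.inflow_mean)} ({_fmt(e.inflow_se)}) | "
            f"{_fmt(e.proportion_pct)} ({_fmt(e.proportion_se)}) | "
            f"{_fmt(e.subsidy)} ({_fmt(e.subsidy_se)}) |")
    lines.append("")

    lines.append("## Configuration")
    lines.append("")
    lines.append("```yaml")
    lines.append(yaml.safe_dump(dict(config), sort_keys=True).rstrip())
    lines.append("```")
    lines.append("")
    return "\n".join(lines)
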