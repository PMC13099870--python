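"""Orchestration of the 3 x 3 x 3 simulation grid.

Three model families (Ising {0,1}, Ising {-1,1}, GVAR) are crossed with three
threshold/mean conditions and three connectivity multipliers, giving 27
landscape cells. Each cell is evaluated for every seed in the configuration;
stable-state counts are summarised by their mode across seeds and minima
locations by their median, and each model family is classified against the
network theory's two predictions.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gvar as gvar_mod
from .ising import active_count_distribution, exact_distribution
from .landscape import (AxisKind, Landscape, StableStateReport,
                        TheoryClassification, classify_model, classify_sweep,
                        find_stable_states, to_landscape)
from .networks import (GridCondition, ModelKind, TauTransform, apply_condition,
                       gen_gvar_baseline, gen_ising_baseline, gvar_connectivity,
                       ising_connectivity)
from .params import Encoding

log = logging.getLogger("netlandscape.grid")


@dataclass(frozen=True)
class GridConfig:
    """Configuration of the full simulation grid (defaults = the study design).

    The defaults reproduce exactly 3 models x 3 conditions x 3 multipliers:
    Ising multipliers {0.9, 1, 2} with mean thresholds {-7, -3.5, 3.5}
    ({0,1} encoding, derived from the baseline by x2 and x-1) and
    {-0.5, -0.2, 0.8} ({-1,1} encoding, generated at the stated means);
    GVAR multipliers {0.5, 1, 1.2} with stationary means mu in {0, 3, 6}.
    """

    seeds: tuple[int, ...] = tuple(range(20))
    n_nodes: int = 9
    models: tuple[ModelKind, ...] = (ModelKind.ISING_01, ModelKind.ISING_PM1,
                                     ModelKind.GVAR)
    ising01_mean_tau: float = -3.5
    ising01_mean_weight: float = 0.5
    pm1_mean_weight: float = 0.14
    pm1_condition_means: tuple[float, ...] = (-0.5, -0.2, 0.8)
    pm1_baseline_mean_tau: float = -0.2
    heterogeneity: float = 1.0
    ising_multipliers: tuple[float, ...] = (0.9, 1.0, 2.0)
    gvar_multipliers: tuple[float, ...] = (0.5, 1.0, 1.2)
    gvar_mu_values: tuple[float, ...] = (0.0, 3.0, 6.0)
    gvar_method: str = "analytic"  # "analytic" | "simulate"
    gvar_sim_T: int = 20000
    gvar_sim_burn_in: int = 1000
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("need at least one seed")
        if self.gvar_method not in ("analytic", "simulate"):
            raise ValueError("gvar_method must be 'analytic' or 'simulate'")
        object.__setattr__(self, "models",
                           tuple(ModelKind(m) for m in self.models))
        object.__setattr__(self, "seeds", tuple(int(s) for s in self.seeds))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GridConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("seeds", "models", "pm1_condition_means", "ising_multipliers",
                    "gvar_multipliers", "gvar_mu_values"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def conditions(self, model: ModelKind) -> list[GridCondition]:
        """Threshold/mean x multiplier conditions for one model family."""
        out: list[GridCondition] = []
        if model is ModelKind.ISING_01:
            base = self.ising01_mean_tau
            specs = [(f"tau={base:g}", TauTransform.IDENTITY, 1.0),
                     (f"tau={2 * base:g}", TauTransform.SCALE, 2.0),
                     (f"tau={-base:g}", TauTransform.SCALE, -1.0)]
            for label, tr, factor in specs:
                for m in self.ising_multipliers:
                    out.append(GridCondition(model=model, label=label,
                                             multiplier=m, tau_transform=tr,
                                             tau_factor=factor))
        elif model is ModelKind.ISING_PM1:
            for mean in self.pm1_condition_means:
                label = f"tau={mean:g}"
                if mean == self.pm1_baseline_mean_tau:
                    tr, target = TauTransform.IDENTITY, None
                else:
                    tr, target = TauTransform.RECENTER, mean
                for m in self.ising_multipliers:
                    out.append(GridCondition(model=model, label=label,
                                             multiplier=m, tau_transform=tr,
                                             target_mean=target))
        else:
            for mu in self.gvar_mu_values:
                for m in self.gvar_multipliers:
                    out.append(GridCondition(model=model, label=f"mu={mu:g}",
                                             multiplier=m, target_mean=mu))
        return out

    def condition_labels(self, model: ModelKind) -> list[str]:
        seen: list[str] = []
        for c in self.conditions(model):
            if c.label not in seen:
                seen.append(c.label)
        return seen

    def theory_condition_labels(self, model: ModelKind) -> list[str]:
        """Conditions consistent with the network theory (negative thresholds)."""
        if model is ModelKind.GVAR:
            return self.condition_labels(model)
        if model is ModelKind.ISING_01:
            means = {f"tau={self.ising01_mean_tau:g}": self.ising01_mean_tau,
                     f"tau={2 * self.ising01_mean_tau:g}": 2 * self.ising01_mean_tau,
                     f"tau={-self.ising01_mean_tau:g}": -self.ising01_mean_tau}
        else:
            means = {f"tau={m:g}": m for m in self.pm1_condition_means}
        return [label for label, m in means.items() if m < 0]


@dataclass(frozen=True)
class CellResult:
    """One grid cell: landscapes/reports for every seed plus their summary."""

    model: ModelKind
    condition: str
    multiplier: float
    reports: dict[int, StableStateReport]           # keyed by seed
    connectivity: dict[int, float]                  # keyed by seed
    landscape: Landscape                            # representative seed
    representative_seed: int
    modal_n_stable: int
    median_minima: tuple[float, ...]

    @property
    def key(self) -> tuple[str, str, float]:
        return (self.model.value, self.condition, self.multiplier)

    def summary_dict(self) -> dict:
        return {
            "model": self.model.value,
            "condition": self.condition,
            "multiplier": self.multiplier,
            "modal_n_stable": self.modal_n_stable,
            "median_minima": list(self.median_minima),
            "representative_seed": self.representative_seed,
            "connectivity": self.connectivity,
            "per_seed": {str(s): r.to_dict() for s, r in self.reports.items()},
        }


@dataclass(frozen=True)
class GridResult:
    """All cells of a grid run plus per-model theory classifications."""

    config: GridConfig
    cells: dict[tuple[str, str, float], CellResult]
    classifications: dict[str, TheoryClassification]
    classification_tallies: dict[str, dict[str, int]]
    failures: list[dict] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _summarise_cell(model: ModelKind, condition: str, multiplier: float,
                    reports: dict[int, StableStateReport],
                    landscapes: dict[int, Landscape],
                    connectivity: dict[int, float]) -> CellResult:
    counts = Counter(r.n_stable for r in reports.values())
    modal = min(sorted(counts, key=lambda c: (-counts[c], c))[:1])
    modal_seeds = [s for s, r in reports.items() if r.n_stable == modal]
    locs = np.array([[m[0] for m in reports[s].minima] for s in modal_seeds])
    median_minima = tuple(float(v) for v in np.median(locs, axis=0))
    rep = modal_seeds[0]
    return CellResult(model=model, condition=condition, multiplier=multiplier,
                      reports=reports, connectivity=connectivity,
                      landscape=landscapes[rep], representative_seed=rep,
                      modal_n_stable=modal, median_minima=median_minima)


def ising_cell(params, condition: GridCondition) -> tuple[Landscape, float]:
    """Landscape over the active-count axis for one Ising parameterisation."""
    applied = apply_condition(params, condition)
    acd = active_count_distribution(exact_distribution(applied))
    ls = to_landscape(acd.counts, acd.probabilities, AxisKind.ACTIVE_COUNT,
                      meta={"model": condition.model.value,
                            "condition": condition.label,
                            "multiplier": condition.multiplier})
    return ls, ising_connectivity(applied.omega)


def gvar_cell(params, condition: GridCondition, method: str = "analytic",
              sim_T: int = 20000, burn_in: int = 1000,
              seed: int = 0) -> tuple[Landscape, float]:
    """Landscape over the sum-score axis for one GVAR parameterisation."""
    applied = apply_condition(params, condition)
    moments = gvar_mod.stationary_moments(applied)
    grid = gvar_mod.default_sum_grid(moments)
    if method == "analytic":
        density = gvar_mod.sum_score_density(moments, grid)
    elif method == "simulate":
        series = gvar_mod.simulate(applied, sim_T, burn_in=burn_in, seed=seed)
        density = gvar_mod.kde_sum_density(series, grid)
    else:
        raise ValueError(f"unknown GVAR landscape method {method!r}")
    ls = to_landscape(grid, density, AxisKind.SUM_SCORE,
                      meta={"model": "gvar", "condition": condition.label,
                            "multiplier": condition.multiplier,
                            "method": method,
                            "sum_mean": moments.sum_mean,
                            "sum_variance": moments.sum_variance})
    return ls, gvar_connectivity(applied.beta)


def _baseline(config: GridConfig, model: ModelKind, seed: int):
    if model is ModelKind.ISING_01:
        return gen_ising_baseline(config.n_nodes, Encoding.ZERO_ONE,
                                  config.ising01_mean_tau,
                                  config.ising01_mean_weight,
                                  config.heterogeneity, seed)
    if model is ModelKind.ISING_PM1:
        return gen_ising_baseline(config.n_nodes, Encoding.MINUS_PLUS,
                                  config.pm1_baseline_mean_tau,
                                  config.pm1_mean_weight,
                                  config.heterogeneity, seed)
    return gen_gvar_baseline(config.n_nodes, seed,
                             max_multiplier=max(config.gvar_multipliers))


def run_grid(config: GridConfig | None = None) -> GridResult:
    """Run every cell of the grid for every seed and classify each model.

    Cell failures are recorded and the run continues; callers (the CLI)
    translate a non-empty failure list into a nonzero exit status.
    """
    config = config or GridConfig()
    cells: dict[tuple[str, str, float], CellResult] = {}
    failures: list[dict] = []
    classifications: dict[str, TheoryClassification] = {}
    tallies: dict[str, dict[str, int]] = {}

    for model in config.models:
        baselines = {s: _baseline(config, model, s) for s in config.seeds}
        # per seed, per condition label, per multiplier -> report
        seed_reports: dict[int, dict[str, dict[float, StableStateReport]]] = {
            s: {} for s in config.seeds}
        by_cell: dict[tuple[str, float], dict[int, StableStateReport]] = {}
        ls_by_cell: dict[tuple[str, float], dict[int, Landscape]] = {}
        conn_by_cell: dict[tuple[str, float], dict[int, float]] = {}

        for condition in config.conditions(model):
            key = (condition.label, condition.multiplier)
            by_cell.setdefault(key, {})
            ls_by_cell.setdefault(key, {})
            conn_by_cell.setdefault(key, {})
            for seed in config.seeds:
                try:
                    if model is ModelKind.GVAR:
                        ls, conn = gvar_cell(baselines[seed], condition,
                                             method=config.gvar_method,
                                             sim_T=config.gvar_sim_T,
                                             burn_in=config.gvar_sim_burn_in,
                                             seed=seed)
                    else:
                        ls, conn = ising_cell(baselines[seed], condition)
                    report = find_stable_states(ls)
                except Exception as exc:  # record and continue
                    failures.append({"model": model.value,
                                     "condition": condition.label,
                                     "multiplier": condition.multiplier,
                                     "seed": seed, "error": str(exc)})
                    continue
                by_cell[key][seed] = report
                ls_by_cell[key][seed] = ls
                conn_by_cell[key][seed] = conn
                seed_reports[seed].setdefault(condition.label, {})[
                    condition.multiplier] = report

        for (label, mult), reports in by_cell.items():
            if not reports:
                continue
            cell = _summarise_cell(model, label, mult, reports,
                                   ls_by_cell[(label, mult)],
                                   conn_by_cell[(label, mult)])
            cells[cell.key] = cell
            log.info("cell model=%s condition=%s multiplier=%g n_stable=%d "
                     "minima=%s connectivity=%.4f", model.value, label, mult,
                     cell.modal_n_stable, list(cell.median_minima),
                     cell.connectivity[cell.representative_seed])

        theory = config.theory_condition_labels(model)
        per_seed_class: list[TheoryClassification] = []
        for seed in config.seeds:
            sweeps = {label: classify_sweep(mults)
                      for label, mults in seed_reports[seed].items()
                      if len(mults) == len(config.ising_multipliers
                                           if model is not ModelKind.GVAR
                                           else config.gvar_multipliers)}
            if all(t in sweeps for t in theory):
                per_seed_class.append(classify_model(sweeps, theory))
        if per_seed_class:
            pairs = Counter((c.prediction1_severity, c.prediction2_discontinuity)
                            for c in per_seed_class)
            modal_pair = pairs.most_common(1)[0][0]
            rep = next(c for c in per_seed_class
                       if (c.prediction1_severity,
                           c.prediction2_discontinuity) == modal_pair)
            classifications[model.value] = rep
            tallies[model.value] = {f"{p1.value}/{p2.value}": k
                                    for (p1, p2), k in pairs.items()}

    result = GridResult(config=config, cells=cells,
                        classifications=classifications,
                        classification_tallies=tallies, failures=failures)
    if config.out_dir is not None:
        write_grid_result(result, config.out_dir)
    return result


def summarize_table2(result: GridResult) -> pd.DataFrame:
    """Per-model yes/partial/no table for the theory's two predictions.

    Raises if the grid is incomplete (missing cells or classifications),
    listing what is missing.
    """
    config = result.config
    missing: list[str] = []
    for model in config.models:
        for c in config.conditions(model):
            if (model.value, c.label, c.multiplier) not in result.cells:
                missing.append(f"{model.value}/{c.label}/x{c.multiplier:g}")
        if model.value not in result.classifications:
            missing.append(f"classification:{model.value}")
    if missing:
        raise ValueError(f"incomplete grid, missing cells: {missing}")
    rows = {"severity (healthy destabilises, unhealthy deepens)":
            {m.value: result.classifications[m.value].prediction1_severity.value
             for m in config.models},
            "discontinuity (tipping point appears)":
            {m.value: result.classifications[m.value].prediction2_discontinuity.value
             for m in config.models}}
    return pd.DataFrame(rows).T


def landscape_frame(ls: Landscape) -> pd.DataFrame:
    return pd.DataFrame({"axis_kind": AxisKind(ls.axis_kind).value,
                         "grid_value": ls.grid,
                         "probability": ls.probability,
                         "potential": ls.potential})


def write_grid_result(result: GridResult, out_dir: str | Path) -> Path:
    """Write landscapes (CSV), reports and classifications (JSON) + manifest."""
    out = Path(out_dir)
    (out / "landscapes").mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seeds": list(result.config.seeds),
                      "calibration": {
                          "ising01_mean_tau": result.config.ising01_mean_tau,
                          "ising01_mean_weight": result.config.ising01_mean_weight,
                          "pm1_baseline_mean_tau": result.config.pm1_baseline_mean_tau,
                          "pm1_mean_weight": result.config.pm1_mean_weight,
                          "heterogeneity": result.config.heterogeneity},
                      "files": [], "failures": result.failures}
    for cell in result.cells.values():
        stem = f"{cell.model.value}_{cell.condition}_x{cell.multiplier:g}".replace(
            "=", "").replace(" ", "")
        ls_path = out / "landscapes" / f"{stem}.csv"
        landscape_frame(cell.landscape).to_csv(ls_path, index=False)
        rep_path = out / "reports" / f"{stem}.json"
        rep_path.write_text(json.dumps(cell.summary_dict(), indent=1))
        manifest["files"].append({
            "landscape": str(ls_path.relative_to(out)),
            "report": str(rep_path.relative_to(out)),
            "model": cell.model.value, "condition": cell.condition,
            "multiplier": cell.multiplier,
            "seed": cell.representative_seed,
            "connectivity": cell.connectivity[cell.representative_seed],
            "modal_n_stable": cell.modal_n_stable})
    (out / "classification.json").write_text(json.dumps(
        {m: c.to_dict() for m, c in result.classifications.items()} |
        {"tallies": result.classification_tallies}, indent=1))
    try:
        table = summarize_table2(result)
        table.to_csv(out / "table2.csv")
    except ValueError:
        pass  # incomplete grids still get their manifest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
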