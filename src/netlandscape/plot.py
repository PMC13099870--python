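"""Panel plots of stability landscapes (3 conditions x 3 multipliers)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .grid import GridResult  # noqa: E402
from .networks import ModelKind  # noqa: E402


def plot_model_panels(result: GridResult, model: ModelKind | str):
    """One figure per model: conditions as columns, multipliers as rows."""
    model = ModelKind(model)
    config = result.config
    conditions = config.condition_labels(model)
    mults = (config.gvar_multipliers if model is ModelKind.GVAR
             else config.ising_multipliers)
    fig, axes = plt.subplots(len(mults), len(conditions),
                             figsize=(3.2 * len(conditions), 2.4 * len(mults)),
                             squeeze=False)
    for i, m in enumerate(mults):
        for j, cond in enumerate(conditions):
            ax = axes[i][j]
            cell = result.cells.get((model.value, cond, m))
            if cell is None:
                ax.set_axis_off()
                continue
            ls = cell.landscape
            ax.plot(ls.grid, ls.potential, lw=1.5)
            for loc, pot in find_minima(cell):
                ax.plot([loc], [pot], "v", color="tab:red", ms=5)
            if i == 0:
                ax.set_title(cond, fontsize=9)
            if j == 0:
                ax.set_ylabel(f"U  (x{m:g})", fontsize=9)
    x_label = ("sum score" if model is ModelKind.GVAR else "number of active symptoms")
    for ax in axes[-1]:
        ax.set_xlabel(x_label, fontsize=9)
    fig.suptitle(model.value)
    fig.tight_layout()
    return fig


def find_minima(cell):
    rep = cell.reports[cell.representative_seed]
    return rep.minima


def save_all_panels(result: GridResult, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for model in result.config.models:
        fig = plot_model_panels(result, model)
        p = out / f"panels_{ModelKind(model).value}.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    return paths
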