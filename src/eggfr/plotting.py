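"""Basic diagnostic plot: expected vs observed parasitism by female age.

Requires matplotlib (optional dependency)."""

from __future__ import annotations

import numpy as np

from .eggmodels import EggParams
from .frmodels import FRParams
from .lifetime import ExperimentDataset, ModelSpec, expected_trajectory


def plot_expected_vs_observed(
    dataset: ExperimentDataset,
    model: ModelSpec,
    frp: FRParams,
    eggp: EggParams,
    day: int = 1,
    ax=None,
    n_grid: int = 120,
):
    """Scatter observed daily counts at age ``day`` against host density,
    with the model's expected-parasitism curve for that age overlaid.

    The expected curve propagates the deterministic mean trajectory
    assuming the female was held at each density on all previous days.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    obs = dataset.df[dataset.df.day == day]
    ax.scatter(obs.n_offered, obs.n_parasitized, color="k", s=18, zorder=3,
               label="observed")
    grid = np.linspace(1, max(1, int(dataset.df.n_offered.max() * 1.1)), n_grid)
    curve = [expected_trajectory(model, frp, eggp, [n] * day)[0][day - 1]
             for n in grid]
    ax.plot(grid, curve, lw=2, label=f"{model.name} expected")
    ax.set_xlabel("hosts offered per day")
    ax.set_ylabel("hosts parasitized")
    ax.set_title(f"day {day}")
    ax.legend(frameon=False)
    return ax
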