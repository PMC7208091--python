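"""Data tables behind the model's six standard illustrations.

The tested artifact is the table, not the rendered plot; ``plot_figure`` is a
thin convenience layer on matplotlib.  Figures 1-4 carry fully specified
parameter sets; figures 5 and 6 do not, so they require explicit overrides.

1. E(P) against the pollen number M           (R=5000, r_m=1, w=1, h=1000)
2. E(F*) with its SD band and E(P) against alpha / F
                                              (R=5000, r_f=10, r_m=1, w=1, h=1000)
3. the same curves for declined budgets qR, q in {1, .8, .6, .4, .2}
4. feasibility of compensation by re-allocation against the prior alpha
                                              (R=5000, r_f=10, r_m=1, w=1, h=10000)
5. retention / range compensation sweeps at one q       (overrides required)
6. (w, h) feasibility map of the two density strategies (overrides required)
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .compensate import (
    DeclineScenario,
    compensable_by_allocation,
    compensate_range,
    compensate_retention,
    compensation_map,
)
from .core import expected_fertilized, expected_proportion
from .params import DispersalParams, ReproductionParams, ResourceBudget

__all__ = ["FIGURE_PARAMS", "run_figure_table", "plot_figure"]

FIGURE_PARAMS: dict[int, dict[str, float]] = {
    1: {"R": 5000, "r_m": 1, "w": 1, "h": 1000},
    2: {"R": 5000, "r_f": 10, "r_m": 1, "w": 1, "h": 1000},
    3: {"R": 5000, "r_f": 10, "r_m": 1, "w": 1, "h": 1000},
    4: {"R": 5000, "r_f": 10, "r_m": 1, "w": 1, "h": 10000},
}
_REQUIRED_OVERRIDES = {5: ("R", "r_f", "r_m", "alpha", "w", "h", "q"),
                       6: ("R", "r_f", "r_m", "alpha", "q")}


def _alpha_grid(n: int = 999) -> np.ndarray:
    return np.linspace(0.001, 0.999, n)


def _curve(params: dict[str, float], q: float, alphas: np.ndarray) -> pd.DataFrame:
    disp = DispersalParams(h=params["h"], w=params["w"])
    rows = []
    for a in alphas:
        p = ReproductionParams(q * params["R"], params["r_f"], params["r_m"], a)
        st = expected_fertilized(p, disp)
        rows.append(
            {
                "q": q,
                "alpha": a,
                "F": st.F,
                "M": st.M,
                "E_P": st.E_P,
                "E_Fstar": st.E_Fstar,
                "SD_Fstar": st.SD_Fstar if st.SD_Fstar is not None else math.nan,
            }
        )
    return pd.DataFrame(rows)


def run_figure_table(
    figure_id: int, overrides: Mapping[str, float] | None = None, n_points: int = 999
) -> pd.DataFrame:
    """Underlying data table of one of the six standard illustrations."""
    overrides = dict(overrides or {})
    if figure_id in _REQUIRED_OVERRIDES:
        missing = [k for k in _REQUIRED_OVERRIDES[figure_id] if k not in overrides]
        if missing:
            raise ValueError(
                f"figure {figure_id}: parameter set not fully printed in the "
                f"original illustration; supply overrides for {', '.join(missing)}"
            )
    if figure_id not in (1, 2, 3, 4, 5, 6):
        raise ValueError(f"figure_id must be 1..6, got {figure_id}")
    p = {**FIGURE_PARAMS.get(figure_id, {}), **overrides}

    if figure_id == 1:
        disp = DispersalParams(h=p["h"], w=p["w"])
        M = np.linspace(0.0, p["R"] / p["r_m"], n_points)
        return pd.DataFrame({"M": M, "E_P": [expected_proportion(m, disp) for m in M]})

    if figure_id == 2:
        return _curve(p, 1.0, _alpha_grid(n_points)).drop(columns="q")

    if figure_id == 3:
        qs = p.pop("q", None) or (1.0, 0.8, 0.6, 0.4, 0.2)
        qs = (qs,) if np.isscalar(qs) else tuple(qs)
        return pd.concat(
            [_curve(p, q, _alpha_grid(n_points)) for q in qs], ignore_index=True
        )

    if figure_id == 4:
        qs = p.pop("q", None) or (0.8, 0.6, 0.4)
        qs = (qs,) if np.isscalar(qs) else tuple(qs)
        disp = DispersalParams(h=p["h"], w=p["w"])
        alpha_max = min(0.999, p["h"] * p["r_f"] / p["R"])
        rows = []
        for q in qs:
            for a0 in np.linspace(0.001, alpha_max, n_points):
                scen = DeclineScenario(
                    q=q,
                    params=ReproductionParams(p["R"], p["r_f"], p["r_m"], a0),
                    disp=disp,
                )
                res = compensable_by_allocation(scen)
                a1, a2 = res.adjusted_value if res.feasible else (math.nan, math.nan)
                rows.append(
                    {
                        "q": q,
                        "alpha0": a0,
                        "baseline_E_Fstar": res.baseline_E_Fstar,
                        "feasible": res.feasible,
                        "alpha_1": a1,
                        "alpha_2": a2,
                    }
                )
        return pd.DataFrame(rows)

    if figure_id == 5:
        params = ReproductionParams(p["R"], p["r_f"], p["r_m"], p["alpha"])
        q = p["q"]
        rows = []
        for w in np.linspace(0.01, 1.0, n_points):  # left panel: vary w at fixed h
            scen = DeclineScenario(q=q, params=params, disp=DispersalParams(h=p["h"], w=w))
            r = compensate_retention(scen)
            rows.append(
                {"panel": "w", "w": w, "h": p["h"], "feasible": r.feasible,
                 "adjusted": r.adjusted_value if r.adjusted_value is not None else math.nan,
                 "reason": r.infeasibility_reason or ""}
            )
        F = params.alpha * params.R / params.r_f
        for h in np.linspace(max(F, 3.0), p["h"], n_points):  # right panel: vary h
            scen = DeclineScenario(q=q, params=params, disp=DispersalParams(h=h, w=p["w"]))
            r = compensate_range(scen)
            rows.append(
                {"panel": "h", "w": p["w"], "h": h, "feasible": r.feasible,
                 "adjusted": r.adjusted_value if r.adjusted_value is not None else math.nan,
                 "reason": r.infeasibility_reason or ""}
            )
        return pd.DataFrame(rows)

    # figure 6: (w, h) feasibility map
    params = ReproductionParams(p["R"], p["r_f"], p["r_m"], p["alpha"])
    F = params.alpha * params.R / params.r_f
    side = max(3, int(math.isqrt(n_points)))
    w_grid = np.linspace(0.02, 1.0, side)
    h_grid = np.linspace(max(F, 3.0), p.get("h_max", 10 * max(F, 100.0)), side)
    return compensation_map(params, w_grid, h_grid, p["q"])


def plot_figure(table: pd.DataFrame, figure_id: int, path: str) -> None:
    """Optional rendering of a figure table to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if figure_id == 1:
        ax.plot(table["M"], table["E_P"])
        ax.set(xlabel="M", ylabel="E(P)")
    elif figure_id == 2:
        ax.plot(table["alpha"], table["E_Fstar"], label="E(F*)")
        band = table["SD_Fstar"].to_numpy()
        ax.fill_between(
            table["alpha"],
            table["E_Fstar"] - band,
            table["E_Fstar"] + band,
            alpha=0.3,
        )
        ax.set(xlabel="alpha", ylabel="E(F*)")
    elif figure_id == 3:
        for q, sub in table.groupby("q"):
            ax.plot(sub["alpha"], sub["E_Fstar"], label=f"q={q:g}")
        ax.legend()
        ax.set(xlabel="alpha", ylabel="E(F*)")
    elif figure_id == 4:
        for q, sub in table.groupby("q"):
            ax.plot(sub["alpha0"], sub["feasible"].astype(int), label=f"q={q:g}")
        ax.legend()
        ax.set(xlabel="alpha before decline", ylabel="compensable (0/1)")
    elif figure_id == 5:
        for panel, sub in table.groupby("panel"):
            x = sub["w"] if panel == "w" else sub["h"]
            ax.plot(x, sub["feasible"].astype(int), label=f"vary {panel}")
        ax.legend()
        ax.set(ylabel="compensable (0/1)")
    else:
        piv = table.pivot_table(index="h", columns="w", values="range_feasible")
        ax.imshow(piv.to_numpy().astype(float), aspect="auto", origin="lower")
        ax.set(xlabel="w index", ylabel="h index", title="range-strategy feasibility")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
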