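"""Figures mirroring the study's reporting: rBias/rRMSE bar panels per
parameter group, and a loading-dose illustration."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pk_model import DoseEvent, PKParameters, Regimen, conc_profile
from .sse import BSV_PARAMS, RV_PARAM, THETA_PARAMS

__all__ = ["metric_panels", "loading_dose_demo", "PARAM_GROUPS"]

PARAM_GROUPS = {
    "structural": list(THETA_PARAMS),
    "bsv": list(BSV_PARAMS),
    "rv": [RV_PARAM],
}


def metric_panels(summary: pd.DataFrame, metric: str,
                  parameters: Sequence[str]) -> plt.Figure:
    """Grouped-bar panels of one metric: parameter columns x clearance rows,
    sample size on the x axis, one bar per dataset type."""
    if metric not in ("rbias", "rrmse"):
        raise ValueError("metric must be 'rbias' or 'rrmse'")
    cls = sorted(summary["CL_true"].unique())
    dtypes = sorted(summary["dataset_type"].unique())
    ns = sorted(summary["n_subjects"].unique())
    fig, axes = plt.subplots(len(cls), len(parameters), squeeze=False,
                             figsize=(3.0 * len(parameters), 2.6 * len(cls)),
                             sharey=True)
    width = 0.8 / len(dtypes)
    for i, cl in enumerate(cls):
        for j, param in enumerate(parameters):
            ax = axes[i][j]
            sub = summary[(summary["CL_true"] == cl)
                          & (summary["parameter"] == param)]
            for k, dt in enumerate(dtypes):
                vals = [sub[(sub["dataset_type"] == dt)
                            & (sub["n_subjects"] == n)][metric].mean()
                        for n in ns]
                ax.bar(np.arange(len(ns)) + k * width, vals, width, label=dt)
            ax.axhline(0.0, color="k", lw=0.5)
            ax.set_xticks(np.arange(len(ns)) + 0.4 - width / 2)
            ax.set_xticklabels([str(n) for n in ns])
            if i == len(cls) - 1:
                ax.set_xlabel("subjects")
            if j == 0:
                ax.set_ylabel(f"{metric} (%)  CL={cl:g} L/h")
            ax.set_title(param)
    axes[0][-1].legend(fontsize=8)
    fig.tight_layout()
    return fig


def loading_dose_demo(CL: float = 2.83, maintenance: float = 500.0,
                      interval: float = 12.0, duration: float = 1.0,
                      loading_doses: Sequence[float] = (500.0, 1000.0, 1500.0),
                      horizon: float = 72.0) -> plt.Figure:
    """Concentration-time curves for several loading-dose strategies
    followed by the same maintenance regimen (illustration only)."""
    params = PKParameters(CL=CL, V1=24.2, V2=32.3, Q=11.2)
    t = np.linspace(0.0, horizon, 400)
    fig, ax = plt.subplots(figsize=(6, 4))
    n_maint = int(horizon // interval)
    for load in loading_doses:
        doses = [DoseEvent(0.0, load, duration)]
        doses += [DoseEvent(k * interval, maintenance, duration)
                  for k in range(1, n_maint + 1)]
        c = conc_profile(params, Regimen(tuple(doses)), t)
        ax.plot(t, c, label=f"loading {load:g} mg")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (mg/L)")
    ax.legend()
    fig.tight_layout()
    return fig
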