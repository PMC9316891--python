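"""Plot helpers for diurnal sensitivity curves and the Cm-vs-SM_t plane."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np


def plot_smt_curves(curves: Sequence, ax=None, label_by: str = "scenario_id"):
    """Overlay SM_t curves against time of day."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for curve in curves:
        hours = np.arange(curve.steps_per_day) * 24.0 / curve.steps_per_day
        ax.plot(hours, curve.values, label=getattr(curve, label_by))
    ax.set_xlabel("time of day [h]")
    ax.set_ylabel(f"SM$_t$ [{curves[0].flux}]")
    ax.legend(fontsize="x-small")
    return ax


def plot_cm_smt(table, flux: str = "LE", block: str = "12:00-15:00", ax=None):
    """Scatter forcing complexity Cm against block-averaged SM_t per scenario."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    col = f"SMt_{flux}_{block}"
    sub = table.dropna(subset=["cm", col])
    for case, grp in sub.groupby("case"):
        marker = "*" if case == "full" else "o"
        ax.scatter(grp["cm"], grp[col], label=case, marker=marker)
    ax.set_xlabel("forcing complexity $C_m$")
    ax.set_ylabel(f"SM$_t$ {flux} {block}")
    ax.legend(fontsize="x-small")
    return ax
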