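"""Simple figure exports: tornado diagram and state-occupancy bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["tornado_plot", "occupancy_plot"]


def tornado_plot(tornado: pd.DataFrame, path: str | Path) -> None:
    """Horizontal bar chart of one-way QALY sensitivities.

    Expects the frame produced by
    :func:`gcsim.sensitivity.one_way_sensitivity` (tornado-ordered).
    """
    wide = tornado.pivot(index="parameter", columns="direction",
                         values="delta_qaly")
    order = wide.abs().max(axis=1).sort_values().index
    wide = wide.loc[order]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(wide) + 1.5))
    ax.barh(wide.index, wide.get("low", 0.0), color="#c44e52", label="-10%")
    ax.barh(wide.index, wide.get("high", 0.0), color="#4c72b0", label="+10%")
    ax.axvline(0.0, color="black", lw=0.8)
    ax.set_xlabel("change in expected QALYs")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def occupancy_plot(occupancy: pd.DataFrame, path: str | Path,
                   value: str = "ly") -> None:
    """Grouped bars of mean time per (state, treatment phase) by arm.

    Expects the frame from
    :meth:`gcsim.engine.ComparisonResult.occupancy_summary`.
    """
    df = occupancy[occupancy["state"] != "TOTAL"].copy()
    df["cell"] = df["state"] + "\n" + df["treatment"]
    wide = df.pivot(index="cell", columns="arm", values=value)
    fig, ax = plt.subplots(figsize=(9, 4))
    wide.plot.bar(ax=ax, rot=0)
    ax.set_ylabel("life-years" if value == "ly" else "QALYs")
    ax.set_xlabel("")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
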