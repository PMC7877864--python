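"""Summary-curve figures for simulated trial arms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt

__all__ = ["plot_arm_summaries"]

_UNITS = {"CRP": "mg/L", "FCP": "mg/kg"}


def plot_arm_summaries(results, marker: str = "CRP",
                       transform: str = "absolute", ax=None):
    """Median lines with IQR bands for one marker across arms.

    ``results`` is an iterable of :class:`~ibdqsp.trial.ArmResult`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for res in results:
        summary = res.summary(marker, "median_iqr", transform)
        ax.plot(summary.index, summary["median"], label=res.name)
        ax.fill_between(summary.index, summary["q25"], summary["q75"],
                        alpha=0.25)
    unit = _UNITS.get(marker, "pg/mL")
    ylabel = {"absolute": f"{marker} ({unit})",
              "change": f"{marker} change ({unit})",
              "percent_change": f"{marker} change from baseline (%)"}[transform]
    ax.set_xlabel("time (days)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    return ax
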