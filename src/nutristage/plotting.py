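"""Prevalence-trajectory figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .core import AGE_GROUP_LABELS, CATEGORY_LABELS
from .simulate import ProjectionResult

__all__ = ["plot_prevalence_trajectories"]


def plot_prevalence_trajectories(
    result: ProjectionResult,
    category: str = "overweight",
    age_groups=None,
    ax=None,
):
    """Plot each age group's prevalence of ``category`` against time.

    Returns the matplotlib axes; call ``figure.savefig`` to persist.
    """
    if category not in CATEGORY_LABELS:
        raise ValueError(f"unknown category {category!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    groups = list(age_groups) if age_groups is not None else list(range(12))
    years = result.years
    for i in groups:
        ax.plot(
            years,
            [result.group_prevalence(y, i, category) for y in years],
            label=AGE_GROUP_LABELS[i],
        )
    ax.set_xlabel("year")
    ax.set_ylabel(f"{category.replace('_', ' ')} prevalence")
    ax.legend(fontsize=7, ncols=2)
    return ax
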