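"""Optional figure helpers (require matplotlib).

Analogues of the trial's result figures: the predicted-volume box plot,
the Bland-Altman agreement plot and the subgroup box plots.
"""

from __future__ import annotations

import numpy as np


def _plt():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "matplotlib is required for plotting (install virtualstroke[plot])"
        ) from exc
    return plt


def volume_boxplot(predictions, path) -> None:
    plt = _plt()
    theo = [p.vol_theophylline_ml for p in predictions]
    plac = [p.vol_placebo_ml for p in predictions]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot([theo, plac], tick_labels=["virtual\ntheophylline", "virtual\nplacebo"])
    ax.set_ylabel("predicted follow-up lesion volume (ml)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def bland_altman_plot(agreement, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(agreement.averages, agreement.differences, s=14)
    for y, style in [
        (agreement.mean_difference, "-"),
        (agreement.lower_limit, "--"),
        (agreement.upper_limit, "--"),
    ]:
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("average of the two predicted volumes (ml)")
    ax.set_ylabel("difference, theophylline - placebo (ml)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def subgroup_boxplot(predictions, flags: dict[str, np.ndarray], path) -> None:
    plt = _plt()
    diffs = np.array(
        [p.vol_theophylline_ml - p.vol_placebo_ml for p in predictions]
    )
    names, groups = [], []
    for name, flag in flags.items():
        flag = np.asarray(flag, dtype=bool)
        names += [f"{name}\nyes", f"{name}\nno"]
        groups += [diffs[flag], diffs[~flag]]
    fig, ax = plt.subplots(figsize=(2 + 1.2 * len(groups), 4))
    ax.boxplot(groups, tick_labels=names)
    ax.axhline(0, color="k", linewidth=0.8)
    ax.set_ylabel("volume difference (ml)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
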