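"""Minimal means-with-confidence-interval figure for speed x direction."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def plot_speed_by_direction(cells, filename=None, ax=None):
    """Mean estimate per Speed x Direction with 95 % CIs, distances collapsed.

    ``cells`` is an averaged per-participant condition table.  Returns the
    matplotlib axes; saves to ``filename`` when given.
    """
    import matplotlib
    if filename is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for direction, marker in (("looming", "o"), ("receding", "s")):
        sub = cells[cells["direction"] == direction]
        per_subj = sub.groupby(["participant_id", "speed_mps"], observed=True)[
            "estimate_mps"].mean().reset_index()
        agg = per_subj.groupby("speed_mps")["estimate_mps"].agg(["mean", "sem", "count"])
        ci = agg["sem"] * sps.t.ppf(0.975, np.maximum(agg["count"] - 1, 1))
        ax.errorbar(agg.index, agg["mean"], yerr=ci, marker=marker,
                    capsize=3, label=direction)
    ax.set_xlabel("source speed (m/s)")
    ax.set_ylabel("estimated speed (m/s)")
    ax.legend()
    if filename is not None:
        ax.figure.savefig(filename, dpi=150, bbox_inches="tight")
    return ax
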