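"""Optional figures for the main analyses (matplotlib required).

Plots are convenience artifacts; the numerical TSVs written by the pipeline
are the contract.  Each function takes the corresponding result table(s),
draws onto a fresh axes (or one supplied) and returns it.
"""

from __future__ import annotations


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(6, 4))
    return ax


def plot_ld_decay(curves: dict, ax=None, max_kb: float | None = None):
    """Decay curves (label -> DataFrame from ld_decay) as mean r2 vs kb."""
    ax = _axes(ax)
    for label, curve in curves.items():
        mid_kb = (curve["lo_bp"] + curve["hi_bp"]) / 2 / 1e3
        sel = slice(None) if max_kb is None else mid_kb <= max_kb
        ax.plot(mid_kb[sel], curve["mean_r2"][sel], marker="o", ms=3, label=str(label))
    ax.set_xlabel("inter-marker distance (kb)")
    ax.set_ylabel(r"mean $r^2$")
    ax.legend()
    return ax


def plot_phase_bins(bins, ax=None):
    """Phase correlation R_PC per distance interval (bar chart)."""
    ax = _axes(ax)
    mid_kb = (bins["lo_bp"] + bins["hi_bp"]) / 2 / 1e3
    width = (bins["hi_bp"] - bins["lo_bp"]).iloc[0] / 1e3 * 0.8
    ax.bar(mid_kb, bins["R_PC"], width=width)
    ax.set_xlabel("inter-marker distance (kb)")
    ax.set_ylabel(r"$R_{P,C}$")
    ax.set_ylim(-1, 1)
    return ax


def plot_ne_trajectory(trajectories: dict, ax=None):
    """Ne vs generations ago (label -> DataFrame from estimate_ne), log-log."""
    ax = _axes(ax)
    for label, traj in trajectories.items():
        ax.plot(traj["t"], traj["N_T"], marker="o", ms=3, label=str(label))
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("generations ago")
    ax.set_ylabel(r"$N_e$")
    ax.legend()
    return ax
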