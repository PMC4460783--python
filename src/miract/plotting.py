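"""Optional running-sum profile figure (requires matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_running_sum"]


def plot_running_sum(profile, null_profiles=None, mirna_id: str = "", path=None):
    """Plot a miRNA's running-sum profile, optionally over grey null profiles.

    Returns the matplotlib Axes; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if null_profiles is not None:
        for prof in null_profiles:
            ax.plot(np.arange(1, len(prof) + 1), prof, color="0.8", lw=0.5, zorder=1)
    profile = np.asarray(profile)
    ax.plot(np.arange(1, len(profile) + 1), profile, color="crimson", lw=1.5, zorder=2)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("rank in correlation-ordered gene list")
    ax.set_ylabel("running sum")
    if mirna_id:
        ax.set_title(mirna_id)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
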