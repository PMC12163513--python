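"""Optional plotting helpers (non-canonical; CSV tables are the tested surface)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .survival import SurvivalStratification


def plot_km_stratification(stratum: SurvivalStratification, path=None):
    """Step plot of the low/high Kaplan-Meier curves of one stratification."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in stratum.km_curves.items():
        ax.step(curve["time"], curve["survival"], where="post",
                label=f"{stratum.variable} {name}")
    ax.set_xlabel(f"{stratum.endpoint} time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(
        f"{stratum.variable} cutoff {stratum.cutoff:.3f} "
        f"(log-rank p={stratum.logrank_p:.2g}, exploratory)"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
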