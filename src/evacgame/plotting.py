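"""Plot helpers for sweep results (headless-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .sweeps import SweepResult

__all__ = ["plot_sweep"]


def plot_sweep(result: SweepResult, path: str) -> None:
    """Two panels: final rate vs grid value, and a round x grid heatmap."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5), constrained_layout=True)
    ax1.errorbar(
        result.values,
        result.final_means,
        yerr=result.final_sds / max(1, result.rep_finals.shape[1]) ** 0.5,
        marker="o",
    )
    ax1.set_xlabel(result.parameter)
    ax1.set_ylabel("final evacuation response rate")
    ax1.set_ylim(-0.02, 1.02)

    im = ax2.imshow(
        result.series_mean,
        aspect="auto",
        origin="lower",
        extent=(0, result.series_mean.shape[1] - 1, 0, len(result.values)),
        vmin=0.0,
        vmax=1.0,
    )
    ax2.set_yticks([i + 0.5 for i in range(len(result.values))])
    ax2.set_yticklabels([f"{v:g}" for v in result.values])
    ax2.set_xlabel("round")
    ax2.set_ylabel(result.parameter)
    fig.colorbar(im, ax=ax2, label="evacuation response rate")
    fig.savefig(path, dpi=150)
    plt.close(fig)
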