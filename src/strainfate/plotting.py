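"""Prediction-vs-observation figures (optional; needs matplotlib)."""

from __future__ import annotations

from pathlib import Path

from .dynamics import FrequencyTrajectory

__all__ = ["plot_prediction_vs_observation"]


def plot_prediction_vs_observation(
    predicted: FrequencyTrajectory,
    observed: list[FrequencyTrajectory] | None = None,
    title: str = "",
    path: str | Path | None = None,
):
    """Focal-strain frequency: full line for the prediction, markers for
    observed replicates. Returns the matplotlib Axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(predicted.generations, predicted.focal_frequencies, "-", color="black",
            label="prediction")
    for i, traj in enumerate(observed or []):
        ax.plot(traj.generations, traj.focal_frequencies, "o--", ms=3, alpha=0.7,
                label=f"replicate {i}" if i < 6 else None)
    ax.set_xlabel("generations")
    ax.set_ylabel("focal strain frequency")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
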