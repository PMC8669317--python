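"""Risk panels: sample abundance trajectories and QEP over time."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def risk_panels(
    trajectories: np.ndarray,
    qe_threshold: float,
    out_path: str | None = None,
    max_lines: int = 50,
):
    """Two-panel summary of a batch of simulated trajectories.

    Top: individual total-abundance trajectories (females) with the QE
    threshold marked.  Bottom: the running proportion of runs that have
    dropped below QE by each year, with the inter-quartile band across runs
    of the crossing indicator.

    ``trajectories`` is (n_runs, years+1) of metapopulation female totals.
    """
    trajectories = np.asarray(trajectories, dtype=float)
    n_runs, horizon = trajectories.shape
    years = np.arange(horizon)

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    for row in trajectories[:max_lines]:
        ax1.plot(years, row, lw=0.7, alpha=0.6, color="steelblue")
    ax1.axhline(qe_threshold, color="firebrick", ls="--", lw=1.2,
                label=f"QE = {qe_threshold:.0f} females")
    ax1.set_ylabel("female abundance")
    ax1.legend(frameon=False)

    below = (np.minimum.accumulate(trajectories, axis=1) < qe_threshold).astype(float)
    frac = below.mean(axis=0)
    ax2.plot(years, frac, color="black", lw=1.5)
    ax2.fill_between(years, np.percentile(below, 25, axis=0),
                     np.percentile(below, 75, axis=0), alpha=0.2, color="grey")
    ax2.set_ylim(-0.02, 1.02)
    ax2.set_xlabel("year")
    ax2.set_ylabel("P(below QE by year)")

    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
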