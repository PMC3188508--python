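"""Optional summary figures (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .protocols import TrialRecord, records_to_frame


def plot_run(records: list[TrialRecord], out_path: str | Path, title: str = "") -> Path:
    """Three stacked panels: angular errors, parameter estimates, relevance."""
    df = records_to_frame(records)
    fig, axes = plt.subplots(3, 1, figsize=(8, 7), sharex=True)
    x = df["trial"]
    axes[0].plot(x, df["error_deg"], ".", ms=3, color="k")
    axes[0].set_ylabel("angular error (deg)")
    axes[1].plot(x, df["theta_b_deg"], label=r"$\hat\theta_b$")
    axes[1].plot(x, df["theta_w_deg"], label=r"$\hat\theta_w$")
    axes[1].plot(x, df["rotation_deg"], "k--", lw=0.8, label="true rotation")
    axes[1].set_ylabel("estimate (deg)")
    axes[1].legend(loc="best", fontsize=8)
    axes[2].plot(x, df["relevance_posterior"], color="tab:red")
    axes[2].set_ylabel("P(relevant)")
    axes[2].set_ylim(-0.05, 1.05)
    axes[2].set_xlabel("trial")
    for b in df["block"].unique():
        first = df[df["block"] == b]["trial"].iloc[0]
        for ax in axes:
            ax.axvline(first, color="0.8", lw=0.6, zorder=0)
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
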