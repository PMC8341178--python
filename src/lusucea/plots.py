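"""Optional figure writers: tornado, cost-effectiveness plane, CEAC."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .sensitivity import OwsaEntry, PsaSummary

__all__ = ["plot_tornado", "plot_ce_plane", "plot_ceac"]


def plot_tornado(entries: Sequence[OwsaEntry], path: Path, top: int = 10) -> Path:
    """Horizontal NMB-range bars, widest at the top."""
    shown = list(entries[:top])[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(shown) + 1.2))
    for i, e in enumerate(shown):
        lo, hi = sorted((e.nmb_low, e.nmb_high))
        ax.barh(i, hi - lo, left=lo, color="#4878b0", height=0.6)
    ax.set_yticks(range(len(shown)), [e.parameter for e in shown])
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("net monetary benefit (JPY) at the WTP threshold")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ce_plane(summary: PsaSummary, path: Path, threshold: float = 5e6) -> Path:
    """Incremental cost vs incremental QALYs, one point per draw."""
    dq = summary.draws["delta_qaly"]
    dc = summary.draws["delta_cost"]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(dq, dc, s=6, alpha=0.4, color="#4878b0", edgecolors="none")
    ax.axhline(0, color="black", lw=0.8)
    ax.axvline(0, color="black", lw=0.8)
    span = max(abs(dq.min()), abs(dq.max()))
    ax.plot([-span, span], [-span * threshold, span * threshold],
            ls="--", lw=0.8, color="grey", label=f"WTP {threshold:,.0f} JPY/QALY")
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (JPY)")
    ax.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ceac(summary: PsaSummary, path: Path) -> Path:
    """Probability of positive NMB against willingness to pay."""
    lams = sorted(summary.acceptability)
    probs = [summary.acceptability[l] for l in lams]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(lams, probs, marker="o", ms=3, color="#4878b0")
    ax.set_ylim(0, 1)
    ax.set_xlabel("willingness to pay (JPY/QALY)")
    ax.set_ylabel("P(cost-effective)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
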