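"""PNG analogues of the standard cost-effectiveness figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .uncertainty import PSAResult


def tornado(dsa: pd.DataFrame, path: str | Path, top: int = 15) -> None:
    """Horizontal-bar tornado of the one-way sensitivity analysis."""
    df = dsa.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(df) + 1.5))
    for i, row in enumerate(df.itertuples()):
        lo = row.icer_low if isinstance(row.icer_low, (int, float)) else np.nan
        hi = row.icer_high if isinstance(row.icer_high, (int, float)) else np.nan
        ax.barh(i, hi - lo, left=lo, color="#4878a8", height=0.6)
    ax.set_yticks(range(len(df)))
    ax.set_yticklabels(df["parameter"])
    ax.set_xlabel("ICER ($/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ce_plane(
    psa: PSAResult, wtp_thresholds: tuple[float, ...], path: str | Path
) -> None:
    """Incremental cost vs. incremental QALY scatter with WTP rays."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=4, alpha=0.3, color="#4878a8")
    q = np.linspace(min(0, psa.delta_qaly.min()), psa.delta_qaly.max(), 50)
    for w in wtp_thresholds:
        ax.plot(q, w * q, lw=1, ls="--", label=f"WTP ${w:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac(psa: PSAResult, path: str | Path) -> None:
    """Cost-effectiveness acceptability curve."""
    table = psa.ceac()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["wtp"], table["probability"], color="#4878a8")
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("P(intervention cost-effective)")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
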