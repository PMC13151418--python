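"""Human-readable rendering of the channel-wise test results."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["render_report", "plot_mean_traces"]

_FOOTNOTE = (
    "Note: negative t-values indicate a decrease in Hb concentration "
    "relative to baseline (one-sample families) or a lower value in the "
    "HL condition (paired families). Corrected p-values are from the "
    "max-|t| permutation distribution over the ROI channels."
)


def render_report(
    results: pd.DataFrame,
    manifest=None,
    alpha: float = 0.05,
) -> str:
    """Render the results table grouped by Hb type, age group and family.

    Rows with corrected p <= ``alpha`` are flagged with ``*``.  Every
    results row appears exactly once.
    """
    lines = ["Channel-wise t-tests with max-|t| permutation correction", "=" * 60]
    if manifest is not None:
        version = getattr(manifest, "version", None) or manifest.get("version", "?")
        lines.append(f"pipeline version {version}")
    if results.empty:
        lines.append("")
        lines.append("No families tested (empty results).")
        return "\n".join(lines)
    for (hb_type, age, family), grp in results.groupby(
        ["hb_type", "age_group", "family"], sort=True
    ):
        lines.append("")
        lines.append(f"[{hb_type}] {age} — {family}")
        lines.append(
            f"  {'CH':>4} {'hemi':>6} {'n':>3} {'t':>8} {'df':>4} "
            f"{'d':>6} {'p unc.':>8} {'p corr.':>8}"
        )
        for _, r in grp.sort_values("channel").iterrows():
            star = " *" if r["p_corrected"] <= alpha else ""
            lines.append(
                f"  {int(r['channel']):>4} {r['hemisphere']:>6} {int(r['n']):>3} "
                f"{r['t']:>8.3f} {int(r['df']):>4} {r['d']:>6.2f} "
                f"{r['p_uncorrected']:>8.4f} {r['p_corrected']:>8.4f}{star}"
            )
    lines.append("")
    lines.append(f"* corrected p <= {alpha}")
    lines.append(_FOOTNOTE)
    return "\n".join(lines)


def plot_mean_traces(
    epoch_sets,
    out_path: str | Path,
    channels: list[int] | None = None,
):
    """Grand-average epoch traces per channel x condition (PNG/SVG).

    Solid lines: oxy-Hb; dashed: deoxy-Hb.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    from nirsblock.core import CONDITIONS

    layout = epoch_sets[0].layout
    if channels is None:
        channels = [int(c) for c in layout.roi_ids]
    rel = epoch_sets[0].rel_times
    fig, axes = plt.subplots(
        1, len(channels), figsize=(3 * len(channels), 3), sharey=True, squeeze=False
    )
    for ax, cid in zip(axes[0], channels):
        ci = layout.index_of(cid)
        for cond, color in zip(CONDITIONS, ("tab:red", "tab:blue")):
            traces_oxy, traces_deoxy = [], []
            for es in epoch_sets:
                sel = [
                    bi
                    for bi, c in enumerate(es.conditions)
                    if c == cond and es.valid[bi, ci]
                ]
                if sel:
                    traces_oxy.append(es.data[sel, :, ci, 0].mean(axis=0))
                    traces_deoxy.append(es.data[sel, :, ci, 1].mean(axis=0))
            if traces_oxy:
                ax.plot(rel, np.mean(traces_oxy, axis=0), color=color, label=f"{cond} oxy")
                ax.plot(
                    rel,
                    np.mean(traces_deoxy, axis=0),
                    color=color,
                    linestyle="--",
                    label=f"{cond} deoxy",
                )
        ax.axvline(0, color="k", lw=0.5)
        ax.set_title(f"CH{cid}")
        ax.set_xlabel("time from onset (s)")
    axes[0][0].set_ylabel("conc. change (uM)")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
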