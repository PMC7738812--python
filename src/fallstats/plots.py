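"""Boxplot and comparison-interval figures for a comparison report."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .comparison import ComparisonReport, SliceResult

__all__ = ["plot_boxplots", "plot_comparison_intervals", "render_report"]


def plot_boxplots(result: SliceResult, path: str | Path) -> Path:
    """Per-dataset box-and-whisker chart for one slice x feature cell."""
    names = list(result.boxplots)
    stats = [
        {
            "med": b.median,
            "q1": b.q1,
            "q3": b.q3,
            "whislo": b.whisker_low,
            "whishi": b.whisker_high,
            "fliers": list(b.outliers),
            "label": name,
        }
        for name, b in result.boxplots.items()
    ]
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(names), 3.2))
    ax.bxp(stats, showfliers=True, flierprops={"marker": "x", "color": "red"})
    ax.set_ylabel(result.feature)
    ax.set_title(f"{result.feature} — {result.slice_name}")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_comparison_intervals(result: SliceResult, path: str | Path) -> Path:
    """Group means with post-hoc comparison intervals; datasets whose mean is
    significantly different from at least one other are highlighted."""
    ph = result.posthoc
    k = len(ph.group_names)
    fig, ax = plt.subplots(figsize=(4.0, 0.8 + 0.5 * k))
    any_sig = ph.significant.any(axis=1)
    for i, name in enumerate(ph.group_names):
        color = "tab:red" if any_sig[i] else "tab:gray"
        ax.errorbar(
            ph.means[i], i, xerr=ph.half_widths[i], fmt="o",
            color=color, capsize=3,
        )
    ax.set_yticks(range(k), ph.group_names)
    ax.invert_yaxis()
    ax.set_xlabel(result.feature)
    ax.set_title(
        f"{result.feature} — {result.slice_name} "
        f"(F={result.anova.f_stat:.3g}, p={result.anova.p_value:.2g})"
    )
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def render_report(report: ComparisonReport, out_dir: str | Path) -> list:
    """Write every boxplot and interval chart of a report under ``out_dir``."""
    out_dir = Path(out_dir)
    written = []
    for (slice_name, feature), result in report.results.items():
        safe = slice_name.replace("/", "_").replace(" ", "_")
        written.append(
            plot_boxplots(result, out_dir / f"box_{safe}_{feature}.png")
        )
        written.append(
            plot_comparison_intervals(result, out_dir / f"anova_{safe}_{feature}.png")
        )
    return written
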