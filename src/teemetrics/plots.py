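"""Optional figures mirroring the report tables (strip and bar charts)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def _strip_pair(ax, summary: dict, title: str, ylabel: str) -> None:
    for k, (label, color) in enumerate((("Test 1", "tab:red"),
                                        ("Test 2", "tab:blue"))):
        d = summary[f"test{k + 1}"]
        ax.scatter([], [], color=color, label=label)
        ax.errorbar([k], [d["median"]],
                    yerr=[[d["median"] - d["q1"]], [d["q3"] - d["median"]]],
                    fmt="_", color=color, capsize=6, markersize=20)
    if "expert" in summary:
        ax.scatter([1.4], [summary["expert"]], color="tab:green", zorder=3,
                   label="expert")
    p = summary["comparison"].get("p_value")
    sub = f" (p = {p:.3g})" if p == p else ""
    ax.set_title(title + sub, fontsize=9)
    ax.set_xticks([0, 1], ["Test 1", "Test 2"])
    ax.set_ylabel(ylabel)


def cohort_figures(report: dict, out_dir: str | Path) -> list[str]:
    """Write summary figures; returns the file names written."""
    out_dir = Path(out_dir)
    written = []

    fig, axes = plt.subplots(2, 2, figsize=(8, 6), constrained_layout=True)
    _strip_pair(axes[0, 0], report["total_time_s"],
                "Total examination time", "s")
    _strip_pair(axes[0, 1], report["mean_precision"],
                "Mean precision", "fraction")
    _strip_pair(axes[1, 0], report["rar"]["rotation"],
                "RAR: probe rotation", "deg/s (summed)")
    _strip_pair(axes[1, 1], report["rar"]["ante_retro"],
                "RAR: ante/retroflexion", "deg/s (summed)")
    name = "cohort_summary.png"
    fig.savefig(out_dir / name, dpi=120)
    plt.close(fig)
    written.append(name)

    fig, ax = plt.subplots(figsize=(4, 3), constrained_layout=True)
    g = report["grades"]
    ax.bar(["improved", "neutral", "worsened"],
           [g["improved"], g["neutral"], g["worsened"]],
           color=["tab:green", "tab:gray", "tab:red"])
    ax.set_title(f"Rubric outcome (mean {g['mean']:+.2f} "
                 f"± {g['sd']:.2f})", fontsize=9)
    ax.set_ylabel("students")
    name = "grade_summary.png"
    fig.savefig(out_dir / name, dpi=120)
    plt.close(fig)
    written.append(name)
    return written
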