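"""Optional figures: ROC curves for the three indices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_roc_curves(report: dict, path) -> Path:
    """Plot the ROC curves stored in a study report to ``path`` (PNG/PDF)."""
    roc_table = report.get("roc")
    if not roc_table:
        raise ValueError("report contains no ROC section")
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, entry in sorted(roc_table.items()):
        curve = entry["curve"]
        ax.plot(curve["one_minus_specificity"], curve["sensitivity"],
                label=f"{name.upper()} (AUC = {entry['auc']:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(roc_table[next(iter(roc_table))]["positive_class_definition"])
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
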