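"""Post-hoc model interpretation and reporting.

For a fitted model, the feature groups present are those feature classes
owning at least one nonzero coefficient (with a MeshVolume flag for the
volume feature); across the repeated CV splits, the frequency with which
each candidate group was selected indicates model robustness.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .features.registry import FEATURE_CLASSES
from .modeling import FitResult, ValidationResult
from .selection import DEFAULT_HIERARCHY


def groups_present(fit: FitResult) -> tuple[set[str], bool]:
    """Feature classes with a nonzero coefficient, plus a MeshVolume flag."""
    classes = {k.feature_class for k in fit.coefficients}
    mesh = any(k.is_mesh_volume for k in fit.coefficients)
    return classes, mesh


def group_label(fit: FitResult) -> str:
    """Composite group label: 'all' when every class is present, otherwise
    classes joined with '|' in hierarchy order (e.g. 'shape|firstorder')."""
    classes, mesh = groups_present(fit)
    if not classes:
        return "none"
    if classes == set(FEATURE_CLASSES):
        return "all"
    order = [c for c in DEFAULT_HIERARCHY if c in classes]
    if classes == {"shape"} and mesh and len(fit.coefficients) == sum(
        1 for k in fit.coefficients if k.is_mesh_volume
    ):
        return "MeshVolume"
    return "|".join(order)


@dataclass
class GroupFrequency:
    counts: dict[str, int]
    roi_set: str
    mode: str

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {g: c / t for g, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(self.counts),
                "count": list(self.counts.values()),
                "fraction": list(self.fractions.values()),
                "roi_set": self.roi_set,
                "mode": self.mode,
            }
        )


def selection_frequency(
    validation: ValidationResult, roi_set: str = ""
) -> GroupFrequency:
    """Selected-group counts over the CV splits of a proposed-mode run."""
    if validation.mode != "proposed":
        raise ValueError(
            "selection frequency is defined for the proposed pipeline; for the "
            "conventional pipeline inspect groups_present of each fit"
        )
    counts = Counter(fit.selected_group for fit in validation.per_split_fit)
    return GroupFrequency(dict(counts), roi_set, validation.mode)


@dataclass
class ModelSummary:
    target: str
    roi_set: str
    mode: str
    mean_auroc: float
    permutation_p: float
    feature_group: str
    n_features: int


def build_report(
    summaries: list[ModelSummary],
    frequencies: list[GroupFrequency] | None = None,
    out_dir: str = ".",
    plot: bool = False,
) -> pd.DataFrame:
    """Write report.csv (one row per target × ROI set × mode, best-AUROC ROI
    set per target/mode flagged) and frequencies.csv; optional stacked-bar
    plot when matplotlib is available."""
    if not summaries:
        raise ValueError("no summaries to report")
    os.makedirs(out_dir, exist_ok=True)
    df = pd.DataFrame([s.__dict__ for s in summaries])
    df["best_roi_set"] = False
    for (_, _), idx in df.groupby(["target", "mode"]).groups.items():
        sub = df.loc[idx]
        df.loc[sub["mean_auroc"].idxmax(), "best_roi_set"] = True
    df.to_csv(os.path.join(out_dir, "report.csv"), index=False)

    if frequencies:
        freq = pd.concat([f.to_frame() for f in frequencies], ignore_index=True)
        freq.to_csv(os.path.join(out_dir, "frequencies.csv"), index=False)
        if plot:
            _plot_frequencies(freq, os.path.join(out_dir, "frequencies.svg"))
    return df


def _plot_frequencies(freq: pd.DataFrame, path: str) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is optional; CSV output already written
        return
    pivot = freq.pivot_table(
        index="roi_set", columns="group", values="fraction", fill_value=0.0
    )
    ax = pivot.plot(kind="bar", stacked=True, figsize=(8, 4))
    ax.set_ylabel("selection fraction")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)
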