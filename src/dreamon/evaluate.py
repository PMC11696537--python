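"""Metrics and statistics for the robustness benchmark.

Balanced accuracy (mean per-class recall), expected calibration error
(10 equal-width confidence bins), the Δ stability score (spread of median
accuracies across noise levels), the binomial above-chance threshold
(~0.411 for 90 trials at chance 1/3), Fleiss' kappa for fixed-panel
inter-rater agreement, the rater-protocol roster, and report aggregation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import balanced_accuracy_score
from statsmodels.stats import inter_rater

from .data import N_CLASSES


def balanced_accuracy(true_labels: Sequence[int], predictions: np.ndarray) -> float:
    """Mean over classes of per-class recall.

    *predictions* are per-sample class-probability rows, reduced by argmax;
    classes absent from *true_labels* are excluded from the mean.  On a
    class-balanced test set this equals plain accuracy.
    """
    y_true = np.asarray(true_labels, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    probs = np.asarray(predictions, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != y_true.size:
        raise ValueError("predictions must be one probability row per true label")
    with warnings.catch_warnings():
        # predicted classes absent from y_true are irrelevant to per-class recall
        warnings.simplefilter("ignore", UserWarning)
        return float(balanced_accuracy_score(y_true, probs.argmax(axis=1)))


def expected_calibration_error(
    predictions: np.ndarray, true_labels: Sequence[int], n_bins: int = 10
) -> float:
    """Bin-weighted mean absolute gap between confidence and accuracy.

    Confidence is the maximum probability per row; [0, 1] is partitioned
    into *n_bins* equal-width right-closed bins and
    ``ECE = sum_b (|b|/N) * |acc_b - conf_b|`` with empty bins contributing
    nothing.
    """
    probs = np.asarray(predictions, dtype=float)
    y_true = np.asarray(true_labels, dtype=int)
    if probs.size == 0:
        raise ValueError("empty input")
    conf = probs.max(axis=1)
    correct = probs.argmax(axis=1) == y_true
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed bins (lo, hi]; confidence 0 lands in the first bin
    idx = np.clip(np.digitize(conf, edges[1:-1], right=True), 0, n_bins - 1)
    ece = 0.0
    n = conf.size
    for b in range(n_bins):
        in_bin = idx == b
        if not in_bin.any():
            continue
        ece += (in_bin.sum() / n) * abs(correct[in_bin].mean() - conf[in_bin].mean())
    return float(ece)


def delta_stability(medians: Sequence[float]) -> float:
    """Δ = max − min of per-level median accuracies; lower means more stable."""
    medians = np.asarray(medians, dtype=float)
    if medians.size == 0:
        raise ValueError("need at least one level median")
    return float(medians.max() - medians.min())


def chance_threshold(n_trials: int, chance_p: float = 1 / 3, alpha: float = 0.05) -> float:
    """Accuracy above which *n_trials* Bernoulli trials beat chance at level *alpha*.

    Returns ``q / n_trials`` where ``q`` is the (1 − alpha) quantile of
    ``Binomial(n_trials, chance_p)`` — the smallest integer whose CDF
    reaches 1 − alpha.  For 90 trials at chance 1/3 this is 37/90 ≈ 0.411.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 < chance_p < 1:
        raise ValueError("chance_p must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    q = int(stats.binom.ppf(1.0 - alpha, n_trials, chance_p))
    return q / n_trials


#: Landis–Koch interpretation bands for kappa (presentational only)
KAPPA_BANDS = (
    (0.0, "poor"),
    (0.01, "slight"),
    (0.21, "fair"),
    (0.41, "moderate"),
    (0.61, "substantial"),
    (0.81, "almost perfect"),
)


def interpret_kappa(kappa: float) -> str:
    label = "poor"
    for cutoff, name in KAPPA_BANDS:
        if kappa >= cutoff:
            label = name
    return label


@dataclasses.dataclass
class RaterMatrix:
    """Items × categories table of rating counts from a fixed panel of raters."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D items x categories table")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        row_sums = self.counts.sum(axis=1)
        if len(set(row_sums.tolist())) != 1:
            raise ValueError("every item must receive the same number of ratings")
        self.n_raters = int(row_sums[0])

    @classmethod
    def from_responses(cls, frame: pd.DataFrame, n_categories: int) -> "RaterMatrix":
        """Build from a long response table with columns ``item_id`` and ``response``."""
        items = sorted(frame["item_id"].unique())
        counts = np.zeros((len(items), n_categories), dtype=int)
        pos = {it: i for i, it in enumerate(items)}
        for _, row in frame.iterrows():
            counts[pos[row["item_id"]], int(row["response"])] += 1
        return cls(counts)


def fleiss_kappa(matrix: RaterMatrix | np.ndarray) -> float:
    """Chance-corrected agreement ``κ = (P̄ − P̄e) / (1 − P̄e)`` for a fixed rater panel.

    Degenerate case: if every rating in the whole table falls in a single
    category, expected agreement is 1 and κ is defined as 1.0 (observed
    agreement is then also perfect).
    """
    if not isinstance(matrix, RaterMatrix):
        matrix = RaterMatrix(np.asarray(matrix))
    counts = matrix.counts
    if matrix.n_raters < 2:
        raise ValueError("need at least 2 raters")
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 items")
    category_share = counts.sum(axis=0) / counts.sum()
    if np.max(category_share) == 1.0:
        return 1.0
    return float(inter_rater.fleiss_kappa(counts, method="fleiss"))


def build_rater_protocol(
    n_raters: int, images_per_level: int, levels: Sequence[int]
) -> pd.DataFrame:
    """Trial roster for the human-observer benchmark.

    One forced-choice trial per (rater, level, image); 4 raters × 30
    images × 7 levels gives the reference 840 trials.  The returned frame
    doubles as a response-sheet template (empty ``response`` column).
    """
    levels = list(levels)
    if n_raters < 1 or images_per_level < 1 or not levels:
        raise ValueError("counts must be positive and levels non-empty")
    rows = []
    for rater in range(n_raters):
        trial = 0
        for level in levels:
            for img in range(images_per_level):
                rows.append(
                    {
                        "rater_id": rater,
                        "trial_index": trial,
                        "item_id": f"L{level}_I{img:03d}",
                        "level": level,
                        "response": "",
                    }
                )
                trial += 1
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ reports


@dataclasses.dataclass
class RobustnessReport:
    """Per-(strategy, run, family, level) metric cells plus aggregates.

    ``aggregates`` carries the median balanced accuracy over runs per
    (strategy, family, level), the Δ stability per (strategy, family) and
    an above-chance flag against the binomial threshold for ``n_test``
    trials.
    """

    cells: pd.DataFrame
    aggregates: pd.DataFrame
    deltas: pd.DataFrame
    n_test: int
    threshold: float

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False)
        payload = {
            "n_test": self.n_test,
            "threshold": self.threshold,
            "aggregates": self.aggregates.to_dict(orient="records"),
            "deltas": self.deltas.to_dict(orient="records"),
        }
        (out / "aggregates.json").write_text(json.dumps(payload, indent=2))
        return out

    @classmethod
    def load(cls, out_dir: str | Path) -> "RobustnessReport":
        out = Path(out_dir)
        cells = pd.read_csv(out / "cells.csv")
        payload = json.loads((out / "aggregates.json").read_text())
        return cls(
            cells=cells,
            aggregates=pd.DataFrame(payload["aggregates"]),
            deltas=pd.DataFrame(payload["deltas"]),
            n_test=int(payload["n_test"]),
            threshold=float(payload["threshold"]),
        )


CELL_COLUMNS = ["strategy", "run", "family", "level", "balanced_accuracy", "ece"]


def aggregate_report(
    cells: pd.DataFrame | Iterable[dict],
    n_test: int,
    chance_p: float = 1 / N_CLASSES,
    alpha: float = 0.05,
) -> RobustnessReport:
    """Aggregate raw metric cells into medians, Δ values and above-chance flags."""
    frame = pd.DataFrame(cells)
    if frame.empty:
        raise ValueError("no metric cells to aggregate")
    missing = set(CELL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cells are missing columns {sorted(missing)}")
    threshold = chance_threshold(n_test, chance_p, alpha)
    agg = (
        frame.groupby(["strategy", "family", "level"], as_index=False)
        .agg(
            median_balanced_accuracy=("balanced_accuracy", "median"),
            median_ece=("ece", "median"),
            n_runs=("run", "nunique"),
        )
        .sort_values(["strategy", "family", "level"], ignore_index=True)
    )
    agg["above_chance"] = agg["median_balanced_accuracy"] > threshold
    deltas = (
        agg.groupby(["strategy", "family"], as_index=False)
        .agg(delta=("median_balanced_accuracy", lambda m: delta_stability(m.to_numpy())))
        .sort_values(["strategy", "family"], ignore_index=True)
    )
    return RobustnessReport(
        cells=frame.reset_index(drop=True),
        aggregates=agg,
        deltas=deltas,
        n_test=n_test,
        threshold=threshold,
    )


def plot_report(report: RobustnessReport, out_path: str | Path) -> Path:
    """Boxplots of balanced accuracy per strategy and level, one panel per family."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    families = sorted(report.cells["family"].unique())
    strategies = sorted(report.cells["strategy"].unique())
    fig, axes = plt.subplots(1, len(families), figsize=(5 * len(families), 4), squeeze=False)
    for ax, family in zip(axes[0], families):
        sub = report.cells[report.cells["family"] == family]
        levels = sorted(sub["level"].unique())
        width = 0.8 / max(len(strategies), 1)
        for k, strat in enumerate(strategies):
            data = [
                sub[(sub["strategy"] == strat) & (sub["level"] == lv)][
                    "balanced_accuracy"
                ].to_numpy()
                for lv in levels
            ]
            positions = [lv + (k - len(strategies) / 2) * width for lv in levels]
            ax.boxplot(data, positions=positions, widths=width * 0.9)
        ax.axhline(1 / 3, ls=":", color="k")
        ax.axhline(report.threshold, ls="-", color="k", lw=1)
        ax.set_title(family)
        ax.set_xlabel("noise level")
        ax.set_ylabel("balanced accuracy")
        ax.set_xticks(levels)
        ax.set_xticklabels(levels)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
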