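"""End-to-end orchestration of the three workflow steps.

Step 1 builds the per-cell classifier: surface parameters for every
cell×channel, Gini-importance ranking of the pooled table, top-k feature
selection (k=10 for a single channel, 20 for a channel combination), a
stratified random train/test split, GP training and per-cell probability
classification at the 50 % threshold.  Step 2 re-runs step 1 on
moving-average-blurred copies to pick the window ("zoom") size.  Step 3
rasters the trained classifier over sliding windows to produce heatmaps.

Ranking precedes the split, i.e. importances are computed on the pooled
labelled table before the random train/test partition, mirroring the order
of the original workflow (parameter reduction is treated as part of dataset
construction).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import yaml

from .features import (
    FeatureTable,
    ImportanceRanking,
    build_feature_table,
    default_top_k,
    rank_gini_importance,
    select_top_k,
)
from .io import CellRecord
from .model import (
    AggressivenessGP,
    AggressivenessGPResults,
    ClassificationReport,
    SplitSpec,
    split_train_test,
)
from .params import DEFAULT_REGISTRY, ParameterRegistry


@dataclass(frozen=True)
class Step1Config:
    """Settings of the classifier-building step; defaults follow the method's
    stated values (k=10/20, max_iter=1000, threshold 0.5, 70/30 split)."""

    channel_kinds: Optional[Sequence[str]] = None  # None -> all channels present
    registry: ParameterRegistry = DEFAULT_REGISTRY
    k: Optional[int] = None  # None -> 10 single channel, 20 combined
    split: SplitSpec = field(default_factory=SplitSpec)
    max_iter: int = 1000
    n_trees: int = 500
    gini_seed: int = 0
    gp_seed: int = 0
    threshold: float = 0.5


@dataclass
class Step1Outcome:
    table: FeatureTable
    ranking: ImportanceRanking
    selected: list
    results: AggressivenessGPResults
    train_report: ClassificationReport
    test_report: ClassificationReport

    @property
    def test_accuracy(self) -> float:
        return self.test_report.accuracy


def evaluate_step1(cells: Sequence[CellRecord], config: Step1Config = Step1Config()) -> Step1Outcome:
    """Run the full step-1 pipeline on in-memory cells."""
    kinds = list(config.channel_kinds) if config.channel_kinds else sorted(cells[0].channels)
    table = build_feature_table(cells, kinds, config.registry)
    ranking = rank_gini_importance(table, n_trees=config.n_trees, seed=config.gini_seed)
    k = config.k if config.k is not None else default_top_k(len(kinds))
    selected = select_top_k(ranking, k)
    train, test = split_train_test(table, config.split)
    results = AggressivenessGP(
        train, selected, max_iter=config.max_iter, seed=config.gp_seed
    ).fit()
    return Step1Outcome(
        table,
        ranking,
        selected,
        results,
        results.classify(train, config.threshold),
        results.classify(test, config.threshold),
    )


def run_step1(cells, config: Step1Config, out_dir) -> Step1Outcome:
    """Step 1 with artefacts: model bundle, ranking CSV, per-cell CSVs and a
    Fig-2-style probability bar chart."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    outcome = evaluate_step1(cells, config)
    outcome.ranking.to_csv(out / "importance_ranking.csv")
    outcome.table.to_csv(out / "feature_table.csv")
    outcome.results.save(out / "model.json")
    outcome.train_report.to_csv(out / "train_cells.csv")
    outcome.test_report.to_csv(out / "test_cells.csv")
    _plot_probabilities(outcome.test_report, out / "test_probabilities.png")
    (out / "step1_summary.txt").write_text(
        outcome.results.summary()
        + f"\n\nTest accuracy: {outcome.test_accuracy:.3f}"
        + f"\nElapsed: {time.time() - t0:.1f} s\n"
    )
    return outcome


def run_step2(
    cells,
    config: Step1Config,
    kernels=None,
    threshold_X: float = 0.8,
    min_zoom_px: int = 32,
    out_dir=None,
):
    """Step 2: blur-accuracy curve plus zoom selection (and optional artefacts)."""
    from .resolution import DEFAULT_KERNELS, accuracy_vs_blur, plot_curve, select_zoom

    kernels = list(kernels) if kernels is not None else list(DEFAULT_KERNELS)
    curve = accuracy_vs_blur(cells, kernels, config)
    zoom = select_zoom(curve, threshold_X=threshold_X, min_zoom_px=min_zoom_px)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        curve.to_csv(out / "blur_accuracy.csv")
        plot_curve(curve, out / "blur_accuracy.png")
        (out / "zoom_selection.json").write_text(
            json.dumps(
                {
                    "zoom_px": zoom.zoom_px,
                    "threshold_X": zoom.threshold_X,
                    "min_zoom_px": zoom.min_zoom_px,
                    "rationale": zoom.rationale,
                }
            )
        )
    return curve, zoom


def run_step3(
    cells: Sequence[CellRecord],
    results: AggressivenessGPResults,
    window_px: int = 32,
    stride_px: int = 1,
    out_dir=None,
    overlay_channel: str = "rm_restored_adhesion",
    min_area_px: int = 16,
):
    """Step 3: heatmap, overlay and thresholded regions for each cell."""
    from .heatmap import compute_heatmap, extract_regions, overlay
    from .io import write_heatmap

    heatmaps = {}
    for cell in cells:
        hm = compute_heatmap(cell, results, window_px=window_px, stride_px=stride_px)
        heatmaps[cell.cell_id] = hm
        if out_dir is not None:
            out = Path(out_dir) / cell.cell_id
            out.mkdir(parents=True, exist_ok=True)
            write_heatmap(hm, out / "heatmap.txt")
            ch = overlay_channel if overlay_channel in cell.channels else sorted(cell.channels)[0]
            overlay(hm, cell.channels[ch], alpha=0.5, path=out / "overlay.png")
            extract_regions(hm, min_area_px=min_area_px).to_json(out / "regions.json")
    return heatmaps


def _plot_probabilities(report: ClassificationReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = report.frame.sort_values(["label", "probability_high"])
    colors = ["tab:red" if lbl == "high" else "tab:blue" for lbl in frame["label"]]
    fig, ax = plt.subplots(figsize=(max(4, 0.25 * len(frame)), 3))
    ax.bar(range(len(frame)), frame["probability_high"], color=colors)
    ax.axhline(report.threshold, ls="--", c="k", lw=0.8)
    ax.set_ylabel("P(high aggressiveness)")
    ax.set_xticks(range(len(frame)))
    ax.set_xticklabels(frame.index, rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Declarative run configuration (YAML)

@dataclass
class RunConfig:
    """Whole-workflow configuration; defaults are the method's stated values."""

    channels: Optional[List[str]] = None
    k: Optional[int] = None
    train_fraction: float = 0.7
    max_iter: int = 1000
    n_trees: int = 500
    kernels: List[int] = field(default_factory=lambda: [1, 2, 4, 8, 16, 32, 64])
    threshold_X: float = 0.8
    min_zoom_px: int = 32
    window_px: int = 32
    stride_px: int = 1
    threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def snapshot(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def step1(self) -> Step1Config:
        return Step1Config(
            channel_kinds=self.channels,
            k=self.k,
            split=SplitSpec(train_fraction=self.train_fraction, seed=self.seed),
            max_iter=self.max_iter,
            n_trees=self.n_trees,
            gini_seed=self.seed,
            gp_seed=self.seed,
            threshold=self.threshold,
        )
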