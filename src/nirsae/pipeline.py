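"""End-to-end replicated analysis: simulate/load -> preprocess -> train ->
score -> window-size selection -> group comparison -> report.

For each candidate window size and replicate (replicate seed = master seed
+ replicate index) a fresh model is trained on score-task windows and both
tasks are scored.  Replicate error maps are averaged before window-size
selection and channel ranking; the group comparison runs only at the
selected window size, pooling each subject's window errors across
replicates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autoencoder import (
    ChannelErrorMap,
    ModelSpec,
    TrainConfig,
    build_autoencoder,
    reconstruction_errors,
    subject_channel_error,
    train_autoencoder,
)
from .io import CohortManifest, load_manifest, read_wide_csv
from .preprocess import apply_normalizer, fit_normalizer, resample_to_length, sliding_windows
from .stats import GroupComparison, WindowSweepTable, compare_groups, rank_channels, select_window_size
from .synthetic import CohortConfig, CohortData, simulate_cohort

log = logging.getLogger("nirsae.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the full analysis once."""

    cohort: CohortConfig | None = None  # synthetic source ...
    manifest_path: str | None = None  # ... or on-disk cohort
    target_len: int = 1800
    window_candidates: tuple = (15, 20, 25)
    stride: int = 1
    train: TrainConfig = field(default_factory=TrainConfig)
    n_replicates: int = 5
    roi_channels: tuple = (1, 15)
    n_permutations: int = 10_000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.window_candidates:
            raise ValueError("window_candidates must be non-empty")
        if (self.cohort is None) == (self.manifest_path is None):
            raise ValueError("configure exactly one of cohort (synthetic) or manifest_path")

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return enc(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class AnalysisReport:
    config: PipelineConfig
    sweep: WindowSweepTable
    selected_window: int
    error_map: ChannelErrorMap  # replicate-averaged, at the selected window size
    channel_ranking: pd.DataFrame
    comparison: GroupComparison
    histories: dict  # (window_size, replicate) -> TrainingHistory
    roi_separation: dict  # replicate -> {"improv_roi_error": ..., "score_holdout_roi_error": ...}

    def to_dict(self) -> dict:
        return {
            "package_version": __version__,
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "window_sweep": [
                {"window_size": w, "train_error": tr, "test_error": te}
                for w, tr, te in self.sweep.rows
            ],
            "selected_window": self.selected_window,
            "channel_ranking": self.channel_ranking.to_dict(orient="records"),
            "error_map": self.error_map.table.to_dict(orient="records"),
            "group_comparison": self.comparison.to_dict(),
            "roi_separation": self.roi_separation,
            "final_losses": {
                f"W{w}_rep{r}": {"train": h.train_loss[-1], "val": h.val_loss[-1]}
                for (w, r), h in sorted(self.histories.items())
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _load_cohort(config: PipelineConfig) -> tuple[list, CohortManifest]:
    if config.cohort is not None:
        cohort: CohortData = simulate_cohort(config.cohort)
        return cohort.recordings, cohort.manifest
    manifest = load_manifest(config.manifest_path)
    base = Path(config.manifest_path).parent
    recordings = []
    for _, row in manifest.table.iterrows():
        rec = read_wide_csv(
            base / row["file"], subject_id=row["subject_id"], group=row["group"], task=row["task"]
        )
        recordings.append(rec)
    return recordings, manifest


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run the full replicated analysis; see the module docstring for stages."""
    t0 = time.time()
    recordings, manifest = _load_cohort(config)
    log.info("cohort: %d recordings, master seed %d", len(recordings), config.master_seed)
    recordings = [resample_to_length(r, config.target_len) for r in recordings]
    channel_ids = tuple(recordings[0].channel_ids)
    n_channels = len(channel_ids)

    sweep_rows = []
    histories: dict = {}
    per_w_maps: dict[int, list[pd.DataFrame]] = {}
    per_w_errors: dict[int, list[tuple[np.ndarray, pd.DataFrame]]] = {}
    per_w_separation: dict[int, dict] = {}

    for W in config.window_candidates:
        train_errs, test_errs = [], []
        per_w_maps[W] = []
        per_w_errors[W] = []
        per_w_separation[W] = {}
        for rep in range(config.n_replicates):
            seed = config.master_seed + rep
            score_recs = [r for r in recordings if r.task == "score"]
            stats = fit_normalizer(score_recs)
            normed = [apply_normalizer(r, stats) for r in recordings]
            score_windows = sliding_windows(
                [r for r in normed if r.task == "score"], W, config.stride
            )
            improv_windows = sliding_windows(
                [r for r in normed if r.task == "improv"], W, config.stride
            )
            spec = ModelSpec(window_len=W, n_channels=n_channels)
            handle = build_autoencoder(spec, seed=seed)
            cfg = dataclasses.replace(config.train, seed=seed)
            history = train_autoencoder(handle, score_windows, cfg)
            histories[(W, rep)] = history

            score_err = reconstruction_errors(handle, score_windows)
            improv_err = reconstruction_errors(handle, improv_windows)
            train_errs.append(float(score_err.mean()))
            test_errs.append(float(improv_err.mean()))

            all_err = np.concatenate([score_err, improv_err], axis=0)
            all_prov = pd.concat(
                [score_windows.provenance, improv_windows.provenance], ignore_index=True
            )
            errmap = subject_channel_error(all_err, all_prov, channel_ids)
            per_w_maps[W].append(errmap.table)
            per_w_errors[W].append((all_err, all_prov))

            roi_cols = [channel_ids.index(c) for c in config.roi_channels]
            holdout = history.val_index
            sep = {
                "improv_roi_error": float(improv_err[:, roi_cols].mean()),
                "score_holdout_roi_error": float(score_err[holdout][:, roi_cols].mean()),
            }
            per_w_separation[W][f"rep{rep}"] = sep
            log.info(
                "W=%d rep=%d: train %.4f test %.4f (%.1fs)",
                W, rep, train_errs[-1], test_errs[-1], time.time() - t0,
            )
        sweep_rows.append((W, float(np.mean(train_errs)), float(np.mean(test_errs))))

    sweep = WindowSweepTable(rows=tuple(sweep_rows))
    selected = select_window_size(sweep)

    # replicate-averaged error map at the selected window size
    stacked = pd.concat(per_w_maps[selected], ignore_index=True)
    averaged = (
        stacked.groupby(["subject_id", "task", "channel"], sort=True)["mean_error"]
        .mean()
        .reset_index()
    )
    errmap = ChannelErrorMap(table=averaged, channel_ids=channel_ids)
    ranking = rank_channels(errmap, task="improv")

    # group comparison pools each subject's window errors across replicates
    errs = np.concatenate([e for e, _ in per_w_errors[selected]], axis=0)
    prov = pd.concat([p for _, p in per_w_errors[selected]], ignore_index=True)
    comparison = compare_groups(
        errs,
        prov,
        manifest,
        roi_channels=config.roi_channels,
        channel_ids=channel_ids,
        n_permutations=config.n_permutations,
        seed=config.master_seed,
    )
    log.info("selected W=%d; done in %.1fs", selected, time.time() - t0)
    return AnalysisReport(
        config=config,
        sweep=sweep,
        selected_window=selected,
        error_map=errmap,
        channel_ranking=ranking,
        comparison=comparison,
        histories=histories,
        roi_separation=per_w_separation[selected],
    )


def render_report(report: AnalysisReport, outdir: str | Path) -> list:
    """Write JSON + text summaries, loss curves, and the channel-error figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    json_path = outdir / "report.json"
    json_path.write_text(report.to_json())
    written.append(json_path)

    txt_path = outdir / "summary.txt"
    lines = [
        f"nirsae analysis report (config {report.config.config_hash()})",
        "",
        "Window sweep (replicate-averaged reconstruction error):",
        report.sweep.to_frame().to_string(index=False),
        f"Selected window size: {report.selected_window}",
        "",
        "Top channels by improv grand-mean error:",
        report.channel_ranking.head(5).to_string(index=False),
        "",
        report.comparison.to_text(),
    ]
    txt_path.write_text("\n".join(lines) + "\n")
    written.append(txt_path)

    fig, ax = plt.subplots(figsize=(6, 4))
    for (w, rep), hist in sorted(report.histories.items()):
        if w != report.selected_window:
            continue
        epochs = np.arange(1, len(hist.train_loss) + 1)
        ax.plot(epochs, hist.train_loss, label=f"train (rep {rep})")
        ax.plot(epochs, hist.val_loss, "--", label=f"val (rep {rep})")
    ax.set_xlabel("epoch")
    ax.set_ylabel("MSE loss")
    ax.set_title(f"Training and validation loss (W={report.selected_window})")
    ax.legend(fontsize=7)
    loss_path = outdir / "loss_curves.png"
    fig.savefig(loss_path, dpi=120)
    plt.close(fig)
    written.append(loss_path)

    # channel-error bars: per-group panels plus overall, improv task
    table = report.error_map.table
    improv = table[table["task"] == "improv"]
    subj_groups = {
        row["subject_id"]: row["group"] for _, row in _manifest_like(report).iterrows()
    }
    improv = improv.assign(group=improv["subject_id"].map(subj_groups))
    panels = [g for g in ("pianist", "non_pianist") if (improv["group"] == g).any()]
    if len(panels) < 2:
        log.warning("one group empty; channel figure degrades to %d panel(s)", len(panels) + 1)
    fig, axes = plt.subplots(1, len(panels) + 1, figsize=(4 * (len(panels) + 1), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, g in zip(axes, panels):
        sub = improv[improv["group"] == g]
        means = sub.groupby("channel")["mean_error"].mean()
        sds = sub.groupby("channel")["mean_error"].std().fillna(0.0)
        ax.bar(means.index, means.to_numpy(), yerr=sds.to_numpy(), color="tab:blue")
        ax.set_title(g)
        ax.set_xlabel("channel")
    means = improv.groupby("channel")["mean_error"].mean()
    sds = improv.groupby("channel")["mean_error"].std().fillna(0.0)
    axes[-1].bar(means.index, means.to_numpy(), yerr=sds.to_numpy(), color="tab:gray")
    axes[-1].set_title("overall")
    axes[-1].set_xlabel("channel")
    axes[0].set_ylabel("mean reconstruction error")
    fig.tight_layout()
    chan_path = outdir / "channel_errors.png"
    fig.savefig(chan_path, dpi=120)
    plt.close(fig)
    written.append(chan_path)
    return written


def _manifest_like(report: AnalysisReport) -> pd.DataFrame:
    return report.comparison.summaries[["subject_id", "group"]]


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (keys mirror the dataclasses)."""
    from .synthetic import EffectSpec, NoiseParams, TaskTiming

    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort = None
    if "cohort" in raw:
        c = dict(raw.pop("cohort") or {})
        if "timing" in c:
            c["timing"] = TaskTiming(**c["timing"])
        if "noise" in c:
            n = dict(c["noise"])
            if "osc_components" in n:
                n["osc_components"] = tuple(tuple(p) for p in n["osc_components"])
            c["noise"] = NoiseParams(**n)
        if "effect" in c:
            e = dict(c["effect"])
            if "target_channels" in e:
                e["target_channels"] = tuple(e["target_channels"])
            c["effect"] = EffectSpec(**e)
        cohort = CohortConfig(**c)
    train = TrainConfig(**(raw.pop("train", {}) or {}))
    for key in ("window_candidates", "roi_channels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(cohort=cohort, train=train, **raw)
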