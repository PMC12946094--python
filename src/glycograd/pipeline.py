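"""End-to-end orchestration: simulate/ingest → preprocess → gradients →
classify → metrics, as a configured, logged, reproducible run.

A run executes every stage for each participant and analysis width, then
reduces the classified events to per-participant confusion matrices, the
performance-metric tables, cross-participant aggregates, and the
consistency tests (exact Wilcoxon signed-rank on correct vs incorrect
classifications per participant; Mann–Whitney U ignoring pairing).  All
outputs are plain CSV/JSON plus a manifest holding the config hash, the
seed, and row counts at every stage; identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, GlycogradError
from .gradients import classify_pa, compute_baseline, compute_gradients
from .hypotheses import HYPOTHESES, Epsilon, build_instants, classify
from .metrics import (ConfusionMatrix, aggregate_metrics, confusion,
                      mann_whitney_exact, performance, wilcoxon_exact)
from .preprocess import (STANDARD_WIDTHS, clean_epochs, merge_streams,
                         read_actigraphy, read_cgm, resample_activity,
                         resample_glucose)
from .synthetic import SimConfig, generate_participant

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("accuracy", "precision", "sensitivity", "specificity", "f1", "mcc")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run.

    Either ``sim`` (synthetic mode, with ``n_participants`` seeded
    participants) or parallel ``actigraphy_paths``/``cgm_paths`` (real-data
    mode) must be provided.
    """

    sim: SimConfig | None = None
    n_participants: int = 8
    actigraphy_paths: tuple[str, ...] = ()
    cgm_paths: tuple[str, ...] = ()
    widths: tuple[int, ...] = STANDARD_WIDTHS
    gradient_basis: str = "level"
    baseline_basis: str = "activity_std"
    eps: float = 0.005
    out_dir: str = "glyco_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.widths:
            raise ConfigurationError("widths: at least one analysis width is required")
        bad = [w for w in self.widths if w not in STANDARD_WIDTHS]
        if bad:
            raise ConfigurationError(f"widths: {bad} not in {STANDARD_WIDTHS}")
        real = bool(self.actigraphy_paths or self.cgm_paths)
        if real and self.sim is not None:
            raise ConfigurationError("provide either sim or real-data paths, not both")
        if not real and self.sim is None:
            raise ConfigurationError("either sim or real-data paths must be set")
        if real and len(self.actigraphy_paths) != len(self.cgm_paths):
            raise ConfigurationError(
                "actigraphy_paths and cgm_paths must pair up one participant each")
        if self.sim is not None and self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")


def participant_seed(base_seed: int, index: int) -> int:
    """Stable per-participant seed derived from the run seed (< 2**31)."""
    return (base_seed * 1_000_003 + 7_919 * index + 1) % (2 ** 31)


def analyze_participant(epochs: pd.DataFrame, cgm: pd.DataFrame, *,
                        participant_id: str, widths=STANDARD_WIDTHS,
                        gradient_basis: str = "level",
                        baseline_basis: str = "activity_std",
                        eps: float = 0.005) -> tuple[pd.DataFrame, dict]:
    """Run the per-participant stages; returns (events, stage row counts)."""
    tol = Epsilon(eps)
    cleaned = clean_epochs(epochs)
    counts = {"epochs_raw": len(epochs), "epochs_clean": len(cleaned),
              "cgm": len(cgm)}
    all_events = []
    for width in widths:
        pa = resample_activity(cleaned, width)
        bg = resample_glucose(cgm, width)
        merged = merge_streams(pa, bg)
        grads = compute_gradients(merged, basis=gradient_basis)
        baseline = compute_baseline(
            grads if baseline_basis == "activity_gradient" else merged,
            baseline_basis, participant_id=participant_id)
        categories = classify_pa(
            grads if baseline_basis == "activity_gradient" else merged, baseline)
        instants = build_instants(grads)
        counts[f"merged_w{width}"] = len(merged)
        counts[f"gradients_w{width}"] = len(grads)
        counts[f"instants_w{width}"] = len(instants)
        for hyp in HYPOTHESES:
            events = classify(instants, categories, hyp, tol)
            events.insert(0, "participant", participant_id)
            all_events.append(events)
    non_empty = [e for e in all_events if not e.empty]
    events = (pd.concat(non_empty, ignore_index=True) if non_empty
              else all_events[0])
    counts["events"] = len(events)
    return events, counts


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _percent_table(perf: pd.DataFrame, hypothesis: str, width: int) -> pd.DataFrame:
    sub = perf[(perf["hypothesis"] == hypothesis)
               & (perf["width_minutes"] == width)]
    out = pd.DataFrame({
        "ID": sub["participant"],
        "Accuracy": (100 * sub["accuracy"]).round(2),
        "Precision": (100 * sub["precision"]).round(2),
        "Sensitivity": (100 * sub["sensitivity"]).round(2),
        "Specificity": (100 * sub["specificity"]).round(2),
    })
    return out.reset_index(drop=True)


def _nan_to_none(x):
    return None if isinstance(x, float) and math.isnan(x) else x


def run(config: RunConfig) -> dict:
    """Execute a full run; returns (and writes) the manifest."""
    logging.getLogger("glycograd").setLevel(config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_stages(config, out_dir, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _write_csv(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")
    written.append(path)


def _write_json(obj, path: Path, written: list[Path]) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    written.append(path)


def _run_stages(config: RunConfig, out_dir: Path, written: list[Path]) -> dict:
    stage = "setup"
    try:
        # ---- ingest or simulate ---------------------------------------
        stage = "ingest"
        participants = []
        if config.sim is not None:
            for i in range(config.n_participants):
                pid = f"P{i + 1:02d}"
                sim_i = dataclasses.replace(
                    config.sim, seed=participant_seed(config.seed, i))
                epochs, cgm, _ = generate_participant(sim_i)
                participants.append((pid, epochs, cgm))
        else:
            for i, (apath, cpath) in enumerate(zip(config.actigraphy_paths,
                                                   config.cgm_paths)):
                pid = f"P{i + 1:02d}"
                participants.append((pid, read_actigraphy(apath), read_cgm(cpath)))

        # ---- per-participant pipeline ---------------------------------
        stage = "classify"
        all_events = []
        stage_counts = {}
        for pid, epochs, cgm in participants:
            events, counts = analyze_participant(
                epochs, cgm, participant_id=pid, widths=config.widths,
                gradient_basis=config.gradient_basis,
                baseline_basis=config.baseline_basis, eps=config.eps)
            all_events.append(events)
            stage_counts[pid] = counts
        events = pd.concat(all_events, ignore_index=True)
        for width in config.widths:
            _write_csv(events[events["width_minutes"] == width],
                       out_dir / f"events_w{width}.csv", written)

        # ---- confusion + performance ----------------------------------
        stage = "metrics"
        cms = confusion(events, ("participant", "hypothesis", "width_minutes"))
        perf_rows = []
        for _, row in cms.iterrows():
            cm = ConfusionMatrix(int(row.tp), int(row.tn), int(row.fp), int(row.fn))
            ms = performance(cm)
            perf_rows.append({"participant": row.participant,
                              "hypothesis": row.hypothesis,
                              "width_minutes": int(row.width_minutes),
                              "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn,
                              **{m: getattr(ms, m) for m in METRIC_COLUMNS}})
        perf = pd.DataFrame(perf_rows)
        _write_csv(perf, out_dir / "performance.csv", written)
        for hyp in HYPOTHESES:
            for width in config.widths:
                _write_csv(_percent_table(perf, hyp, width),
                           out_dir / f"metrics_{hyp}_{width}.csv", written)

        # ---- aggregates ------------------------------------------------
        stage = "aggregate"
        aggregate = {}
        for hyp in HYPOTHESES:
            sub = perf[perf["hypothesis"] == hyp]
            block = {}
            for metric in METRIC_COLUMNS:
                values = sub[metric].dropna()
                if values.empty:
                    continue
                scale = 1.0 if metric == "mcc" else 100.0
                summary = aggregate_metrics(scale * values)
                block[metric] = {k: _nan_to_none(v)
                                 for k, v in dataclasses.asdict(summary).items()}
            pooled = (sub.groupby("participant")[["tp", "tn", "fp", "fn"]].sum())
            block["pooled_counts_mean_std"] = {
                k: {"mean": float(pooled[k].mean()),
                    "std": _nan_to_none(float(pooled[k].std(ddof=1)))}
                for k in ("tp", "tn", "fp", "fn")}
            aggregate[hyp] = block
        _write_json(aggregate, out_dir / "aggregate_report.json", written)

        # ---- consistency tests ----------------------------------------
        stage = "consistency"
        consistency = {}
        for scope, sub in [("H1", perf[perf["hypothesis"] == "H1"]),
                           ("H2", perf[perf["hypothesis"] == "H2"]),
                           ("pooled", perf)]:
            by_p = sub.groupby("participant")[["tp", "tn", "fp", "fn"]].sum()
            correct = (by_p["tp"] + by_p["tn"]).to_numpy(float)
            incorrect = (by_p["fp"] + by_p["fn"]).to_numpy(float)
            entry = {}
            if len(by_p) >= 2 and (correct != incorrect).any():
                w = wilcoxon_exact(correct, incorrect)
                u = mann_whitney_exact(correct, incorrect)
                entry = {"wilcoxon": {"W": w.statistic, "p": w.p_value,
                                      "rank_biserial": w.effect_size,
                                      "method": w.method, "n": w.n},
                         "mann_whitney": {"U": u.statistic, "p": u.p_value,
                                          "method": u.method, "n": u.n}}
            consistency[scope] = entry
        _write_json(consistency, out_dir / "consistency_report.json", written)

        # ---- manifest --------------------------------------------------
        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "widths": list(config.widths),
            "n_participants": len(participants),
            "stage_counts": stage_counts,
            "n_events": int(len(events)),
            "outputs": sorted([p.name for p in written] + ["manifest.json"]),
        }
        _write_json(manifest, out_dir / "manifest.json", written)
        return manifest
    except GlycogradError as err:
        raise type(err)(f"stage {stage!r}: {err}") from err


def render_report(out_dir) -> list[Path]:
    """Render F1 bar charts and MCC box plots from a completed run.

    The numbers plotted are read back from the run's CSV outputs, so the
    figures equal the tables exactly.  Groups whose MCC is undefined are
    omitted from the box plots and noted in the caption.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    perf_path = out_dir / "performance.csv"
    manifest_path = out_dir / "manifest.json"
    missing = [str(p) for p in (perf_path, manifest_path) if not p.exists()]
    if missing:
        raise GlycogradError(f"render_report: missing inputs {missing}")
    perf = pd.read_csv(perf_path)
    widths = sorted(perf["width_minutes"].unique())
    figures = []
    for hyp in HYPOTHESES:
        sub = perf[perf["hypothesis"] == hyp]
        if sub.empty:
            continue
        # F1 bars by participant x width
        fig, ax = plt.subplots(figsize=(8, 4))
        pids = sorted(sub["participant"].unique())
        x = np.arange(len(pids))
        bar_w = 0.8 / len(widths)
        for j, width in enumerate(widths):
            s = (sub[sub["width_minutes"] == width]
                 .set_index("participant")["f1"].reindex(pids))
            ax.bar(x + j * bar_w, s.to_numpy(), bar_w, label=f"{width} min")
        ax.set_xticks(x + 0.4 - bar_w / 2, pids, rotation=45)
        ax.set_ylabel("F1 score")
        ax.set_title(f"F1 by participant, hypothesis {hyp}")
        ax.legend()
        path = out_dir / f"f1_{hyp}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures.append(path)
        # MCC box plot by width
        fig, ax = plt.subplots(figsize=(6, 4))
        data, labels, dropped = [], [], 0
        for width in widths:
            vals = sub.loc[sub["width_minutes"] == width, "mcc"].dropna()
            dropped += int(sub[sub["width_minutes"] == width]["mcc"].isna().sum())
            if len(vals):
                data.append(vals.to_numpy())
                labels.append(f"{width} min")
        if data:
            ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("MCC")
        caption = f"MCC by window width, hypothesis {hyp}"
        if dropped:
            caption += f" ({dropped} undefined group(s) omitted)"
        ax.set_title(caption)
        path = out_dir / f"mcc_{hyp}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures.append(path)
    return figures
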