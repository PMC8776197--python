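"""End-to-end orchestration: simulate -> extract -> classify -> report.

Each stage is a plain function over a resolved config mapping (see
:mod:`eegscape.config`); the command-line interface wraps these thinly.
Every stage writes a resolved-config snapshot and per-stage counts so a run
is reproducible from its output directory alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from eegscape import io as eio
from eegscape.classify import (ClassifierSpec, best_per_subject, evaluate_grid)
from eegscape.config import dump_config, montage_from_config
from eegscape.errors import DataError
from eegscape.features import BandScheme, extract_all
from eegscape.preprocess import preprocess_recording
from eegscape.simulate import (NoiseModel, default_signatures, generate_subject,
                               make_schedule)

log = logging.getLogger("eegscape")


def _band_scheme(cfg: dict) -> BandScheme:
    return BandScheme(bands={k: tuple(v) for k, v in cfg["features"]["bands"].items()})


def _specs(cfg: dict) -> list[ClassifierSpec]:
    c = cfg["classify"]
    table = {
        "knn": {"k": c["knn_k"]},
        "rf": {"trees": c["rf_trees"]},
        "svm": {"kernel": c["svm_kernel"], "C": c["svm_C"]},
        "bp": {"hidden": (c["bp_hidden"],), "max_iter": c["bp_max_iter"]},
    }
    return [ClassifierSpec(kind, table[kind]) for kind in c["classifiers"]]


def run_simulate(cfg: dict, out_dir, n_subjects: int | None = None,
                 seed: int | None = None) -> list[Path]:
    """Generate the synthetic study and write one EDF + events TSV per subject."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    s = cfg["synthetic_eeg"]
    n = n_subjects if n_subjects is not None else s["n_subjects"]
    base_seed = seed if seed is not None else s["base_seed"]
    montage = montage_from_config(cfg)
    signatures = default_signatures(montage, effect_size=s["effect_size"],
                                    asymmetry=s["asymmetry"])
    noise = NoiseModel(**s["noise"])
    dump_config(cfg, out_dir / "config_resolved.yaml")

    paths = []
    for i in range(n):
        sched = make_schedule(base_seed + i, **s["schedule"])
        rec = generate_subject(sched, signatures, noise, montage,
                               rate_hz=s["rate_hz"], seed=base_seed * 1000 + i,
                               band_rms_uv=s["band_rms_uv"],
                               gain_jitter=s["gain_jitter"], subject_id=i)
        edf = eio.write_edf(rec, out_dir / f"sub-{i:02d}.edf")
        eio.write_events_tsv(rec, out_dir / f"sub-{i:02d}_events.tsv")
        log.info("subject %d: wrote %s (%.0f s, %d channels)", i, edf.name,
                 rec.duration_s, rec.samples.shape[0])
        paths.append(edf)
    return paths


def run_extract(cfg: dict, in_dir, out_dir) -> list[Path]:
    """Preprocess every recording in ``in_dir`` and write its feature table."""
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recs = sorted(in_dir.glob("sub-*.edf")) + sorted(in_dir.glob("sub-*.vhdr"))
    if not recs:
        raise DataError(f"no recordings (sub-*.edf / sub-*.vhdr) found in {in_dir}")
    montage = montage_from_config(cfg)
    bands = _band_scheme(cfg)
    p = cfg["preprocess"]
    dump_config(cfg, out_dir / "config_resolved.yaml")

    paths, counts = [], []
    for path in recs:
        subject_id = int("".join(ch for ch in path.stem.split("_")[0] if ch.isdigit()))
        events = path.with_name(path.stem + "_events.tsv")
        if not events.exists():
            raise DataError(f"missing events file for subject {subject_id}: {events}")
        rec = eio.read_recording(path, events_path=events, subject_id=subject_id)
        epochs = preprocess_recording(rec, montage, artifact_method=p["artifact_method"],
                                      reject_uv=p["reject_uv"], lo_hz=p["lo_hz"],
                                      hi_hz=p["hi_hz"], seed=subject_id)
        if not epochs:
            log.warning("subject %d: all epochs rejected", subject_id)
        tensor = extract_all(epochs, montage, bands,
                             de_backend=cfg["features"]["de_backend"])
        out = eio.write_feature_tensor(tensor, out_dir / f"sub-{subject_id:02d}_features.tsv")
        log.info("subject %d: %d epochs retained", subject_id, len(epochs))
        counts.append({"subject_id": subject_id, "epochs_retained": len(epochs)})
        paths.append(out)
    pd.DataFrame(counts).to_csv(out_dir / "epoch_counts.tsv", sep="\t", index=False)
    return paths


def run_classify(cfg: dict, features_dir, out_dir) -> dict[str, Path]:
    """Evaluate the full grid over all subjects' feature tables; write grid + summary."""
    features_dir, out_dir = Path(features_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = sorted(features_dir.glob("sub-*_features.tsv"))
    if not files:
        raise DataError(f"no feature tables found in {features_dir}")
    tensors = [eio.read_feature_tensor(f) for f in files]
    c = cfg["classify"]
    grid = evaluate_grid(tensors, _specs(cfg), families=c["families"],
                         bands=c["bands"], protocol=c["protocol"], seed=c["seed"])
    dump_config(cfg, out_dir / "config_resolved.yaml")
    paths = eio.write_grid(grid, out_dir)
    best = best_per_subject(grid, by="classifier")
    best_path = out_dir / "best_per_subject.tsv"
    best.to_csv(best_path, sep="\t", index=False, float_format="%.6f")
    paths["best"] = best_path
    paths["summary"] = _write_summary(grid, out_dir / "summary.txt")
    return paths


def _write_summary(grid, path) -> Path:
    """Human-readable ranking of classifiers and bands by aggregate accuracy."""
    agg = grid.aggregate()
    lines = ["Aggregate decoding summary", "=" * 26, ""]
    by_clf = agg.groupby("classifier")["mean_accuracy"].mean().sort_values(ascending=False)
    lines.append("Classifiers ranked by mean accuracy over all cells:")
    for k, v in by_clf.items():
        lines.append(f"  {k:>4s}: {100 * v:6.2f}%")
    by_band = agg.groupby("band")["mean_accuracy"].mean().sort_values(ascending=False)
    lines.append("")
    lines.append("Bands ranked by mean accuracy over all cells:")
    for k, v in by_band.items():
        lines.append(f"  {k:>5s}: {100 * v:6.2f}%")
    top = agg.sort_values("mean_accuracy", ascending=False).head(5)
    lines.append("")
    lines.append("Top cells (family/band/classifier):")
    for _, r in top.iterrows():
        sd = f" ± {100 * r.sd_accuracy:.2f}" if np.isfinite(r.sd_accuracy) else ""
        lines.append(f"  {r.family}/{r.band}/{r.classifier}: {100 * r.mean_accuracy:.2f}%{sd}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def simulate_and_extract(n_subjects: int, base_seed: int = 0, effect_size: float = 1.0,
                         asymmetry: float = 0.1, noise=None, artifact_method: str = "none",
                         montage=None, gain_jitter: float = 0.1):
    """Generate a scaled study in memory and return one FeatureTensor per subject.

    The default noise model here is artifact-free (no blinks, no line noise)
    so that epoch bookkeeping is exact; pass a NoiseModel to exercise the
    artifact pipeline.
    """
    from eegscape.montage import default_montage
    from eegscape.simulate import NoiseModel as NM

    montage = montage or default_montage()
    noise = noise if noise is not None else NM(blink_rate_per_min=0.0, line_amp_uv=0.0)
    signatures = default_signatures(montage, effect_size=effect_size, asymmetry=asymmetry)
    tensors = []
    for i in range(n_subjects):
        sched = make_schedule(base_seed + i)
        rec = generate_subject(sched, signatures, noise, montage,
                               seed=base_seed * 1000 + i, subject_id=i,
                               gain_jitter=gain_jitter)
        epochs = preprocess_recording(rec, montage, artifact_method=artifact_method,
                                      seed=i)
        tensors.append(extract_all(epochs, montage))
    return tensors


def plot_accuracy_by_band(agg: pd.DataFrame, path) -> Path:
    """Bar chart of aggregate accuracy per band, grouped by classifier."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = agg.pivot_table(index="band", columns="classifier",
                            values="mean_accuracy", aggfunc="mean", sort=False)
    ax = pivot.plot.bar(rot=0, figsize=(7, 4))
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1)
    ax.axhline(1 / 7, color="grey", ls="--", lw=1, label="chance (1/7)")
    ax.legend(fontsize=8)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
    return Path(path)


def run_report(grid_aggregate_path, out=None, plot=None) -> str:
    """Render the aggregate grid as a family x band accuracy matrix per classifier."""
    agg = eio.read_grid_aggregate(grid_aggregate_path)
    agg = agg.copy()
    agg["formatted"] = agg.apply(
        lambda r: f"{100 * r.mean_accuracy:.2f} ± {100 * r.sd_accuracy:.2f}"
        if "sd_accuracy" in agg.columns and np.isfinite(r.get("sd_accuracy", np.nan))
        else f"{100 * r.mean_accuracy:.2f}", axis=1)
    table = agg.pivot_table(index=["family", "classifier"], columns="band",
                            values="formatted", aggfunc="first", sort=False)
    text = table.to_string()
    cells_path = Path(grid_aggregate_path).with_name(
        Path(grid_aggregate_path).name.replace("_aggregate", "_cells"))
    if cells_path.exists():
        cells = pd.read_csv(cells_path, sep="\t")
        best = cells.loc[cells.groupby("subject_id")["accuracy"].idxmax()]
        lines = ["", "", "Per-subject best cells:"]
        for _, r in best.iterrows():
            lines.append(f"  subject {int(r.subject_id):2d}: {100 * r.accuracy:6.2f}%  "
                         f"({r.family}/{r.band}/{r.classifier})")
        text += "\n".join(lines)
    if plot is not None:
        plot_accuracy_by_band(agg, plot)
    if out is not None:
        Path(out).write_text(text + "\n")
    return text


def run_all(cfg: dict, out_dir, n_subjects: int | None = None,
            seed: int | None = None) -> dict[str, Path]:
    """simulate -> extract -> classify -> report under one output directory."""
    out_dir = Path(out_dir)
    raw = out_dir / "raw"
    feats = out_dir / "features"
    res = out_dir / "grid"
    run_simulate(cfg, raw, n_subjects=n_subjects, seed=seed)
    run_extract(cfg, raw, feats)
    paths = run_classify(cfg, feats, res)
    report_path = res / "report.txt"
    run_report(paths["aggregate"], out=report_path)
    paths["report"] = report_path
    return paths
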