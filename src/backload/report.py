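"""Rendered summary of an experiment run: markdown tables plus figure analogs."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _fig_sweep(sweep_csv: Path, figdir: Path) -> str | None:
    if not sweep_csv.exists():
        return None
    df = pd.read_csv(sweep_csv)
    best = df[df["best_per_size"]].sort_values("size")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(df["size"] + np.random.default_rng(0).uniform(-0.12, 0.12, len(df)),
            df["r2_mean"], "o", color="0.7", ms=4, label="all subsets")
    ax.plot(best["size"], best["r2_mean"], "o-", color="tab:orange", label="best per size")
    ax.set_xlabel("number of sensor locations")
    ax.set_ylabel("mean held-out $r^2$")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    out = figdir / "sweep_accuracy.png"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out.name


def _fig_scatter(pred_parquet: Path, figdir: Path) -> str | None:
    if not pred_parquet.exists():
        return None
    df = pd.read_parquet(pred_parquet)
    pred_cols = [c for c in df.columns if c.startswith("pred_")]
    if not pred_cols:
        return None
    col = "pred_trunk+insole" if "pred_trunk+insole" in pred_cols else pred_cols[0]
    n = min(len(df), 20000)
    idx = np.random.default_rng(0).choice(len(df), n, replace=False)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(df["y_true"].iloc[idx], df[col].iloc[idx], ".", ms=1, alpha=0.3)
    lim = (df["y_true"].min(), df["y_true"].max())
    ax.plot(lim, lim, "k-", lw=0.8)
    ax.set_xlabel("lab-based moment (BW x BH)")
    ax.set_ylabel("wearable estimate (BW x BH)")
    ax.set_title(col.removeprefix("pred_"), fontsize=9)
    fig.tight_layout()
    out = figdir / "scatter_lab_vs_wearable.png"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out.name


def _fig_importance(importance_csv: Path, figdir: Path) -> str | None:
    if not importance_csv.exists():
        return None
    df = pd.read_csv(importance_csv).head(10)[::-1]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.barh(df["channel"], df["delta_r2"], xerr=df["delta_r2_sd"], color="tab:orange")
    ax.set_xlabel(r"signal importance ($\Delta r^2$)")
    fig.tight_layout()
    out = figdir / "signal_importance.png"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out.name


def render_report(outdir: str | Path, config) -> Path:
    outdir = Path(outdir)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    figs = [
        _fig_scatter(outdir / "cv_predictions.parquet", figdir),
        _fig_sweep(outdir / "sweep.csv", figdir),
        _fig_importance(outdir / "importance.csv", figdir),
    ]

    lines = ["# Lumbar-load monitoring run report", ""]
    lines.append(f"- target: **{config.target}**; features: **{config.features.provenance}**; "
                 f"seed: {config.seed}")
    metrics = outdir / "cv_metrics.json"
    if metrics.exists():
        data = json.loads(metrics.read_text())
        lines += ["", "## Held-out accuracy by sensor subset", "",
                  "| subset | mean r2 | RMSE (Nm) | MAPE (%) |", "|---|---|---|---|"]
        for name, row in data["subsets"].items():
            lines.append(f"| {name} | {row['r2_mean']:.3f} | {row['rmse_nm']:.1f} | "
                         f"{row['mape_pct']:.1f} |")
    evaluation = outdir / "evaluation.json"
    if evaluation.exists():
        data = json.loads(evaluation.read_text())
        lines += ["", "## Trunk IMU vs trunk IMU + insoles", "",
                  f"- mean r2: {data['trunk_r2']['mean']:.3f} -> "
                  f"{data['trunk_insole_r2']['mean']:.3f} "
                  f"(Wilcoxon p = {data['wilcoxon_p_trunk_vs_trunk_insole']:.4g})",
                  f"- most important channels: {', '.join(data['top_channels'])}"]
    lines += ["", "## Figures", ""]
    lines += [f"![{f}](figures/{f})" for f in figs if f]
    report = outdir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
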