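"""Exhaustive sensor-location subset sweep.

Six candidate sensor locations (trunk, pelvis, thigh, shank, foot IMUs and
the pressure insoles, bilateral locations worn as symmetric pairs) give 62
reduced subsets of size 1-5 plus the full distributed set: 63 pipelines,
each trained and evaluated under leave-one-subject-out CV.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anthropometry import Anthropometry
from .estimator import GbdtConfig, loso_cv
from .evaluate import accuracy_report
from .features import CANONICAL_LOCATIONS, FeatureMatrix, subset_features

logger = logging.getLogger(__name__)

__all__ = ["enumerate_subsets", "run_sweep", "SweepTable"]


def enumerate_subsets(locations=CANONICAL_LOCATIONS) -> list[tuple[str, ...]]:
    """All non-empty subsets of the six locations: 62 reduced + the full set.

    Ordered by size then lexicographically; deterministic.
    """
    locations = tuple(locations)
    if len(set(locations)) != len(locations):
        raise ValueError("duplicate location tokens")
    if sorted(locations) != sorted(CANONICAL_LOCATIONS):
        raise ValueError("expected exactly the 6 canonical sensor locations")
    out: list[tuple[str, ...]] = []
    for size in range(1, len(locations) + 1):
        out.extend(sorted(itertools.combinations(sorted(locations), size)))
    return out


@dataclass
class SweepTable:
    """Per-subset accuracy rows plus per-participant r² detail."""

    table: pd.DataFrame  # subset, size, n_channels, r2_mean, rmse_*, mape_pct, best_per_size
    per_participant: dict[str, dict[str, float]]  # subset name -> pid -> r2

    def best_per_size(self) -> pd.DataFrame:
        return self.table[self.table["best_per_size"]].reset_index(drop=True)

    def row(self, subset) -> pd.Series:
        name = "+".join(subset) if not isinstance(subset, str) else subset
        match = self.table[self.table["subset"] == name]
        if match.empty:
            raise KeyError(name)
        return match.iloc[0]

    def to_markdown(self) -> str:
        cols = ["subset", "size", "n_channels", "r2_mean", "rmse_nm", "mape_pct", "best_per_size"]
        lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
        for _, r in self.table.iterrows():
            lines.append(
                f"| {r['subset']} | {r['size']} | {r['n_channels']} | "
                f"{r['r2_mean']:.3f} | {r['rmse_nm']:.1f} | {r['mape_pct']:.1f} | "
                f"{'*' if r['best_per_size'] else ''} |")
        return "\n".join(lines)


def run_sweep(
    fm: FeatureMatrix,
    y: np.ndarray,
    cohort: list[Anthropometry],
    subsets: list[tuple[str, ...]] | None = None,
    config: GbdtConfig | None = None,
    stride: int = 1,
) -> SweepTable:
    """Train/evaluate the LOSO pipeline for every sensor subset.

    ``stride`` decimates samples for the sweep fits (per-sample model, so
    this only shrinks the problem size).  A failing subset is logged and
    skipped rather than aborting the sweep.
    """
    subsets = subsets if subsets is not None else enumerate_subsets()
    if stride > 1:
        rows = np.arange(0, fm.n_samples, stride)
        fm = fm.rows(rows)
        y = np.asarray(y)[rows]

    records = []
    per_participant: dict[str, dict[str, float]] = {}
    for subset in subsets:
        name = "+".join(subset)
        try:
            sub = subset_features(fm, subset)
            cv = loso_cv(sub, y, config, keep_models=False)
            rep = accuracy_report(cv, cohort)
        except Exception:  # noqa: BLE001 - one bad row must not kill the sweep
            logger.exception("sweep row %s failed", name)
            continue
        records.append({
            "subset": name,
            "size": len(subset),
            "n_channels": len(sub.channels),
            "r2_mean": rep.r2_mean,
            "rmse_bwbh": rep.rmse_bwbh,
            "rmse_nm": rep.rmse_nm,
            "mape_pct": rep.mape_pct,
        })
        per_participant[name] = rep.r2_per_participant

    df = pd.DataFrame.from_records(records)
    # best per size: ties broken by fewer channels, then subset name
    df["best_per_size"] = False
    for size, grp in df.groupby("size"):
        best = grp.sort_values(
            ["r2_mean", "n_channels", "subset"], ascending=[False, True, True]).index[0]
        df.loc[best, "best_per_size"] = True
    return SweepTable(table=df.reset_index(drop=True), per_participant=per_participant)
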