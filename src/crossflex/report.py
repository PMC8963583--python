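"""Tabular and JSON rendering of study results.

Machine-readable output (JSON) keeps full precision; the human tables round
to one decimal at render time only, and scores are always computed from the
unrounded M/A values before rounding.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .crossover import StudyReport
from .trajectory_metrics import DistanceSeries, FluctuationProfile, RmsdSeries


def series_frame(series: RmsdSeries) -> pd.DataFrame:
    return pd.DataFrame({"frame": np.arange(len(series)), "rmsd_A": series.values})


def series_summary(series: RmsdSeries) -> dict:
    return {
        "reference": series.reference_label,
        "selection": series.selection_label,
        "n_frames": len(series),
        "mean_A": series.mean,
        "sd_A": series.sd,
        "min_A": series.min,
        "max_A": series.max,
        "rms_A": series.rms,
    }


def profile_frame(profile: FluctuationProfile) -> pd.DataFrame:
    return pd.DataFrame({
        "chain": [c for c, _ in profile.residues],
        "resnum": [r for _, r in profile.residues],
        "rmsf_A": profile.rmsf,
    })


def distance_frame(series: DistanceSeries) -> pd.DataFrame:
    return pd.DataFrame({"frame": np.arange(len(series.values)),
                         "min_distance_A": series.values})


def reference_table(report: StudyReport, round_to: int | None = 1) -> pd.DataFrame:
    """Mean RMSD of every system against both crystal references."""
    data = {
        crystal: [report.reference_series[(system, crystal)].mean
                  for system in report.system_labels]
        for crystal in report.crystal_labels
    }
    frame = pd.DataFrame(data, index=list(report.system_labels))
    frame.index.name = "system"
    return frame.round(round_to) if round_to is not None else frame


def movement_table(report: StudyReport, round_to: int | None = None) -> pd.DataFrame:
    """Movement RMSD M with SD, min and max per system."""
    rows = []
    for system in report.system_labels:
        series = report.movement[system]
        rows.append({"system": system, "M_A": series.mean, "SD_A": series.sd,
                     "min_A": series.min, "max_A": series.max})
    frame = pd.DataFrame(rows).set_index("system")
    if round_to is not None:
        frame = frame.round(round_to)
    return frame


def pair_table(report: StudyReport, round_to: int | None = 1) -> pd.DataFrame:
    """The six pairwise scores, ascending (most similar dynamics first)."""
    rows = [{
        "system1": p.system1, "system2": p.system2,
        "M1_A": p.M1, "M2_A": p.M2, "A1_A": p.A1, "A2_A": p.A2,
        "score_A": p.score,
    } for p in report.pair_scores]
    frame = pd.DataFrame(rows)
    return frame.round(round_to) if round_to is not None else frame


def interpretation_table(report: StudyReport) -> pd.DataFrame:
    rows = [{
        "system": row.system_label,
        "closest_crystal": row.reference_crystal,
        "mean_rmsd_A": round(row.similarity, 2),
        "verdict": row.verdict,
    } for row in report.interpretations]
    return pd.DataFrame(rows).set_index("system")


def study_json(report: StudyReport) -> dict:
    """Full-precision machine-readable study report."""
    return {
        "selection": report.selection_label,
        "fit": report.fit,
        "systems": list(report.system_labels),
        "crystals": list(report.crystal_labels),
        "reference_rmsd": {
            f"{system}|{crystal}": series_summary(series)
            for (system, crystal), series in report.reference_series.items()
        },
        "movement": {
            system: series_summary(series)
            for system, series in report.movement.items()
        },
        "pair_scores": [
            {"system1": p.system1, "system2": p.system2,
             "M1": p.M1, "M2": p.M2, "A1": p.A1, "A2": p.A2,
             "score": p.score, "score_rounded": p.rounded()}
            for p in report.pair_scores
        ],
        "interpretations": [
            {"system": row.system_label, "closest_crystal": row.reference_crystal,
             "mean_rmsd": row.similarity, "verdict": row.verdict}
            for row in report.interpretations
        ],
    }


def write_study(report: StudyReport, out_dir) -> None:
    """Write the TSV tables and the JSON report into ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference_table(report).to_csv(out / "reference_rmsd.tsv", sep="\t")
    movement_table(report, round_to=None).round(2).to_csv(out / "movement_rmsd.tsv", sep="\t")
    pair_table(report).to_csv(out / "pair_scores.tsv", sep="\t", index=False)
    interpretation_table(report).to_csv(out / "interpretation.tsv", sep="\t")
    with open(out / "report.json", "w") as handle:
        json.dump(study_json(report), handle, indent=2, sort_keys=True)
        handle.write("\n")
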