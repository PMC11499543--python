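"""Per-subject score trajectories and report figures.

Assembles, per subject and panel, the time-ordered sequence of panel scores
from ex-vivo blood draws (in-vitro assay aliquots are excluded — they belong
to the stimulation analysis), together with therapy intervals, infusion
dates, clinical event labels and the healthy reference band.  The report
renderer draws one score-vs-time figure per subject and panel in the style
used for interferon-signature monitoring — log-scale score line over a shaded
healthy band, therapy ribbons, vertical infusion markers — and writes a
cohort summary CSV (baseline score, latest score, fold-change, fraction of
points inside the band).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .rcc import SampleAnnotation, TherapyRecord, annotations_by_id
from .scoring import ReferenceStats


class TrajectoryError(ValueError):
    pass


@dataclass
class Trajectory:
    subject_id: str
    panel: str
    points: pd.DataFrame  # date-ordered: sample_id, date, geomean_score, z_score, batch
    therapy_intervals: tuple[TherapyRecord, ...] = ()
    infusion_dates: tuple[dt.date, ...] = ()
    events: tuple[tuple[dt.date, str], ...] = ()
    band: tuple[float, float] | None = None
    unanchored_infusions: tuple[dt.date, ...] = ()


def _infusions_outside_therapy(
    infusions: Sequence[dt.date], therapy: Sequence[TherapyRecord]
) -> tuple[dt.date, ...]:
    out = []
    for d in infusions:
        covered = any(
            t.start <= d and (t.stop is None or d <= t.stop) for t in therapy
        )
        if not covered:
            out.append(d)
    return tuple(out)


def assemble_trajectories(
    scores: pd.DataFrame,
    annotations: Sequence[SampleAnnotation],
    references: Mapping[str, ReferenceStats] | None = None,
) -> list[Trajectory]:
    """One trajectory per (subject, panel), points ordered by date then
    sample id.  Only ex-vivo samples (stimulation ``none``) contribute."""
    if scores.empty:
        return []
    by_id = annotations_by_id(annotations)
    orphans = sorted(set(scores["sample_id"]) - set(by_id))
    if orphans:
        raise TrajectoryError(f"scores without annotation: {orphans}")
    keep = scores[scores["sample_id"].map(lambda s: by_id[s].stimulation == "none")].copy()
    trajectories = []
    for (subject, panel), grp in keep.groupby(["subject_id", "panel"], sort=True):
        pts = grp.copy()
        pts["date"] = pts["date"].map(dt.date.fromisoformat)
        pts = pts.sort_values(["date", "sample_id"], kind="mergesort").reset_index(drop=True)
        pts = pts[["sample_id", "date", "geomean_score", "z_score", "batch"]]
        subj_anns = [a for a in annotations if a.subject_id == subject]
        therapy: list[TherapyRecord] = []
        infusions: list[dt.date] = []
        events: list[tuple[dt.date, str]] = []
        for a in subj_anns:
            for t in a.therapy:
                if t not in therapy:
                    therapy.append(t)
            for d in a.infusion_dates:
                if d not in infusions:
                    infusions.append(d)
            for e in a.events:
                if e not in events:
                    events.append(e)
        band = None
        if references is not None and panel in references:
            band = references[panel].score_band
        trajectories.append(
            Trajectory(
                subject_id=subject,
                panel=panel,
                points=pts,
                therapy_intervals=tuple(therapy),
                infusion_dates=tuple(sorted(infusions)),
                events=tuple(sorted(events)),
                band=band,
                unanchored_infusions=_infusions_outside_therapy(infusions, therapy),
            )
        )
    return trajectories


def summarize_trajectories(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Cohort summary: per (subject, panel) baseline, latest, fold-change and
    the fraction of points inside the healthy band (NaN without a band)."""
    rows = []
    for t in trajectories:
        if t.points.empty:
            continue
        baseline = float(t.points["geomean_score"].iloc[0])
        latest = float(t.points["geomean_score"].iloc[-1])
        if t.band is not None:
            lo, hi = t.band
            inside = t.points["geomean_score"].between(lo, hi).mean()
        else:
            inside = float("nan")
        rows.append({
            "subject_id": t.subject_id,
            "panel": t.panel,
            "n_points": len(t.points),
            "baseline_score": baseline,
            "latest_score": latest,
            "fold_change": latest / baseline,
            "fraction_in_band": float(inside),
        })
    return pd.DataFrame(
        rows,
        columns=["subject_id", "panel", "n_points", "baseline_score",
                 "latest_score", "fold_change", "fraction_in_band"],
    )


def render_report(
    trajectories: Sequence[Trajectory],
    out_dir: str | Path,
    band_color: str = "0.85",
    infusion_color: str = "#e75480",
    fig_format: str = "svg",
) -> pd.DataFrame:
    """Write one figure per trajectory plus ``summary.csv``; returns the summary."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for t in trajectories:
        fig, ax = plt.subplots(figsize=(7, 3.2))
        if t.band is not None:
            ax.axhspan(t.band[0], t.band[1], color=band_color, zorder=0,
                       label="healthy band")
        for d in t.infusion_dates:
            ax.axvline(d, color=infusion_color, lw=1.0, zorder=1)
        ax.plot(t.points["date"], t.points["geomean_score"], "o-", color="k", zorder=2)
        for d, label in t.events:
            ax.annotate(label, (d, ax.get_ylim()[1]), fontsize=7, rotation=90,
                        va="top", ha="right", color="0.3")
        for rec in t.therapy_intervals:
            stop = rec.stop or (t.points["date"].iloc[-1] if len(t.points) else rec.start)
            ax.axvspan(rec.start, stop, ymin=0.97, ymax=1.0, alpha=0.4,
                       label=f"{rec.drug} {rec.dose}")
        ax.set_yscale("log")
        ax.set_ylabel(f"{t.panel} geomean score")
        ax.set_title(f"{t.subject_id} — {t.panel}")
        fig.autofmt_xdate()
        fig.tight_layout()
        fig.savefig(out_dir / f"{t.subject_id}_{t.panel}.{fig_format}")
        plt.close(fig)
    summary = summarize_trajectories(trajectories)
    summary.to_csv(out_dir / "summary.csv", index=False)
    return summary
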