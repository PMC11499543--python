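"""Panel scores and healthy-reference statistics.

Two per-sample summaries are computed for each endogenous panel (ISG-30,
NF-kB, IFN-gamma):

* geomean score — the geometric mean of normalized counts across the panel
  genes.  For the 30-gene ISG panel this is the single "ISG" number used to
  follow patients over time.
* Z-score — each gene's log-transformed normalized count is standardized
  against its mean and standard deviation in healthy reference donors, and
  the per-gene z values are averaged over the panel.

The healthy references also define a score band (default the 2.5th-97.5th
percentile of healthy geomean scores) used as the normality region in
longitudinal plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panels import GenePanel, PipelineConfig
from .normalize import NormalizedCountMatrix, control_geomeans
from .rcc import SampleAnnotation, annotations_by_id

#: absolute lower bound on a reference standard deviation, applied after the
#: relative floor so that fully degenerate references stay finite
_SD_ABS_FLOOR = 1e-8


class ScoringError(ValueError):
    pass


@dataclass
class ReferenceStats:
    """Healthy-donor reference distribution for one panel.

    ``gene_mean``/``gene_sd`` are per-gene moments of
    log_base(normalized value + pseudocount) across healthy unstimulated
    reference samples; ``score_band`` is a percentile interval of the healthy
    geomean scores.
    """

    panel_name: str
    genes: tuple[str, ...]
    gene_mean: pd.Series
    gene_sd: pd.Series
    n_reference: int
    score_band: tuple[float, float]
    log_base: float
    pseudocount: float

    def __post_init__(self) -> None:
        if self.n_reference < 2:
            raise ScoringError(
                f"reference for panel {self.panel_name!r} needs >=2 healthy samples, "
                f"got {self.n_reference}"
            )
        if (self.gene_sd <= 0).any():
            raise ScoringError("reference standard deviations must be positive")


def geomean_score(
    matrix: NormalizedCountMatrix,
    panel: GenePanel,
    pseudocount: float = 1.0,
    allow_partial: bool = False,
) -> pd.Series:
    """Per-sample geometric mean of normalized counts over the panel genes."""
    present = [g for g in panel.genes if g in matrix.values.index]
    if len(present) < len(panel.genes) and not allow_partial:
        missing = sorted(set(panel.genes) - set(present))
        raise ScoringError(
            f"panel {panel.name!r}: genes missing from matrix: {missing} "
            "(set allow_partial to score anyway)"
        )
    if not present:
        raise ScoringError(f"panel {panel.name!r}: no panel gene present in matrix")
    sub = GenePanel(panel.name, tuple(present), panel.code_class)
    return control_geomeans(matrix.values, sub, pseudocount)


def _log_values(values: pd.DataFrame, genes: Sequence[str], log_base: float, pseudocount: float) -> pd.DataFrame:
    return np.log(values.loc[list(genes)].astype(float) + pseudocount) / np.log(log_base)


def _reference_sample_ids(
    matrix: NormalizedCountMatrix,
    annotations: Sequence[SampleAnnotation],
) -> list[str]:
    by_id = annotations_by_id(annotations)
    return [
        s
        for s in matrix.samples
        if s in by_id
        and by_id[s].group == "healthy_reference"
        and by_id[s].stimulation == "none"
    ]


def fit_reference(
    matrix: NormalizedCountMatrix,
    annotations: Sequence[SampleAnnotation],
    panel: GenePanel,
    config: PipelineConfig,
    allow_partial: bool = False,
) -> ReferenceStats:
    """Fit per-gene reference moments and the healthy score band.

    Uses every healthy_reference sample with stimulation ``none``.  A gene
    with zero variance across references gets its sd floored at 10% of the
    panel-median sd (degenerate references are reported, not fatal).
    """
    ref_ids = _reference_sample_ids(matrix, annotations)
    if len(ref_ids) < 2:
        raise ScoringError(
            f"need >=2 healthy unstimulated reference samples, found {len(ref_ids)}"
        )
    genes = [g for g in panel.genes if g in matrix.values.index]
    if len(genes) < len(panel.genes) and not allow_partial:
        missing = sorted(set(panel.genes) - set(genes))
        raise ScoringError(f"panel {panel.name!r}: genes missing from matrix: {missing}")
    logs = _log_values(matrix.values[ref_ids], genes, config.log_base, config.pseudocount)
    mean = logs.mean(axis=1)
    sd = logs.std(axis=1, ddof=1)
    floor = max(0.1 * float(sd.median()), _SD_ABS_FLOOR)
    degenerate = sd.index[sd < floor].tolist()
    if degenerate:
        warnings.warn(
            f"panel {panel.name!r}: sd floored at {floor:.3g} for genes {degenerate}",
            stacklevel=2,
        )
    sd = sd.clip(lower=floor)
    scores = geomean_score(matrix, panel, config.pseudocount, allow_partial=allow_partial)
    lo, hi = config.reference_band
    band = (
        float(np.percentile(scores[ref_ids], lo)),
        float(np.percentile(scores[ref_ids], hi)),
    )
    return ReferenceStats(
        panel_name=panel.name,
        genes=tuple(genes),
        gene_mean=mean,
        gene_sd=sd,
        n_reference=len(ref_ids),
        score_band=band,
        log_base=config.log_base,
        pseudocount=config.pseudocount,
    )


def z_score(
    matrix: NormalizedCountMatrix,
    panel: GenePanel,
    reference: ReferenceStats,
    truncation: float | None = 10.0,
) -> pd.Series:
    """Panel-average of per-gene standardized log counts.

    Per-gene z values are clipped at ``+/-truncation`` (pass ``None`` for the
    strict, unclipped construction).
    """
    if reference.panel_name != panel.name:
        raise ScoringError(
            f"reference fitted for panel {reference.panel_name!r}, scoring {panel.name!r}"
        )
    missing = sorted(set(reference.genes) - set(matrix.values.index))
    if missing:
        raise ScoringError(f"reference genes missing from matrix: {missing}")
    logs = _log_values(matrix.values, reference.genes, reference.log_base, reference.pseudocount)
    z = logs.sub(reference.gene_mean, axis=0).div(reference.gene_sd, axis=0)
    if truncation is not None:
        z = z.clip(-truncation, truncation)
    out = z.mean(axis=0)
    out.name = f"z_{panel.name}"
    return out


def score_samples(
    matrix: NormalizedCountMatrix,
    annotations: Sequence[SampleAnnotation],
    config: PipelineConfig,
    references: Mapping[str, ReferenceStats] | None = None,
    allow_partial: bool = False,
) -> pd.DataFrame:
    """Score every sample on every endogenous panel.

    Returns one row per (sample, panel) with both scores and the sample
    annotations; deterministic given inputs.  If ``references`` is None they
    are fitted from the healthy references present in the matrix.
    """
    by_id = annotations_by_id(annotations)
    orphans = [s for s in matrix.samples if s not in by_id]
    if orphans:
        raise ScoringError(f"samples without annotation: {orphans}")
    rows = []
    for panel in config.score_panels():
        if references is not None and panel.name in references:
            ref = references[panel.name]
        else:
            ref = fit_reference(matrix, annotations, panel, config, allow_partial)
        gscores = geomean_score(matrix, panel, config.pseudocount, allow_partial)
        zscores = z_score(matrix, panel, ref, config.z_truncation)
        n_used = len(ref.genes)
        for s in matrix.samples:
            a = by_id[s]
            rows.append({
                "sample_id": s,
                "subject_id": a.subject_id,
                "date": a.date.isoformat(),
                "panel": panel.name,
                "geomean_score": float(gscores[s]),
                "z_score": float(zscores[s]),
                "n_genes_used": n_used,
                "batch": a.batch,
                "stimulation": a.stimulation,
                "days_since_last_infusion": a.days_since_last_infusion,
            })
    return pd.DataFrame(rows)


def reference_frame(reference: ReferenceStats) -> pd.DataFrame:
    """Reference stats as a flat DataFrame (gene rows plus band rows)."""
    rows = [
        {"panel": reference.panel_name, "gene": g,
         "mean": float(reference.gene_mean[g]), "sd": float(reference.gene_sd[g]),
         "n": reference.n_reference}
        for g in reference.genes
    ]
    rows.append({"panel": reference.panel_name, "gene": "__band_lower__",
                 "mean": reference.score_band[0], "sd": np.nan, "n": reference.n_reference})
    rows.append({"panel": reference.panel_name, "gene": "__band_upper__",
                 "mean": reference.score_band[1], "sd": np.nan, "n": reference.n_reference})
    return pd.DataFrame(rows)
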