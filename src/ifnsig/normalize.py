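"""Two-factor nCounter normalization.

Each lane (sample) is rescaled twice.  Step 1 uses the six spiked-in
positive-control probes to remove lane-to-lane technical variation; step 2
uses the three housekeeping genes (NRDC, OTUD5, TUBB) to remove variation in
RNA input.  Both factors share one construction: within a scope of n samples
(one cartridge batch by default, or the whole cohort),

    factor_i = (1/n * sum_j geomean_j) / geomean_i

where geomean_i is the geometric mean of the control probes in sample i.
Multiplying sample i by factor_i equalizes the control geomeans across the
scope while conserving their arithmetic mean — the scope is rescaled to its
own average lane, not to an external standard.

The housekeeping geomeans are taken on the step-1-rescaled counts (vendor
convention), which makes housekeeping geomeans exactly equal within scope
after step 2; computing both factors from raw counts is available via
``hk_factor_on_raw`` for reproduction studies.  Normalized value =
raw count x pos_factor x hk_factor either way.

Zeros: geometric means are computed on max(count, pseudocount); counts
themselves are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panels import GenePanel, PipelineConfig
from .rcc import RawCountMatrix


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationFactors:
    """Both per-sample factors plus the scope they were computed in."""

    sample_id: str
    pos_factor: float
    hk_factor: float
    batch_id: str
    n_samples_in_scope: int


@dataclass
class NormalizedCountMatrix:
    """Same shape as the raw matrix; values = raw x pos_factor x hk_factor."""

    values: pd.DataFrame  # genes x samples, float
    gene_info: pd.DataFrame
    batch_of: dict[str, str]
    provenance: dict

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def genes_of_class(self, code_class: str) -> list[str]:
        return list(self.gene_info.index[self.gene_info["code_class"] == code_class])


def geometric_mean(values: Sequence[float] | np.ndarray) -> float:
    """exp(mean(log(values))); requires a nonempty all-positive input."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise NormalizationError("geometric mean of empty input")
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise NormalizationError(
            "geometric mean requires positive finite values; floor zeros with "
            "the pseudocount policy before calling"
        )
    return float(np.exp(np.mean(np.log(arr))))


def control_geomeans(
    values: pd.DataFrame,
    panel: GenePanel,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-sample geometric mean of max(count, pseudocount) over panel genes."""
    missing = sorted(set(panel.genes) - set(values.index))
    if missing:
        raise NormalizationError(f"panel {panel.name!r}: genes missing from matrix: {missing}")
    sub = values.loc[list(panel.genes)].astype(float).clip(lower=pseudocount)
    gm = np.exp(np.log(sub).mean(axis=0))
    gm.name = f"geomean_{panel.name}"
    return gm


def normalization_factor(geomeans: pd.Series) -> pd.Series:
    """factor_i = mean(geomeans in scope) / geomean_i for one scope."""
    if len(geomeans) == 0:
        raise NormalizationError("empty normalization scope")
    if (geomeans <= 0).any() or not np.isfinite(geomeans).all():
        raise NormalizationError("geomeans must be positive and finite")
    return geomeans.mean() / geomeans


def _scoped_factors(geomeans: pd.Series, scope_of: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Apply normalization_factor within each scope; returns (factors, scope sizes)."""
    factors = pd.Series(index=geomeans.index, dtype=float)
    n_in_scope = pd.Series(index=geomeans.index, dtype=int)
    for _, idx in geomeans.groupby(scope_of).groups.items():
        factors.loc[idx] = normalization_factor(geomeans.loc[idx])
        n_in_scope.loc[idx] = len(idx)
    return factors, n_in_scope


def normalize(
    matrix: RawCountMatrix,
    config: PipelineConfig,
) -> tuple[NormalizedCountMatrix, list[NormalizationFactors]]:
    """Run both normalization steps.

    Returns the normalized matrix and one :class:`NormalizationFactors` per
    sample.  With the default per-batch policy each cartridge is its own
    scope; with ``batch_policy: global`` the whole cohort is one scope.
    """
    pos_panel = config.panel_by_class("positive_control")
    hk_panel = config.panel_by_class("housekeeping")
    if pos_panel is None or hk_panel is None:
        raise NormalizationError("config must define positive-control and housekeeping panels")
    counts = matrix.counts.astype(float)
    if config.batch_policy == "per_batch":
        scope_of = matrix.batches()
    else:
        scope_of = pd.Series("all", index=counts.columns)

    pos_gm = control_geomeans(counts, pos_panel, config.pseudocount)
    pos_factor, n_in_scope = _scoped_factors(pos_gm, scope_of)
    step1 = counts.mul(pos_factor, axis=1)

    hk_basis = counts if config.hk_factor_on_raw else step1
    hk_gm = control_geomeans(hk_basis, hk_panel, config.pseudocount)
    hk_factor, _ = _scoped_factors(hk_gm, scope_of)

    total = pos_factor * hk_factor
    if not np.isfinite(total).all():
        raise NormalizationError("nonfinite normalization factor")
    normalized = counts.mul(total, axis=1)

    factors = [
        NormalizationFactors(
            sample_id=s,
            pos_factor=float(pos_factor[s]),
            hk_factor=float(hk_factor[s]),
            batch_id=str(scope_of[s]),
            n_samples_in_scope=int(n_in_scope[s]),
        )
        for s in counts.columns
    ]
    norm = NormalizedCountMatrix(
        values=normalized,
        gene_info=matrix.gene_info.copy(),
        batch_of=dict(matrix.batch_of),
        provenance={
            "batch_policy": config.batch_policy,
            "pseudocount": config.pseudocount,
            "hk_factor_on_raw": config.hk_factor_on_raw,
        },
    )
    return norm, factors


def factors_frame(factors: list[NormalizationFactors]) -> pd.DataFrame:
    """Factors as a DataFrame (columns: sample_id, batch, pos_factor,
    hk_factor, n_in_scope)."""
    return pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "batch": f.batch_id,
                "pos_factor": f.pos_factor,
                "hk_factor": f.hk_factor,
                "n_in_scope": f.n_samples_in_scope,
            }
            for f in factors
        ]
    )
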