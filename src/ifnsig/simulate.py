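"""Synthetic nCounter cohorts with known ground truth.

Emulates the structure the normalization and scoring modules assume: lanes
run in cartridge batches of 12 that each carry healthy-donor references; a
six-step positive-control ladder at 2-fold-style descending concentrations;
three housekeeping genes whose biological level does not depend on the
sample; 56 endogenous immune genes including a 30-gene ISG panel; per-lane
technical scaling factors; overdispersed (negative-binomial) counts; ISG
elevation in patients and fold-induction of ISGs under IFN-beta stimulation.

The generative model for endogenous gene g in lane i is

    count ~ NegBin(mean = lane_i * baseline_g * effect_{g,i}, size = dispersion)

with lane_i ~ LogNormal(0, sigma_lane), per-cohort baselines drawn once from
a lognormal, and effect = theta^s * m on ISG genes (theta the patient ISG
elevation, s in [0, 1] the residual fraction of elevation on the log scale
under treatment, m the in-vitro stimulation multiplier) and 1 elsewhere.
Positive and negative controls are Poisson around lane_i times the ladder
concentration or the background mean.  All randomness flows from one seed.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panels import PipelineConfig, default_config
from .rcc import (
    RawCountMatrix,
    SampleAnnotation,
    write_sample_sheet,
)

#: endogenous immune genes beyond the three scored panels, bringing the
#: synthetic codeset to 56 endogenous genes
EXTRA_ENDOGENOUS = ("IFNG", "IL10", "IL17A", "FOXP3", "CD274", "IL2RA")

#: nCounter-style descending spike-in concentrations (arbitrary units)
DEFAULT_LADDER = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


class SimulationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Cohort layout and generative parameters (defaults emulate the assay:
    batches of 12 lanes with healthy references, moderate lane effects,
    strongly elevated ISGs in untreated patients, 5-fold ISG induction on
    stimulation)."""

    seed: int = 0
    n_patients: int = 8
    n_healthy: int = 4
    n_stim_pairs_healthy: int = 0   # healthy draws split into unstim/stim aliquots
    n_stim_pairs_patient: int = 0   # patient draws split likewise
    sigma_lane: float = 0.3         # sd of log lane factor
    dispersion: float = 50.0        # negative-binomial size; larger = closer to Poisson
    isg_elevation: float = 8.0      # theta: ISG fold-elevation in untreated patients
    suppression: float = 1.0        # s: residual fraction of log-elevation (1 = untreated)
    stim_multiplier: float = 5.0    # m: ISG fold-induction in stimulated aliquots
    ladder: tuple[float, ...] = DEFAULT_LADDER
    ladder_scale: float = 60.0      # counts per concentration unit at lane factor 1
    neg_background: float = 2.0     # mean negative-control count at lane factor 1
    baseline_geomean: float = 150.0  # center of endogenous baseline lognormal
    baseline_sigma: float = 0.6
    hk_baselines: dict[str, float] = field(
        default_factory=lambda: {"NRDC": 600.0, "OTUD5": 400.0, "TUBB": 2000.0}
    )
    batch_size: int = 12
    min_healthy_per_batch: int = 2
    start_date: dt.date = dt.date(2023, 1, 4)
    #: override: explicit (subject_id, iso date, suppression s) patient draws,
    #: e.g. a longitudinal series for one subject; replaces n_patients
    patient_schedule: tuple[tuple[str, str, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.isg_elevation < 1 or self.stim_multiplier < 1:
            raise SimulationError("isg_elevation and stim_multiplier must be >= 1")
        if not 0 <= self.suppression <= 1:
            raise SimulationError("suppression must lie in [0, 1]")
        if self.dispersion <= 0 or self.sigma_lane < 0:
            raise SimulationError("dispersion must be > 0 and sigma_lane >= 0")
        if len(self.ladder) != 6:
            raise SimulationError("positive-control ladder must have 6 steps")


@dataclass
class SyntheticTruth:
    """Everything needed to check recovery: the generating parameters."""

    seed: int
    lane_factor: pd.Series          # per sample
    baselines: pd.Series            # per endogenous/housekeeping gene
    isg_effect: pd.Series           # per sample: theta^s * m on ISG genes
    dispersion: float
    isg_genes: tuple[str, ...]


def _plan_samples(config: SyntheticConfig) -> list[dict]:
    """Deterministic sample plan: ids, subjects, dates, groups, stimulation,
    per-sample ISG effect exponent pieces."""
    plan: list[dict] = []
    week = dt.timedelta(days=7)
    if config.patient_schedule is not None:
        schedule = [
            (sub, dt.date.fromisoformat(d), float(s))
            for sub, d, s in config.patient_schedule
        ]
    else:
        schedule = [
            (f"P{k + 1:02d}", config.start_date + k * week, config.suppression)
            for k in range(config.n_patients)
        ]
    for k, (subject, date, s) in enumerate(schedule):
        plan.append(dict(
            sample_id=f"{subject}_{date.isoformat()}",
            subject_id=subject, date=date, group="patient",
            stimulation="none", s=s, stim=False,
        ))
    for k in range(config.n_healthy):
        subject = f"H{k + 1:02d}"
        date = config.start_date + k * week
        plan.append(dict(
            sample_id=f"{subject}_{date.isoformat()}",
            subject_id=subject, date=date, group="healthy_reference",
            stimulation="none", s=0.0, stim=False,
        ))
    for kind, n, group, s in (
        ("SH", config.n_stim_pairs_healthy, "healthy_reference", 0.0),
        ("SP", config.n_stim_pairs_patient, "patient", config.suppression),
    ):
        for k in range(n):
            subject = f"{kind}{k + 1:02d}"
            date = config.start_date + k * week
            for stim_status, flag in (("unstimulated_cultured", False),
                                      ("IFNb_stimulated", True)):
                tag = "stim" if flag else "unstim"
                plan.append(dict(
                    sample_id=f"{subject}_{date.isoformat()}_{tag}",
                    subject_id=subject, date=date, group=group,
                    stimulation=stim_status, s=s, stim=flag,
                ))
    return plan


def _assign_batches(plan: list[dict], config: SyntheticConfig) -> None:
    """Chunk samples into batches of ``batch_size``, spreading healthy
    unstimulated references so every batch holds at least the minimum."""
    n_batches = math.ceil(len(plan) / config.batch_size)
    is_ref = lambda p: p["group"] == "healthy_reference" and p["stimulation"] == "none"
    refs = [p for p in plan if is_ref(p)]
    others = [p for p in plan if not is_ref(p)]
    if len(refs) < config.min_healthy_per_batch * n_batches:
        raise SimulationError(
            f"{n_batches} batches need >= {config.min_healthy_per_batch} healthy "
            f"references each but only {len(refs)} are planned; increase n_healthy"
        )
    batches: list[list[dict]] = [[] for _ in range(n_batches)]
    for i, p in enumerate(refs[: config.min_healthy_per_batch * n_batches]):
        batches[i % n_batches].append(p)
    remaining = refs[config.min_healthy_per_batch * n_batches:] + others
    for p in remaining:
        target = min(batches, key=len)
        target.append(p)
    for b, members in enumerate(batches, start=1):
        for p in members:
            p["batch"] = f"SYNB{b:02d}"


def simulate_cohort(
    config: SyntheticConfig,
    pipeline_config: PipelineConfig | None = None,
) -> tuple[RawCountMatrix, list[SampleAnnotation], SyntheticTruth]:
    """Generate a full cohort: counts, sample sheet annotations and truth.

    Deterministic given ``config.seed``.  The codeset is taken from the
    pipeline config panels (ISG + NF-kB + IFN-gamma + extras = 56 endogenous
    genes with the bundled defaults) plus housekeeping, 6 positive and 8
    negative controls.
    """
    pc = pipeline_config or default_config()
    rng = np.random.default_rng(config.seed)
    plan = _plan_samples(config)
    _assign_batches(plan, config)
    sample_ids = [p["sample_id"] for p in plan]

    isg_genes = tuple(pc.panels["ISG"].genes)
    endo_genes: list[str] = []
    for panel in pc.score_panels():
        endo_genes.extend(panel.genes)
    endo_genes.extend(g for g in EXTRA_ENDOGENOUS if g not in endo_genes)
    hk_genes = list(pc.panel_by_class("housekeeping").genes)
    pos_genes = list(pc.panel_by_class("positive_control").genes)
    neg_panel = pc.panel_by_class("negative_control")
    neg_genes = list(neg_panel.genes) if neg_panel else [f"NEG_{c}" for c in "ABCDEFGH"]

    # per-cohort biology: baselines drawn once, housekeeping fixed
    baselines = pd.Series(
        rng.lognormal(math.log(config.baseline_geomean), config.baseline_sigma,
                      size=len(endo_genes)),
        index=endo_genes,
    )
    for g, level in config.hk_baselines.items():
        baselines[g] = level
    missing_hk = [g for g in hk_genes if g not in baselines.index]
    for g in missing_hk:  # housekeeping panel renamed in config
        baselines[g] = 500.0

    lane = pd.Series(
        rng.lognormal(0.0, config.sigma_lane, size=len(sample_ids)),
        index=sample_ids, name="lane_factor",
    )
    theta = config.isg_elevation
    isg_effect = pd.Series(
        [
            (theta ** p["s"] if p["group"] == "patient" else 1.0)
            * (config.stim_multiplier if p["stim"] else 1.0)
            for p in plan
        ],
        index=sample_ids, name="isg_effect",
    )

    all_genes = list(pos_genes) + list(neg_genes) + hk_genes + list(endo_genes)
    counts = np.zeros((len(all_genes), len(sample_ids)), dtype=np.int64)
    bio_genes = hk_genes + list(endo_genes)
    mean_bio = np.outer(baselines[bio_genes].to_numpy(), lane.to_numpy())
    isg_mask = np.array([g in isg_genes for g in bio_genes])
    mean_bio[isg_mask] *= isg_effect.to_numpy()[None, :]
    size = config.dispersion
    counts_bio = rng.negative_binomial(size, size / (size + mean_bio))
    ladder_means = np.outer(
        config.ladder_scale * np.asarray(config.ladder), lane.to_numpy()
    )
    counts_pos = rng.poisson(ladder_means)
    counts_neg = rng.poisson(config.neg_background * lane.to_numpy()[None, :]
                             * np.ones((len(neg_genes), 1)))
    counts[: len(pos_genes)] = counts_pos
    counts[len(pos_genes): len(pos_genes) + len(neg_genes)] = counts_neg
    counts[len(pos_genes) + len(neg_genes):] = counts_bio

    classes = (
        ["positive_control"] * len(pos_genes)
        + ["negative_control"] * len(neg_genes)
        + ["housekeeping"] * len(hk_genes)
        + ["endogenous"] * len(endo_genes)
    )
    index = pd.Index(all_genes, name="gene")
    matrix = RawCountMatrix(
        counts=pd.DataFrame(counts, index=index, columns=sample_ids),
        gene_info=pd.DataFrame(
            {"code_class": classes, "accession": [f"SYN_{g}" for g in all_genes]},
            index=index,
        ),
        batch_of={p["sample_id"]: p["batch"] for p in plan},
    )
    annotations = [
        SampleAnnotation(
            sample_id=p["sample_id"],
            subject_id=p["subject_id"],
            date=p["date"],
            group=p["group"],
            batch=p["batch"],
            stimulation=p["stimulation"],
        )
        for p in plan
    ]
    truth = SyntheticTruth(
        seed=config.seed,
        lane_factor=lane,
        baselines=baselines,
        isg_effect=isg_effect,
        dispersion=config.dispersion,
        isg_genes=isg_genes,
    )
    return matrix, annotations, truth


def expected_scores(
    truth: SyntheticTruth,
    pipeline_config: PipelineConfig | None = None,
) -> pd.Series:
    """Analytic noise-free ISG geomean score per sample, as perfect
    normalization would see it: geomean of ISG baselines times the sample's
    ISG effect (lane factors removed)."""
    pc = pipeline_config or default_config()
    genes = [g for g in pc.panels["ISG"].genes if g in truth.baselines.index]
    base = float(np.exp(np.mean(np.log(truth.baselines[genes]))))
    out = base * truth.isg_effect
    out.name = "expected_isg_score"
    return out


def write_synthetic_rcc(
    matrix: RawCountMatrix,
    annotations: Sequence[SampleAnnotation],
    out_dir: str | Path,
) -> list[Path]:
    """Write one RCC file per sample plus ``sheet.csv``; the files read back
    to a count-identical matrix under the strict RCC reader."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    class_out = {
        "endogenous": "Endogenous",
        "housekeeping": "Housekeeping",
        "positive_control": "Positive",
        "negative_control": "Negative",
    }
    lanes_in_batch: dict[str, int] = {}
    paths = []
    for a in annotations:
        lanes_in_batch[a.batch] = lanes_in_batch.get(a.batch, 0) + 1
        lane_id = lanes_in_batch[a.batch]
        lines = [
            "<Header>",
            "FileVersion,1.7",
            "SoftwareVersion,ifnsig-sim",
            "</Header>",
            "<Sample_Attributes>",
            f"ID,{a.sample_id}",
            "Owner,",
            "Comments,synthetic",
            f"Date,{a.date.strftime('%Y%m%d')}",
            "GeneRLF,SYN_CodeSet",
            "SystemAPF,n/a",
            "</Sample_Attributes>",
            "<Lane_Attributes>",
            f"ID,{lane_id}",
            "FovCount,280",
            "FovCounted,278",
            "ScannerID,SYN01",
            f"StagePosition,{lane_id}",
            "BindingDensity,0.55",
            f"CartridgeID,{a.batch}",
            "</Lane_Attributes>",
            "<Code_Summary>",
            "CodeClass,Name,Accession,Count",
        ]
        col = matrix.counts[a.sample_id]
        for g in matrix.counts.index:
            cls = class_out.get(matrix.gene_info.loc[g, "code_class"],
                                matrix.gene_info.loc[g, "code_class"])
            lines.append(f"{cls},{g},{matrix.gene_info.loc[g, 'accession']},{int(col[g])}")
        lines += ["</Code_Summary>", "<Messages>", "</Messages>", ""]
        path = out_dir / f"{a.sample_id}.RCC"
        path.write_text("\n".join(lines))
        paths.append(path)
    write_sample_sheet(annotations, out_dir / "sheet.csv")
    return paths


def truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-sample truth as a DataFrame for ``truth.csv``."""
    return pd.DataFrame({
        "sample_id": truth.lane_factor.index,
        "lane_factor": truth.lane_factor.to_numpy(),
        "isg_effect": truth.isg_effect.to_numpy(),
    })
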