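"""Gene panels and pipeline configuration.

A :class:`GenePanel` is a named, ordered list of probe symbols sharing one
nCounter code class (endogenous, housekeeping, positive or negative control).
The :class:`PipelineConfig` bundles the panels with the handful of numeric
policies the pipeline needs: how normalization scopes are chosen (per
cartridge batch or globally), the pseudocount used wherever a geometric mean
or logarithm meets a zero, the healthy reference band percentiles, the
fold-induction threshold for the in-vitro stimulation assay, and the log base
for Z-scores.

Configurations are plain YAML files with an explicit ``schema_version`` so a
run can always be reproduced from its config.  Panel gene lists may be given
inline or in a one-symbol-per-line text file referenced via ``genes_file``
(resolved relative to the config file).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

CODE_CLASSES = ("endogenous", "housekeeping", "positive_control", "negative_control")
BATCH_POLICIES = ("per_batch", "global")

#: Housekeeping transcripts assumed biologically stable across blood samples.
DEFAULT_HOUSEKEEPING = ("NRDC", "OTUD5", "TUBB")


class ConfigError(ValueError):
    """A configuration file is malformed or violates a panel invariant."""


@dataclass(frozen=True)
class GenePanel:
    """A named ordered set of gene symbols used for a score or for controls."""

    name: str
    genes: tuple[str, ...]
    code_class: str = "endogenous"

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("panel name must be nonempty")
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) == 0:
            raise ConfigError(f"panel {self.name!r}: gene list is empty")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise ConfigError(f"panel {self.name!r}: duplicated gene symbols {dupes}")
        if self.code_class not in CODE_CLASSES:
            raise ConfigError(
                f"panel {self.name!r}: code_class {self.code_class!r} "
                f"not one of {CODE_CLASSES}"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PipelineConfig:
    """Validated pipeline settings: panels plus numeric policies."""

    panels: dict[str, GenePanel]
    batch_policy: str = "per_batch"
    pseudocount: float = 1.0
    reference_band: tuple[float, float] = (2.5, 97.5)
    induction_threshold: float = 2.0
    log_base: float = 2.0
    z_truncation: float | None = 10.0
    hk_factor_on_raw: bool = False
    schema_version: int = 1

    def __post_init__(self) -> None:
        self.reference_band = (float(self.reference_band[0]), float(self.reference_band[1]))
        self.validate()

    def validate(self) -> None:
        if self.batch_policy not in BATCH_POLICIES:
            raise ConfigError(
                f"batch_policy {self.batch_policy!r} not one of {BATCH_POLICIES}"
            )
        if not self.pseudocount > 0:
            raise ConfigError(f"pseudocount must be > 0, got {self.pseudocount}")
        lo, hi = self.reference_band
        if not (0 <= lo < hi <= 100):
            raise ConfigError(
                f"reference_band must satisfy 0 <= lower < upper <= 100, got {lo, hi}"
            )
        if not self.induction_threshold > 1:
            raise ConfigError(
                f"induction_threshold must be > 1, got {self.induction_threshold}"
            )
        if not self.log_base > 1:
            raise ConfigError(f"log_base must be > 1, got {self.log_base}")
        if self.z_truncation is not None and not self.z_truncation > 0:
            raise ConfigError(f"z_truncation must be > 0 or null, got {self.z_truncation}")
        pos = self.panel_by_class("positive_control")
        if pos is not None and len(pos) != 6:
            raise ConfigError(
                f"positive-control panel must have exactly 6 probes, got {len(pos)}"
            )
        hk = self.panel_by_class("housekeeping")
        if hk is not None and len(hk) != 3:
            raise ConfigError(
                f"housekeeping panel must have exactly 3 genes, got {len(hk)}"
            )

    # -- panel lookups -----------------------------------------------------

    def panel_by_class(self, code_class: str) -> GenePanel | None:
        """First panel of the given code class (controls are singletons)."""
        for p in self.panels.values():
            if p.code_class == code_class:
                return p
        return None

    def score_panels(self) -> list[GenePanel]:
        """Endogenous panels that get a geomean score and a Z-score."""
        return [p for p in self.panels.values() if p.code_class == "endogenous"]


# ---------------------------------------------------------------------------
# Loading / saving


def _panel_from_entry(entry: Mapping, base_dir: Path) -> GenePanel:
    if not isinstance(entry, Mapping) or "name" not in entry:
        raise ConfigError(f"panel entry missing 'name': {entry!r}")
    name = str(entry["name"])
    if "genes" in entry and "genes_file" in entry:
        raise ConfigError(f"panel {name!r}: give 'genes' or 'genes_file', not both")
    if "genes" in entry:
        genes = [str(g) for g in entry["genes"]]
    elif "genes_file" in entry:
        path = base_dir / str(entry["genes_file"])
        if not path.exists():
            raise ConfigError(f"panel {name!r}: genes_file {path} not found")
        genes = [ln.strip() for ln in path.read_text().splitlines()
                 if ln.strip() and not ln.startswith("#")]
    else:
        raise ConfigError(f"panel {name!r}: no 'genes' or 'genes_file' key")
    return GenePanel(
        name=name,
        genes=tuple(genes),
        code_class=str(entry.get("code_class", "endogenous")),
    )


def _config_from_dict(raw: Mapping, base_dir: Path) -> PipelineConfig:
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    if "panels" not in raw:
        raise ConfigError("config missing required key 'panels'")
    panels: dict[str, GenePanel] = {}
    for entry in raw["panels"]:
        panel = _panel_from_entry(entry, base_dir)
        if panel.name in panels:
            raise ConfigError(f"duplicate panel name {panel.name!r}")
        panels[panel.name] = panel
    kwargs: dict = {"panels": panels}
    scalar_keys = (
        "batch_policy", "pseudocount", "induction_threshold",
        "log_base", "z_truncation", "hk_factor_on_raw", "schema_version",
    )
    for key in scalar_keys:
        if key in raw:
            kwargs[key] = raw[key]
    if "reference_band" in raw:
        band = raw["reference_band"]
        if not isinstance(band, (list, tuple)) or len(band) != 2:
            raise ConfigError(f"reference_band must be a [lower, upper] pair, got {band!r}")
        kwargs["reference_band"] = (float(band[0]), float(band[1]))
    try:
        return PipelineConfig(**kwargs)
    except TypeError as exc:  # unknown key smuggled through
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load and fully validate a pipeline configuration from a YAML file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return _config_from_dict(raw, path.parent)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips through load_config)."""
    doc = {
        "schema_version": config.schema_version,
        "batch_policy": config.batch_policy,
        "pseudocount": config.pseudocount,
        "log_base": config.log_base,
        "reference_band": list(config.reference_band),
        "induction_threshold": config.induction_threshold,
        "z_truncation": config.z_truncation,
        "hk_factor_on_raw": config.hk_factor_on_raw,
        "panels": [
            {"name": p.name, "code_class": p.code_class, "genes": list(p.genes)}
            for p in config.panels.values()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_config() -> PipelineConfig:
    """The bundled default configuration (30-gene ISG panel, NRDC/OTUD5/TUBB
    housekeeping, 6 positive controls).  Panel identities are placeholders —
    see the file header in ``data/default_config.yaml``."""
    with resources.as_file(
        resources.files("ifnsig.data").joinpath("default_config.yaml")
    ) as p:
        return load_config(p)


def validate_panels_against_matrix(panels: Iterable[GenePanel], matrix) -> dict[str, list[str]]:
    """Report, per panel, the genes absent from a count matrix.

    Returns a mapping panel name -> sorted missing symbols; panels with no
    missing genes are omitted, so an empty dict means every panel is fully
    scorable.
    """
    present = set(matrix.counts.index)
    report: dict[str, list[str]] = {}
    for panel in panels:
        missing = sorted(set(panel.genes) - present)
        if missing:
            report[panel.name] = missing
    return report
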