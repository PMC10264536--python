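"""Synthetic cohort generator with planted ground truth.

Cohorts are drawn as exp(multivariate normal) per toxicity group:
log-normal marginals mimic the positive, right-skewed serum
concentrations the analysis log-transforms, and block-constant
within-group correlation is the simplest structure producing
group-dependent rewiring (edges dense in one group, absent in the
other). Group means are equal except for a fixed log-scale shift on a
designated elevated-marker subset in the toxicity group. A fraction of
the lowest values per analyte is censored to zero to emulate
below-detection-limit readouts and exercise the missing-value path.

Defaults emulate the study conditions the pipeline targets: 52
no-toxicity and 27 toxicity patients over the 34-analyte panel, eight
toxicity-elevated markers, a core cytokine block shared by both groups,
chemokine and checkpoint blocks present only without toxicity, and an
sPD-L2-coupled block present only with toxicity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable
from .panel import PanelMetadata, default_panel

#: Markers elevated in the toxicity group by default.
DEFAULT_ELEVATED = (
    "IP10", "IL8", "sLAG3", "sPDL2", "sHVEM", "sCD137", "sCD27", "sICAM1",
)

_CORE_CYTOKINES = ("IL10", "IL13", "IL6", "IL1a", "IL1b", "GMCSF", "TNFa", "IFNa", "IFNg")
_CHEMOKINES = ("MCP1", "MIP1a", "MIP1b", "IL8", "IP10")
_CHECKPOINT_TRIO = ("sCD137", "sCD27", "sCD28")
_TOX_COUPLED = ("sPDL2", "IL17A", "IL4", "IL12p70")

DEFAULT_BLOCK_RHO = 0.9

Block = tuple[frozenset, float]


def default_blocks_group0() -> list[Block]:
    """No-toxicity structure: core cytokines plus chemokine and checkpoint blocks."""
    return [
        (frozenset(_CORE_CYTOKINES), DEFAULT_BLOCK_RHO),
        (frozenset(_CHEMOKINES), DEFAULT_BLOCK_RHO),
        (frozenset(_CHECKPOINT_TRIO), DEFAULT_BLOCK_RHO),
    ]


def default_blocks_group1() -> list[Block]:
    """Toxicity structure: the core cytokine block survives; chemokine and
    checkpoint coupling is lost and an sPD-L2-coupled block appears."""
    return [
        (frozenset(_CORE_CYTOKINES), DEFAULT_BLOCK_RHO),
        (frozenset(_TOX_COUPLED), DEFAULT_BLOCK_RHO),
    ]


class ConfigError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


@dataclass
class SyntheticCohortConfig:
    """Generator configuration.

    ``shift_log_units`` is the additive group-1 mean shift on the natural-log
    scale for ``elevated_analytes``; ``noise_sd_log`` the within-group
    log-scale standard deviation (0.7 corresponds to a geometric SD of
    about 2, typical of serum cytokine panels); ``base_log_mean`` the
    common log-scale mean (e^4 is about 55 pg/ml);
    ``lod_censor_fraction`` the fraction of lowest values per analyte set
    to zero as below-detection.
    """

    n_group0: int = 52
    n_group1: int = 27
    panel: PanelMetadata | None = None
    elevated_analytes: tuple[str, ...] = DEFAULT_ELEVATED
    shift_log_units: float = 0.8
    correlation_blocks_group0: list[Block] | None = None
    correlation_blocks_group1: list[Block] | None = None
    noise_sd_log: float = 0.7
    base_log_mean: float = 4.0
    lod_censor_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel is None:
            self.panel = default_panel()
        if self.correlation_blocks_group0 is None:
            self.correlation_blocks_group0 = default_blocks_group0()
        if self.correlation_blocks_group1 is None:
            self.correlation_blocks_group1 = default_blocks_group1()
        self.correlation_blocks_group0 = [
            (frozenset(b), float(r)) for b, r in self.correlation_blocks_group0
        ]
        self.correlation_blocks_group1 = [
            (frozenset(b), float(r)) for b, r in self.correlation_blocks_group1
        ]
        if self.n_group0 < 1 or self.n_group1 < 1:
            raise ConfigError("group sizes must be positive")
        if self.shift_log_units < 0:
            raise ConfigError("shift_log_units must be >= 0")
        if self.noise_sd_log <= 0:
            raise ConfigError("noise_sd_log must be > 0")
        if not 0 <= self.lod_censor_fraction < 1:
            raise ConfigError("lod_censor_fraction must be in [0, 1)")
        panel_ids = set(self.panel.analyte_ids)
        missing = set(self.elevated_analytes) - panel_ids
        if missing:
            raise ConfigError(f"elevated analytes not in panel: {sorted(missing)}")
        for blocks in (self.correlation_blocks_group0, self.correlation_blocks_group1):
            seen: set[str] = set()
            for members, rho in blocks:
                if not members <= panel_ids:
                    raise ConfigError(
                        f"block analytes not in panel: {sorted(members - panel_ids)}"
                    )
                if len(members) < 2:
                    raise ConfigError("correlation blocks need at least 2 analytes")
                if not 0 <= rho < 1:
                    raise ConfigError(f"block correlation must be in [0, 1), got {rho}")
                overlap = members & seen
                if overlap:
                    raise ConfigError(f"overlapping correlation blocks at {sorted(overlap)}")
                seen |= members
        # fail construction on a non-positive-semidefinite structure
        for group in (0, 1):
            corr = self.correlation_matrix(group)
            eigmin = float(np.linalg.eigvalsh(corr).min())
            if eigmin < -1e-8:
                raise ConfigError(
                    f"group-{group} correlation structure is not positive "
                    f"semidefinite (min eigenvalue {eigmin:.3e})"
                )

    def _canonical_ids(self) -> list[str]:
        # canonical sorted order decouples random draws from panel ordering
        return sorted(self.panel.analyte_ids)

    def correlation_matrix(self, group: int) -> np.ndarray:
        """Planted within-group correlation matrix, canonical (sorted-id) order."""
        ids = self._canonical_ids()
        index = {a: i for i, a in enumerate(ids)}
        corr = np.eye(len(ids))
        blocks = (
            self.correlation_blocks_group0 if group == 0 else self.correlation_blocks_group1
        )
        for members, rho in blocks:
            idx = [index[a] for a in members]
            for i in idx:
                for j in idx:
                    if i != j:
                        corr[i, j] = rho
        return corr


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure the downstream stages should recover."""

    true_elevated: frozenset
    true_edges_group0: frozenset  # frozensets of analyte-id pairs
    true_edges_group1: frozenset
    level: float


def ground_truth_edges(config: SyntheticCohortConfig, level: float = 0.6) -> GroundTruth:
    """All planted pairs whose block correlation is at least ``level``, per group."""
    if not 0 < level < 1:
        raise ConfigError(f"level must be in (0, 1), got {level}")

    def edges(blocks: Sequence[Block]) -> frozenset:
        pairs = set()
        for members, rho in blocks:
            if rho >= level:
                ms = sorted(members)
                pairs.update(
                    frozenset((a, b)) for i, a in enumerate(ms) for b in ms[i + 1:]
                )
        return frozenset(pairs)

    return GroundTruth(
        true_elevated=frozenset(config.elevated_analytes),
        true_edges_group0=edges(config.correlation_blocks_group0),
        true_edges_group1=edges(config.correlation_blocks_group1),
        level=level,
    )


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # exactly singular PSD matrices: eigendecomposition factor
        w, v = np.linalg.eigh(corr)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def generate_cohort(
    config: SyntheticCohortConfig, *, truth_level: float = 0.6
) -> tuple[CohortTable, GroundTruth]:
    """Draw one synthetic cohort; a pure function of ``config.seed``."""
    panel = config.panel
    ids = config._canonical_ids()
    m = len(ids)
    ss = np.random.SeedSequence(config.seed)
    child0, child1, _reserved = ss.spawn(3)

    frames = []
    for group, child, n in ((0, child0, config.n_group0), (1, child1, config.n_group1)):
        rng = np.random.default_rng(child)
        corr = config.correlation_matrix(group)
        factor = _psd_factor(corr)
        z = rng.standard_normal((n, m))
        logs = config.base_log_mean + config.noise_sd_log * (z @ factor.T)
        if group == 1 and config.shift_log_units > 0:
            for analyte in config.elevated_analytes:
                logs[:, ids.index(analyte)] += config.shift_log_units
        frames.append(np.exp(logs))
    values = np.vstack(frames)

    # below-LOD censoring: lowest values per analyte become exact zeros
    n_total = config.n_group0 + config.n_group1
    k = int(np.floor(config.lod_censor_fraction * n_total))
    if k > 0:
        for j in range(m):
            order = np.argsort(values[:, j], kind="stable")
            values[order[:k], j] = 0.0

    width = len(str(n_total))
    patient_ids = [f"P{i + 1:0{width}d}" for i in range(n_total)]
    toxicity = pd.Series(
        [0] * config.n_group0 + [1] * config.n_group1, index=patient_ids, name="cumulative_toxicity"
    )
    grade = pd.Series(
        ["G0G1"] * config.n_group0 + ["G2G3"] * config.n_group1,
        index=patient_ids,
        name="grade_class",
    )
    abundance = pd.DataFrame(values, index=patient_ids, columns=ids)
    abundance.index.name = "patient_id"
    cohort = CohortTable(
        abundance=abundance[panel.analyte_ids],
        toxicity=toxicity,
        panel=panel,
        grade_class=grade,
    )
    return cohort, ground_truth_edges(config, truth_level)


def save_ground_truth(
    truth: GroundTruth, config: SyntheticCohortConfig, path: str | Path
) -> Path:
    """Ground-truth edge list TSV: group, analyte_a, analyte_b, planted_rho."""
    planted: dict[tuple[int, frozenset], float] = {}
    for group, blocks in (
        (0, config.correlation_blocks_group0),
        (1, config.correlation_blocks_group1),
    ):
        for members, rho in blocks:
            ms = sorted(members)
            for i, a in enumerate(ms):
                for b in ms[i + 1:]:
                    planted[(group, frozenset((a, b)))] = rho
    rows = []
    for group, edges in ((0, truth.true_edges_group0), (1, truth.true_edges_group1)):
        for pair in sorted(edges, key=sorted):
            a, b = sorted(pair)
            rows.append(dict(group=group, analyte_a=a, analyte_b=b,
                             planted_rho=planted[(group, pair)]))
    pd.DataFrame(rows, columns=["group", "analyte_a", "analyte_b", "planted_rho"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def config_to_dict(config: SyntheticCohortConfig) -> dict:
    return dict(
        n_group0=config.n_group0,
        n_group1=config.n_group1,
        analytes=config.panel.analyte_ids,
        elevated_analytes=list(config.elevated_analytes),
        shift_log_units=config.shift_log_units,
        correlation_blocks_group0=[
            dict(analytes=sorted(b), rho=r) for b, r in config.correlation_blocks_group0
        ],
        correlation_blocks_group1=[
            dict(analytes=sorted(b), rho=r) for b, r in config.correlation_blocks_group1
        ],
        noise_sd_log=config.noise_sd_log,
        base_log_mean=config.base_log_mean,
        lod_censor_fraction=config.lod_censor_fraction,
        seed=config.seed,
    )


def config_from_dict(data: dict, *, panel: PanelMetadata | None = None) -> SyntheticCohortConfig:
    data = dict(data)
    data.pop("analytes", None)
    for key in ("correlation_blocks_group0", "correlation_blocks_group1"):
        if data.get(key) is not None:
            data[key] = [
                (frozenset(entry["analytes"]), float(entry["rho"])) for entry in data[key]
            ]
    if "elevated_analytes" in data:
        data["elevated_analytes"] = tuple(data["elevated_analytes"])
    return SyntheticCohortConfig(panel=panel, **data)


def config_from_file(path: str | Path) -> SyntheticCohortConfig:
    """Read a generator configuration from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return config_from_dict(data)
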