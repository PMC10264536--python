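"""Cohort container and file I/O.

A cohort is a patient x analyte abundance matrix (serum concentrations in
pg/ml, plus the dimensionless kyn/trp ratio for IDO activity) together with
a per-patient binary cumulative-toxicity label (1 = more than one
immune-related adverse event of any grade) and an optional toxicity grade
class (G0-G1 vs G2-G3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import PanelMetadata, load_panel, resolve_analyte_id

GRADE_CLASSES = ("G0G1", "G2G3")

#: Minimum observed values per toxicity group for an analyte to be testable.
MIN_GROUP_OBS = 3


class CohortError(ValueError):
    """Raised when a cohort violates its invariants."""


@dataclass
class CohortTable:
    """Validated patient x analyte table with toxicity labels.

    ``abundance`` is indexed by patient_id with one column per panel
    analyte, in panel (functional-group block) order. Values are
    non-negative or missing on the raw scale; after :func:`log_transform`
    they are natural-log values and ``log_scale`` is True.
    """

    abundance: pd.DataFrame
    toxicity: pd.Series
    panel: PanelMetadata
    grade_class: pd.Series | None = None
    log_scale: bool = False
    missing_report: dict[str, int] = field(default_factory=dict)
    unusable_analytes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.abundance.empty or len(self.abundance.index) == 0:
            raise CohortError("no patients in abundance table")
        if self.abundance.index.has_duplicates:
            dupes = sorted(self.abundance.index[self.abundance.index.duplicated()])
            raise CohortError(f"duplicate patient_id: {dupes}")
        panel_ids = self.panel.analyte_ids
        extra = set(self.abundance.columns) - set(panel_ids)
        if extra:
            raise CohortError(f"analytes absent from panel: {sorted(extra)}")
        missing_cols = set(panel_ids) - set(self.abundance.columns)
        if missing_cols:
            raise CohortError(f"panel analytes missing from table: {sorted(missing_cols)}")
        # normalize to panel (functional-group block) order
        self.abundance = self.abundance[panel_ids].astype(float)
        if not self.toxicity.index.equals(self.abundance.index):
            self.toxicity = self.toxicity.reindex(self.abundance.index)
        if self.toxicity.isna().any():
            missing = sorted(self.toxicity.index[self.toxicity.isna()])
            raise CohortError(f"patients without toxicity label: {missing}")
        bad = set(np.unique(self.toxicity)) - {0, 1}
        if bad:
            raise CohortError(f"cumulative_toxicity must be 0 or 1; found {sorted(bad)}")
        self.toxicity = self.toxicity.astype(int)
        if self.grade_class is not None:
            self.grade_class = self.grade_class.reindex(self.abundance.index)
            bad_grades = set(self.grade_class.dropna()) - set(GRADE_CLASSES)
            if bad_grades:
                raise CohortError(
                    f"grade_class must be one of {GRADE_CLASSES}; found {sorted(bad_grades)}"
                )
        if not self.log_scale:
            with np.errstate(invalid="ignore"):
                if (self.abundance.to_numpy() < 0).any():
                    raise CohortError("raw abundances must be non-negative or missing")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def n_patients(self) -> int:
        return len(self.abundance.index)

    def group_sizes(self) -> tuple[int, int]:
        return int((self.toxicity == 0).sum()), int((self.toxicity == 1).sum())

    def group_frame(self, group: int) -> pd.DataFrame:
        if group not in (0, 1):
            raise CohortError(f"toxicity group must be 0 or 1, got {group}")
        return self.abundance.loc[self.toxicity == group]

    def usable_analytes(self) -> list[str]:
        return [a for a in self.panel.analyte_ids if a not in self.unusable_analytes]

    def drop_analytes(self, analyte_ids: list[str]) -> "CohortTable":
        keep = [a for a in self.panel.analyte_ids if a not in set(analyte_ids)]
        return replace(
            self,
            abundance=self.abundance[keep],
            panel=self.panel.subset(keep),
            missing_report={k: v for k, v in self.missing_report.items() if k in keep},
            unusable_analytes=self.unusable_analytes & set(keep),
        )


def grade_class_proportions(cohort: CohortTable) -> dict[str, float]:
    """Percentage of patients in each toxicity grade class (G0-G1 / G2-G3)."""
    if cohort.grade_class is None:
        raise CohortError("cohort has no grade_class annotations")
    counts = cohort.grade_class.value_counts()
    n = int(counts.sum())
    return {g: 100.0 * int(counts.get(g, 0)) / n for g in GRADE_CLASSES}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep)


def load_cohort(
    abundance_path: str | Path,
    panel_path: str | Path | None = None,
    toxicity_path: str | Path | None = None,
    *,
    panel: PanelMetadata | None = None,
) -> CohortTable:
    """Load and validate a cohort from the abundance/panel/toxicity file trio.

    Either ``panel_path`` or a pre-built ``panel`` must be given. Analyte
    column headers are passed through the alias map, so vendor spelling
    variants resolve to canonical panel ids.
    """
    if panel is None:
        if panel_path is None:
            raise CohortError("either panel_path or panel is required")
        panel = load_panel(panel_path)
    abundance = _read_table(abundance_path)
    if abundance.shape[0] == 0:
        raise CohortError("no patients in abundance table")
    id_col = abundance.columns[0]
    abundance = abundance.set_index(id_col)
    abundance.index = abundance.index.astype(str)
    abundance.index.name = "patient_id"
    abundance.columns = [resolve_analyte_id(c) for c in abundance.columns]
    unknown = set(abundance.columns) - set(panel.analyte_ids)
    if unknown:
        raise CohortError(f"analytes absent from panel: {sorted(unknown)}")

    if toxicity_path is None:
        raise CohortError("toxicity_path is required")
    tox = _read_table(toxicity_path)
    if "patient_id" not in tox.columns or "cumulative_toxicity" not in tox.columns:
        raise CohortError(
            "toxicity file must have columns patient_id, cumulative_toxicity"
        )
    tox["patient_id"] = tox["patient_id"].astype(str)
    if tox["patient_id"].duplicated().any():
        dupes = sorted(tox.loc[tox["patient_id"].duplicated(), "patient_id"])
        raise CohortError(f"duplicate patient_id in toxicity file: {dupes}")
    tox = tox.set_index("patient_id")
    toxicity = tox["cumulative_toxicity"]
    grade = None
    if "grade_class" in tox.columns:
        grade = tox["grade_class"]
    return CohortTable(
        abundance=abundance, toxicity=toxicity, panel=panel, grade_class=grade
    )


def save_cohort(cohort: CohortTable, outdir: str | Path, *, prefix: str = "cohort") -> dict[str, Path]:
    """Write the abundance/panel/toxicity trio; values at full precision."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / f"{prefix}_abundance.csv",
        "panel": outdir / f"{prefix}_panel.csv",
        "toxicity": outdir / f"{prefix}_toxicity.csv",
    }
    cohort.abundance.to_csv(paths["abundance"], index_label="patient_id")
    cohort.panel.save(paths["panel"])
    tox = pd.DataFrame({"cumulative_toxicity": cohort.toxicity})
    if cohort.grade_class is not None:
        tox["grade_class"] = cohort.grade_class
    tox.to_csv(paths["toxicity"], index_label="patient_id")
    return paths


def log_transform(cohort: CohortTable) -> CohortTable:
    """Natural-log transform of the abundance matrix.

    Zero (below detection) and negative values become missing and are
    counted in the per-analyte missingness report. Analytes left with
    fewer than three observed values in either toxicity group are flagged
    unusable for group tests; analytes more than half missing trigger a
    warning.
    """
    if cohort.log_scale:
        raise CohortError("cohort is already log-transformed")
    values = cohort.abundance.to_numpy(dtype=float, copy=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.where(values > 0, np.log(np.where(values > 0, values, 1.0)), np.nan)
    log_df = pd.DataFrame(logged, index=cohort.abundance.index, columns=cohort.abundance.columns)

    report: dict[str, int] = {}
    unusable: set[str] = set()
    n = cohort.n_patients
    mask0 = (cohort.toxicity == 0).to_numpy()
    mask1 = (cohort.toxicity == 1).to_numpy()
    for j, analyte in enumerate(log_df.columns):
        col = logged[:, j]
        n_missing = int(np.isnan(col).sum())
        report[analyte] = n_missing
        if n_missing > 0.5 * n:
            warnings.warn(
                f"analyte {analyte!r}: {n_missing}/{n} values missing after log transform",
                stacklevel=2,
            )
        obs = ~np.isnan(col)
        if (obs & mask0).sum() < MIN_GROUP_OBS or (obs & mask1).sum() < MIN_GROUP_OBS:
            unusable.add(analyte)
    return replace(
        cohort,
        abundance=log_df,
        log_scale=True,
        missing_report=report,
        unusable_analytes=frozenset(unusable),
    )
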