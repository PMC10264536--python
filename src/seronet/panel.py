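"""Analyte panel metadata: identifiers, display names, functional groups.

The bundled default panel describes a 34-analyte serum immuno-profiling
panel: 12 cytokines, 5 chemokines, 13 soluble immune checkpoints,
3 adhesion molecules and one IDO-activity readout (the serum
kynurenine/tryptophan ratio, treated as a single analyte).
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence


class FunctionalGroup(str, enum.Enum):
    """Functional class of a panel analyte; drives ordering and coloring."""

    CYTOKINE = "cytokine"
    CHEMOKINE = "chemokine"
    SOLUBLE_IMMUNE_CHECKPOINT = "soluble_immune_checkpoint"
    ADHESION_MOLECULE = "adhesion_molecule"
    IDO_ACTIVITY = "ido_activity"


#: Canonical block order used for heatmap / network layouts.
GROUP_ORDER: tuple[FunctionalGroup, ...] = (
    FunctionalGroup.CYTOKINE,
    FunctionalGroup.CHEMOKINE,
    FunctionalGroup.SOLUBLE_IMMUNE_CHECKPOINT,
    FunctionalGroup.ADHESION_MOLECULE,
    FunctionalGroup.IDO_ACTIVITY,
)

#: Spelling variants seen in vendor exports and tables, mapped to canonical ids.
ANALYTE_ALIASES: dict[str, str] = {
    "HEVM": "sHVEM",
    "HVEM": "sHVEM",
    "GM-CSF": "GMCSF",
    "TNFalpha": "TNFa",
    "IFNalpha": "IFNa",
    "IFNgamma": "IFNg",
    "sPD-L1": "sPDL1",
    "sPDL-1": "sPDL1",
    "sPD-L2": "sPDL2",
    "sPDL-2": "sPDL2",
    "sCTLA-4": "sCTLA4",
    "sLAG-3": "sLAG3",
    "sTIM-3": "sTIM3",
    "sPD-1": "sPD1",
    "sICAM-1": "sICAM1",
    "sE-selectin": "sEselectin",
    "sP-selectin": "sPselectin",
    "MIP-1a": "MIP1a",
    "MIP-1b": "MIP1b",
    "IP-10": "IP10",
    "MCP-1": "MCP1",
}


class PanelError(ValueError):
    """Raised when a panel definition violates its invariants."""


@dataclass(frozen=True)
class Analyte:
    analyte_id: str
    display_name: str
    functional_group: FunctionalGroup


def resolve_analyte_id(token: str) -> str:
    """Map a (possibly variant) analyte spelling to its canonical id.

    Identifiers are case-sensitive exact tokens; only the listed alias
    spellings are rewritten.
    """
    return ANALYTE_ALIASES.get(token, token)


class PanelMetadata:
    """Ordered collection of panel analytes.

    Analytes are stored in functional-group block order (cytokines,
    chemokines, soluble immune checkpoints, adhesion molecules, IDO
    activity), preserving input order within each block. This ordering is
    the canonical column order for cohorts and heatmaps.
    """

    def __init__(self, analytes: Iterable[Analyte]):
        analytes = list(analytes)
        if not analytes:
            raise PanelError("panel must contain at least one analyte")
        for a in analytes:
            if not a.analyte_id:
                raise PanelError("analyte_id must be non-empty")
            if not isinstance(a.functional_group, FunctionalGroup):
                raise PanelError(
                    f"invalid functional group for {a.analyte_id!r}: "
                    f"{a.functional_group!r}"
                )
        ids = [a.analyte_id for a in analytes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate analyte ids: {dupes}")
        order = {g: i for i, g in enumerate(GROUP_ORDER)}
        self._analytes: tuple[Analyte, ...] = tuple(
            sorted(analytes, key=lambda a: order[a.functional_group])
        )
        self._by_id = {a.analyte_id: a for a in self._analytes}

    @property
    def analytes(self) -> tuple[Analyte, ...]:
        return self._analytes

    @property
    def analyte_ids(self) -> list[str]:
        return [a.analyte_id for a in self._analytes]

    def __len__(self) -> int:
        return len(self._analytes)

    def __contains__(self, analyte_id: str) -> bool:
        return analyte_id in self._by_id

    def __getitem__(self, analyte_id: str) -> Analyte:
        return self._by_id[analyte_id]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PanelMetadata) and self._analytes == other._analytes

    def functional_group(self, analyte_id: str) -> FunctionalGroup:
        return self._by_id[analyte_id].functional_group

    def group_counts(self) -> dict[FunctionalGroup, int]:
        counts = {g: 0 for g in GROUP_ORDER}
        for a in self._analytes:
            counts[a.functional_group] += 1
        return counts

    def subset(self, analyte_ids: Sequence[str]) -> "PanelMetadata":
        """Restrict the panel to the given analytes (block order preserved)."""
        keep = set(analyte_ids)
        missing = keep - set(self.analyte_ids)
        if missing:
            raise PanelError(f"analytes not in panel: {sorted(missing)}")
        return PanelMetadata([a for a in self._analytes if a.analyte_id in keep])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["analyte_id", "display_name", "functional_group"])
            for a in self._analytes:
                writer.writerow([a.analyte_id, a.display_name, a.functional_group.value])


def _parse_panel_rows(rows: Iterable[dict[str, str]]) -> PanelMetadata:
    analytes = []
    for row in rows:
        try:
            group = FunctionalGroup(row["functional_group"].strip())
        except ValueError as exc:
            raise PanelError(
                f"unknown functional group {row['functional_group']!r} "
                f"for analyte {row.get('analyte_id')!r}"
            ) from exc
        analytes.append(
            Analyte(
                analyte_id=resolve_analyte_id(row["analyte_id"].strip()),
                display_name=row.get("display_name", row["analyte_id"]).strip(),
                functional_group=group,
            )
        )
    return PanelMetadata(analytes)


def load_panel(path: str | Path) -> PanelMetadata:
    """Read a panel file (CSV or TSV with a header row)."""
    path = Path(path)
    text = path.read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    required = {"analyte_id", "functional_group"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise PanelError(
            f"panel file must have columns {sorted(required)}; "
            f"found {reader.fieldnames}"
        )
    return _parse_panel_rows(reader)


def default_panel() -> PanelMetadata:
    """The bundled 34-analyte serum panel (12 cytokines, 5 chemokines,
    13 soluble immune checkpoints, 3 adhesion molecules, IDO activity)."""
    text = resources.files("seronet.data").joinpath("default_panel.csv").read_text()
    return _parse_panel_rows(csv.DictReader(io.StringIO(text)))
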