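"""ROI parcellation handling.

The analysis consumes a fixed cortical/subcortical/cerebellar parcellation:
an ordered table of ROIs with millimetre coordinates in RAS atlas space and a
consensus resting-state-network label per ROI.  The table's row order is the
canonical row/column order of every connectivity matrix downstream, so it is
preserved through every operation.

Hemisphere assignment follows the RAS sign convention (x > 0 is right).
ROIs exactly on the midline are rejected by default because the hemispheric
truncation step assumes a clean left/right split; ``midline="drop"`` discards
them instead at load time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import FormatError, MidlineError, ValidationError

#: The 11 analyzed resting-state networks, in canonical display order,
#: as (abbreviation, full name) pairs.
ANALYZED_NETWORKS: tuple[tuple[str, str], ...] = (
    ("SDN", "Somatomotor Dorsal"),
    ("SLN", "Somatomotor Lateral"),
    ("CON", "Cingulo-Opercular"),
    ("AN", "Auditory"),
    ("DMN", "Default Mode"),
    ("PMN", "Parieto-Medial"),
    ("VN", "Visual"),
    ("FPN", "Fronto-Parietal"),
    ("SN", "Salience"),
    ("VAN", "Ventral Attention"),
    ("DAN", "Dorsal Attention"),
)

#: Community labels that exist in the parcellation but are excluded from
#: per-network analysis (less well characterised in the literature).  Their
#: ROIs still participate in the hemisphere-level comparison.
EXCLUDED_NETWORKS: tuple[str, ...] = (
    "Striatal Orbitofrontal Amygdalar",
    "Medial Temporal Lobe",
    "Unlabeled",
)

#: Full controlled vocabulary of network labels (14 names).
CONTROLLED_VOCABULARY: tuple[str, ...] = tuple(
    name for _, name in ANALYZED_NETWORKS
) + EXCLUDED_NETWORKS

_ABBREV_TO_NAME: dict[str, str] = {abbr: name for abbr, name in ANALYZED_NETWORKS}
_NAME_TO_ABBREV: dict[str, str] = {name: abbr for abbr, name in ANALYZED_NETWORKS}

# case-insensitive lookup accepting full names and abbreviations
_CANONICAL: dict[str, str] = {}
for _abbr, _name in ANALYZED_NETWORKS:
    _CANONICAL[_abbr.lower()] = _name
    _CANONICAL[_name.lower()] = _name
for _name in EXCLUDED_NETWORKS:
    _CANONICAL[_name.lower()] = _name


def canonical_network(label: str) -> str:
    """Return the canonical full network name for ``label``.

    Accepts full names or abbreviations, case-insensitively.  Raises
    :class:`ValidationError` for labels outside the controlled vocabulary.
    """
    key = str(label).strip().lower()
    try:
        return _CANONICAL[key]
    except KeyError:
        raise ValidationError(
            f"unknown network label {label!r}; expected one of "
            f"{sorted(set(CONTROLLED_VOCABULARY))} or an abbreviation"
        ) from None


def network_abbreviation(name: str) -> str:
    """Abbreviation for an analyzed network's full name (identity otherwise)."""
    return _NAME_TO_ABBREV.get(name, name)


@dataclass(frozen=True)
class ROIRecord:
    """One ROI: identifier, RAS millimetre coordinates, network label."""

    roi_id: str
    x: float
    y: float
    z: float
    network: str

    def __post_init__(self) -> None:
        for axis, value in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.isfinite(value):
                raise ValidationError(
                    f"ROI {self.roi_id!r}: non-finite {axis} coordinate {value!r}"
                )
        object.__setattr__(self, "network", canonical_network(self.network))


@dataclass(frozen=True)
class ROITable:
    """Ordered ROI table; row order is the canonical matrix order."""

    records: tuple[ROIRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValidationError("ROI table is empty")
        seen: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.roi_id in seen:
                raise ValidationError(
                    f"duplicate roi_id {rec.roi_id!r} at rows "
                    f"{seen[rec.roi_id]} and {i}"
                )
            seen[rec.roi_id] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ROIRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ROIRecord:
        return self.records[i]

    @property
    def roi_ids(self) -> tuple[str, ...]:
        return tuple(rec.roi_id for rec in self.records)

    @property
    def networks(self) -> tuple[str, ...]:
        return tuple(rec.network for rec in self.records)

    @property
    def x(self) -> np.ndarray:
        return np.array([rec.x for rec in self.records], dtype=float)

    def hemispheres(self) -> tuple[str, ...]:
        """Per-ROI hemisphere codes; raises on midline ROIs."""
        return tuple(hemisphere_of(rec) for rec in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "x": self.x,
                "y": [r.y for r in self.records],
                "z": [r.z for r in self.records],
                "network": self.networks,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_roi_table(path, sep: str = "\t", midline: str = "error") -> ROITable:
    """Load and validate an ROI table from delimited text.

    Expected columns: ``roi_id``, ``x``, ``y``, ``z``, ``network`` (header
    row required; extra columns are ignored).  ``midline`` controls handling
    of ROIs with x == 0: ``"error"`` (default) rejects the file, ``"drop"``
    excludes them.
    """
    if midline not in ("error", "drop"):
        raise ValidationError(f"midline policy must be 'error' or 'drop', got {midline!r}")
    try:
        frame = pd.read_csv(path, sep=sep, dtype={"roi_id": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse ROI table {path}: {exc}") from exc
    required = ["roi_id", "x", "y", "z", "network"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"ROI table {path} missing column(s) {missing}")

    records: list[ROIRecord] = []
    offenders: list[str] = []
    for row in frame.itertuples(index=False):
        try:
            rec = ROIRecord(
                roi_id=str(row.roi_id),
                x=float(row.x),
                y=float(row.y),
                z=float(row.z),
                network=str(row.network),
            )
        except ValidationError as exc:
            if "unknown network label" in str(exc):
                offenders.append(f"{row.roi_id}: {row.network!r}")
                continue
            raise
        if rec.x == 0.0:
            if midline == "error":
                raise MidlineError(
                    f"ROI {rec.roi_id!r} lies exactly on the midline (x = 0); "
                    "use midline='drop' to exclude midline ROIs"
                )
            continue
        records.append(rec)
    if offenders:
        raise ValidationError(
            "network label(s) outside the controlled vocabulary: "
            + "; ".join(offenders)
        )
    return ROITable(records=tuple(records), provenance=str(path))


def hemisphere_of(record: ROIRecord) -> str:
    """Hemisphere code for one ROI: ``"R"`` if x > 0, ``"L"`` if x < 0."""
    if not np.isfinite(record.x):
        raise ValidationError(f"ROI {record.roi_id!r}: non-finite x coordinate")
    if record.x > 0:
        return "R"
    if record.x < 0:
        return "L"
    raise MidlineError(f"ROI {record.roi_id!r} lies exactly on the midline (x = 0)")


def contralesional_indices(table: ROITable, lesion_side: str) -> np.ndarray:
    """Canonical-order indices of all ROIs opposite the lesioned hemisphere.

    The hemisphere ipsilateral to the lesion is excluded wholesale; the
    returned indices select the contralesional principal submatrix of any
    whole-brain connectivity matrix in the table's order.
    """
    if lesion_side not in ("L", "R"):
        raise ValidationError(f"lesion_side must be 'L' or 'R', got {lesion_side!r}")
    hemis = table.hemispheres()
    idx = np.array([i for i, h in enumerate(hemis) if h != lesion_side], dtype=int)
    if idx.size == 0:
        raise ValidationError(
            f"no contralesional ROIs: every ROI lies in hemisphere {lesion_side}"
        )
    return idx
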