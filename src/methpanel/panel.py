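"""Marker-panel definition and validation.

A panel is a set of CpG-island *markers*, each interrogated by one or two
MS-qPCR *assays* (a second assay, designed from the reverse-complement strand,
probes a different portion of the same island).  Recovery-control assays are
carried as QC metadata and never enter marker-level scores.

The default panel is the 19-marker / 24-assay urine prostate-cancer panel that
ships with the package (``data/default_panel.yaml``); the machinery itself is
panel-agnostic and validates any config with the same schema.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "Assay",
    "Marker",
    "PanelDefinition",
    "PanelValidationError",
    "load_panel",
    "default_panel",
    "save_panel",
]

STRAND_VARIANTS = ("forward", "reverse-complement")


class PanelValidationError(ValueError):
    """Raised when a panel config violates the panel schema or invariants."""


@dataclass(frozen=True)
class Assay:
    """One MS-qPCR assay interrogating part of a CpG island."""

    assay_id: str
    marker_id: str
    strand_variant: str = "forward"
    bisulfite_group: str = ""

    def __post_init__(self) -> None:
        if self.strand_variant not in STRAND_VARIANTS:
            raise PanelValidationError(
                f"assay {self.assay_id!r}: strand_variant must be one of "
                f"{STRAND_VARIANTS}, got {self.strand_variant!r}"
            )


@dataclass(frozen=True)
class Marker:
    """One CpG-island marker with its one or two assays."""

    marker_id: str
    gene: str
    assay_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.assay_ids) <= 2:
            raise PanelValidationError(
                f"marker {self.marker_id!r} carries {len(self.assay_ids)} assays; "
                "expected 1 or 2"
            )


@dataclass(frozen=True)
class PanelDefinition:
    """A validated marker panel.

    ``control_assays`` are recovery controls (QC only).  ``aliases`` maps
    alternate assay labels to canonical assay ids and is applied on ingest.
    """

    name: str
    markers: tuple[Marker, ...]
    assays: tuple[Assay, ...]
    control_assays: tuple[Assay, ...] = ()
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        marker_ids = [m.marker_id for m in self.markers]
        dupes = _duplicates(marker_ids)
        if dupes:
            raise PanelValidationError(f"duplicate marker ids: {sorted(dupes)}")
        assay_ids = [a.assay_id for a in self.assays]
        dupes = _duplicates(assay_ids + [c.assay_id for c in self.control_assays])
        if dupes:
            raise PanelValidationError(f"duplicate assay ids: {sorted(dupes)}")
        known = set(marker_ids)
        for a in self.assays:
            if a.marker_id not in known:
                raise PanelValidationError(
                    f"assay {a.assay_id!r} references unknown marker {a.marker_id!r}"
                )
        # marker.assay_ids and assay.marker_id must agree exactly
        by_marker: dict[str, set[str]] = {m: set() for m in marker_ids}
        for a in self.assays:
            by_marker[a.marker_id].add(a.assay_id)
        for m in self.markers:
            if set(m.assay_ids) != by_marker[m.marker_id]:
                raise PanelValidationError(
                    f"marker {m.marker_id!r} lists assays {sorted(m.assay_ids)} but "
                    f"panel assays map {sorted(by_marker[m.marker_id])} to it"
                )
        for alias, target in self.aliases.items():
            if target not in {a.assay_id for a in self.assays}:
                raise PanelValidationError(
                    f"alias {alias!r} points at unknown assay {target!r}"
                )

    # -- lookups ------------------------------------------------------------

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(m.marker_id for m in self.markers)

    @property
    def assay_ids(self) -> tuple[str, ...]:
        return tuple(a.assay_id for a in self.assays)

    @property
    def control_assay_ids(self) -> tuple[str, ...]:
        return tuple(a.assay_id for a in self.control_assays)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_assays(self) -> int:
        return len(self.assays)

    @property
    def dual_assay_markers(self) -> tuple[str, ...]:
        return tuple(m.marker_id for m in self.markers if len(m.assay_ids) == 2)

    def marker_for(self, assay_id: str) -> str:
        for a in self.assays:
            if a.assay_id == assay_id:
                return a.marker_id
        raise KeyError(f"unknown assay {assay_id!r}")

    def assays_for(self, marker_id: str) -> tuple[str, ...]:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m.assay_ids
        raise KeyError(f"unknown marker {marker_id!r}")

    def canonical_assay_id(self, assay_id: str) -> str:
        """Resolve an alias to the canonical assay id (identity if canonical)."""
        if assay_id in self.assay_ids or assay_id in self.control_assay_ids:
            return assay_id
        if assay_id in self.aliases:
            return self.aliases[assay_id]
        raise KeyError(f"unknown assay {assay_id!r}")

    # -- serialization ------------------------------------------------------

    def to_config_dict(self) -> dict:
        return {
            "name": self.name,
            "markers": [
                {
                    "marker_id": m.marker_id,
                    "gene": m.gene,
                    "assays": [
                        {
                            "assay_id": a.assay_id,
                            "strand": a.strand_variant,
                            "bisulfite_group": a.bisulfite_group,
                        }
                        for a in self.assays
                        if a.marker_id == m.marker_id
                    ],
                }
                for m in self.markers
            ],
            "controls": [
                {"assay_id": c.assay_id, "bisulfite_group": c.bisulfite_group}
                for c in self.control_assays
            ],
            "aliases": dict(self.aliases),
        }


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def _panel_from_config(cfg: dict) -> PanelDefinition:
    try:
        raw_markers = cfg["markers"]
    except (KeyError, TypeError):
        raise PanelValidationError("panel config must contain a 'markers' list")
    markers: list[Marker] = []
    assays: list[Assay] = []
    for entry in raw_markers:
        mid = entry.get("marker_id")
        if not mid:
            raise PanelValidationError(f"marker entry without marker_id: {entry!r}")
        a_entries = entry.get("assays") or []
        for a in a_entries:
            assays.append(
                Assay(
                    assay_id=a["assay_id"],
                    marker_id=mid,
                    strand_variant=a.get("strand", "forward"),
                    bisulfite_group=a.get("bisulfite_group", ""),
                )
            )
        markers.append(
            Marker(
                marker_id=mid,
                gene=entry.get("gene", mid),
                assay_ids=tuple(a["assay_id"] for a in a_entries),
            )
        )
    controls = tuple(
        Assay(
            assay_id=c["assay_id"],
            marker_id=c["assay_id"],
            strand_variant=c.get("strand", "forward"),
            bisulfite_group=c.get("bisulfite_group", ""),
        )
        for c in cfg.get("controls") or []
    )
    # control Assay.marker_id self-reference is a convention; controls are not
    # part of the marker map and bypass the marker-existence check above.
    panel = PanelDefinition.__new__(PanelDefinition)
    object.__setattr__(panel, "name", cfg.get("name", "unnamed-panel"))
    object.__setattr__(panel, "markers", tuple(markers))
    object.__setattr__(panel, "assays", tuple(assays))
    object.__setattr__(panel, "control_assays", controls)
    object.__setattr__(panel, "aliases", dict(cfg.get("aliases") or {}))
    panel.__post_init__()
    return panel


def load_panel(
    source: str | Path | io.TextIOBase | dict | None = None,
    *,
    expected_markers: int | None = 19,
    expected_assays: int | None = 24,
) -> PanelDefinition:
    """Load and validate a panel definition.

    ``source`` may be a YAML path, an open text stream, an already-parsed
    config dict, or ``None`` for the built-in default panel.  ``expected_*``
    enforce the panel size this pipeline was designed around; pass ``None`` to
    accept panels of any size.
    """
    if source is None:
        cfg = yaml.safe_load(
            resources.files("methpanel.data").joinpath("default_panel.yaml").read_text()
        )
    elif isinstance(source, dict):
        cfg = source
    elif isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = yaml.safe_load(source)
    panel = _panel_from_config(cfg)
    if expected_markers is not None and panel.n_markers != expected_markers:
        raise PanelValidationError(
            f"panel {panel.name!r} defines {panel.n_markers} markers; "
            f"expected {expected_markers}"
        )
    if expected_assays is not None and panel.n_assays != expected_assays:
        raise PanelValidationError(
            f"panel {panel.name!r} defines {panel.n_assays} assays; "
            f"expected {expected_assays}"
        )
    return panel


def default_panel() -> PanelDefinition:
    """The built-in 19-marker / 24-assay urine prostate-cancer panel."""
    return load_panel(None)


def save_panel(panel: PanelDefinition, path: str | Path) -> None:
    """Write a panel back to YAML; ``load_panel`` of the output round-trips."""
    with open(path, "wt") as fh:
        yaml.safe_dump(panel.to_config_dict(), fh, sort_keys=False)
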