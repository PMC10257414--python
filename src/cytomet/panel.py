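"""Marker panel: channel ↔ antibody/metal bookkeeping for a CyTOF acquisition.

A panel entry ties an FCS channel name to the antibody (marker) it reports,
the metal isotope of the conjugate, and a functional class that downstream
stages key on:

* ``phenotypic`` / ``signaling`` — the analysis markers used for gating,
  clustering and scoring;
* ``barcode`` — the combinatorial mass-tag channels used for debarcoding;
* ``viability`` — the cisplatin dead-cell channel (exactly one);
* ``dna`` — iridium DNA-intercalator channels (singlet/debris gating);
* ``other`` — anything else acquired but not analyzed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

MARKER_CLASSES = ("phenotypic", "signaling", "barcode", "viability", "dna", "other")

#: Epithelial / mesenchymal marker triplets of the MET score.
EPITHELIAL_MARKERS = ("EpCAM", "CD49f", "CD9")
MESENCHYMAL_MARKERS = ("Vimentin", "aSMA", "CD44")
MET_MARKERS = EPITHELIAL_MARKERS + MESENCHYMAL_MARKERS


@dataclass(frozen=True)
class PanelEntry:
    channel: str
    marker: str
    metal: str
    cls: str

    def __post_init__(self) -> None:
        if self.cls not in MARKER_CLASSES:
            raise ValueError(
                f"unknown marker class {self.cls!r} for channel {self.channel!r}; "
                f"expected one of {MARKER_CLASSES}"
            )


class MarkerPanel:
    """Ordered collection of :class:`PanelEntry`, the column schema of events.

    Channel names must be unique; marker names must be unique within every
    class except ``other``. Lookup by marker is case-insensitive.
    """

    def __init__(self, entries: Iterable[PanelEntry]):
        self.entries: tuple[PanelEntry, ...] = tuple(entries)
        channels = [e.channel for e in self.entries]
        if len(set(c.lower() for c in channels)) != len(channels):
            raise ValueError("duplicate channel names in panel")
        for cls in MARKER_CLASSES:
            if cls == "other":
                continue
            names = [e.marker.lower() for e in self.entries if e.cls == cls]
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate marker names within class {cls!r}")
        self._marker_index: dict[str, int] = {}
        for i, e in enumerate(self.entries):
            self._marker_index.setdefault(e.marker.lower(), i)
        self._channel_index = {e.channel.lower(): i for i, e in enumerate(self.entries)}

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def channel_names(self) -> list[str]:
        return [e.channel for e in self.entries]

    @property
    def marker_names(self) -> list[str]:
        return [e.marker for e in self.entries]

    def markers_of(self, *classes: str) -> list[str]:
        """Marker names of the given classes, in panel order."""
        return [e.marker for e in self.entries if e.cls in classes]

    def channels_of(self, *classes: str) -> list[str]:
        return [e.channel for e in self.entries if e.cls in classes]

    @property
    def analysis_markers(self) -> list[str]:
        """The phenotypic + signaling markers clustering and scoring act on."""
        return self.markers_of("phenotypic", "signaling")

    def index_of(self, name: str) -> int:
        """Column index for a marker name (preferred) or channel name."""
        key = name.lower()
        if key in self._marker_index:
            return self._marker_index[key]
        if key in self._channel_index:
            return self._channel_index[key]
        raise KeyError(f"marker or channel {name!r} not in panel")

    def __contains__(self, name: str) -> bool:
        key = name.lower()
        return key in self._marker_index or key in self._channel_index

    # -- validation hooks used by downstream stages ------------------------
    def require_gating_channels(self) -> None:
        n_viab = sum(e.cls == "viability" for e in self.entries)
        n_dna = sum(e.cls == "dna" for e in self.entries)
        if n_viab != 1:
            raise ValueError(f"gating needs exactly one viability channel, found {n_viab}")
        if n_dna < 1:
            raise ValueError("gating needs at least one DNA channel")

    def require_met_markers(self) -> None:
        missing = [m for m in MET_MARKERS if m not in self]
        if missing:
            raise ValueError(f"MET scoring needs markers {missing} missing from panel")

    # -- (de)serialization --------------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {"channel": e.channel, "marker": e.marker, "metal": e.metal, "class": e.cls}
            for e in self.entries
        ]

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "MarkerPanel":
        return cls(
            PanelEntry(r["channel"], r["marker"], r["metal"], r["class"]) for r in records
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump({"panel": self.to_records()}, sort_keys=False))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "MarkerPanel":
        """Load from YAML or JSON ({"panel": [{channel, marker, metal, class}]})."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_records(data["panel"])


# --------------------------------------------------------------------------
# Default TNBC panel: 36 analysis markers (23 phenotypic + 13 signaling as
# acquired), 9 barcode isotopes (2 Pt + 7 Cd), cisplatin viability, 2x Ir DNA.
# --------------------------------------------------------------------------

_PHENOTYPIC = [
    ("89Y", "CD45"), ("142Nd", "CD28"), ("143Nd", "CD49f"), ("144Nd", "CD69"),
    ("145Nd", "CD4"), ("146Nd", "CD8a"), ("147Sm", "ITGB5"), ("148Nd", "CD111"),
    ("149Sm", "CD38"), ("150Nd", "CD112"), ("152Sm", "EpCAM"), ("156Gd", "CD29"),
    ("159Tb", "ROR1"), ("160Gd", "CD14"), ("162Dy", "CD49c"), ("165Ho", "CD24"),
    ("166Er", "CD44"), ("167Er", "CD90"), ("169Tm", "CD19"), ("170Er", "CD3"),
    ("171Yb", "CD97"), ("172Yb", "CD9"), ("174Yb", "HLA-DR"), ("175Lu", "CD31"),
    ("176Yb", "CD56"), ("141Pr", "aSMA"), ("154Sm", "Vimentin"), ("173Yb", "PanCK"),
]
_SIGNALING = [
    ("151Eu", "pSmad1/5/9"), ("153Eu", "pStat1"), ("155Gd", "pSmad2"),
    ("158Gd", "pStat3"), ("161Dy", "pNF-kB"), ("163Dy", "pAkt"),
    ("164Dy", "npBcatenin"), ("168Er", "Ki-67"),
]
BARCODE_METALS = ("195Pt", "196Pt", "106Cd", "110Cd", "111Cd", "112Cd",
                  "113Cd", "114Cd", "116Cd")


def tnbc_panel() -> MarkerPanel:
    """The default panel emulating a TNBC CyTOF acquisition."""
    entries = []
    for metal, marker in _PHENOTYPIC:
        entries.append(PanelEntry(f"{metal}_{marker}", marker, metal, "phenotypic"))
    for metal, marker in _SIGNALING:
        entries.append(PanelEntry(f"{metal}_{marker}", marker, metal, "signaling"))
    for i, metal in enumerate(BARCODE_METALS, start=1):
        entries.append(PanelEntry(f"{metal}_BC{i}", f"BC{i}", metal, "barcode"))
    entries.append(PanelEntry("198Pt_Cisplatin", "Cisplatin", "198Pt", "viability"))
    entries.append(PanelEntry("191Ir_DNA1", "DNA1", "191Ir", "dna"))
    entries.append(PanelEntry("193Ir_DNA2", "DNA2", "193Ir", "dna"))
    return MarkerPanel(entries)
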