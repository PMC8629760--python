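"""Versioned, PanelApp-style gene panels.

A panel maps gene symbols to a confidence rating (green = diagnostic grade,
amber, red) and a mode of inheritance. Two snapshots of each panel are
modelled — the version applied when a case was originally analysed
("original") and the current one ("updated") — because that is the
granularity at which re-analysis decisions are made. When several panels
are applied to a case, a gene's effective status is its maximum rating
across them: a variant is treated as diagnostic grade if the gene is Green
on at least one relevant panel.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "RATINGS",
    "MOI_VALUES",
    "VERSION_TAGS",
    "PanelEntry",
    "Panel",
    "PanelAssignment",
    "PanelRegistry",
    "bundled_registry",
]

RATINGS = ("green", "amber", "red")
MOI_VALUES = ("monoallelic", "biallelic", "x_linked", "both")
VERSION_TAGS = ("original", "updated")

_RANK = {"green": 3, "amber": 2, "red": 1, "not_listed": 0}


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    rating: str
    moi: str = "both"

    def __post_init__(self) -> None:
        if self.rating not in RATINGS:
            raise ValueError(f"unknown rating {self.rating!r}")
        if self.moi not in MOI_VALUES:
            raise ValueError(f"unknown mode of inheritance {self.moi!r}")


@dataclass(frozen=True)
class Panel:
    panel_id: str
    version_tag: str
    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        if self.version_tag not in VERSION_TAGS:
            raise ValueError(f"unknown version tag {self.version_tag!r}")
        genes = [e.gene for e in self.entries]
        if len(genes) != len(set(genes)):
            raise ValueError(f"panel {self.panel_id}/{self.version_tag}: duplicate gene")

    def entry(self, gene: str) -> PanelEntry | None:
        for e in self.entries:
            if e.gene == gene:
                return e
        return None


@dataclass(frozen=True)
class PanelAssignment:
    """The panels applied to one case (always at least one)."""

    case_id: str
    panel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.panel_ids:
            raise ValueError(f"case {self.case_id}: no panels assigned")


class PanelRegistry:
    """All known panels, indexed by (panel_id, version_tag)."""

    def __init__(self, panels: list[Panel]):
        self._panels: dict[tuple[str, str], Panel] = {}
        for p in panels:
            key = (p.panel_id, p.version_tag)
            if key in self._panels:
                raise ValueError(f"duplicate panel {key}")
            self._panels[key] = p

    @property
    def panel_ids(self) -> list[str]:
        return sorted({pid for pid, _ in self._panels})

    def panel(self, panel_id: str, version_tag: str) -> Panel:
        try:
            return self._panels[(panel_id, version_tag)]
        except KeyError:
            raise KeyError(f"unknown panel {panel_id!r} at version {version_tag!r}") from None

    def gene_status(self, assignment: PanelAssignment, version_tag: str, gene: str) -> str:
        """Maximum rating of ``gene`` across the applied panels, or ``not_listed``."""
        if not gene:
            raise ValueError("empty gene symbol")
        best = "not_listed"
        for pid in assignment.panel_ids:
            entry = self.panel(pid, version_tag).entry(gene)
            if entry is not None and _RANK[entry.rating] > _RANK[best]:
                best = entry.rating
        return best

    def is_diagnostic_grade(self, assignment: PanelAssignment, version_tag: str, gene: str) -> bool:
        return self.gene_status(assignment, version_tag, gene) == "green"

    def moi(self, assignment: PanelAssignment, version_tag: str, gene: str) -> str | None:
        """Mode of inheritance of the highest-rated entry for the gene, if listed."""
        if not gene:
            raise ValueError("empty gene symbol")
        best: PanelEntry | None = None
        for pid in assignment.panel_ids:
            entry = self.panel(pid, version_tag).entry(gene)
            if entry is not None and (best is None or _RANK[entry.rating] > _RANK[best.rating]):
                best = entry
        return best.moi if best else None

    # -- serialization ------------------------------------------------------

    def to_documents(self) -> list[dict]:
        docs = []
        for (pid, tag), panel in sorted(self._panels.items()):
            docs.append(
                {
                    "panel_id": pid,
                    "version_tag": tag,
                    "entries": [
                        {"gene": e.gene, "rating": e.rating, "moi": e.moi}
                        for e in panel.entries
                    ],
                }
            )
        return docs

    def write(self, path: str | os.PathLike) -> str:
        with open(path, "w") as fh:
            json.dump(self.to_documents(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return str(path)

    @classmethod
    def from_documents(cls, docs: list[dict]) -> "PanelRegistry":
        panels = []
        for doc in docs:
            for key in ("panel_id", "version_tag", "entries"):
                if key not in doc:
                    raise ValueError(f"panel document missing {key!r}")
            panels.append(
                Panel(
                    panel_id=doc["panel_id"],
                    version_tag=doc["version_tag"],
                    entries=tuple(
                        PanelEntry(e["gene"], e["rating"], e.get("moi", "both"))
                        for e in doc["entries"]
                    ),
                )
            )
        return cls(panels)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "PanelRegistry":
        with open(path) as fh:
            return cls.from_documents(json.load(fh))


def bundled_registry() -> PanelRegistry:
    """The panels shipped with the package (synthetic stand-ins that
    reproduce the audited cohort's green / not-green outcomes per gene)."""
    text = resources.files("tieraudit.data").joinpath("panels.json").read_text()
    return PanelRegistry.from_documents(json.loads(text))
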