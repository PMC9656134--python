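"""Indicator metadata registry.

Every diagnostic indicator used by the pipeline carries four pieces of
metadata that downstream stages depend on:

* ``orientation`` — whether a high raw value is unfavourable
  ("destimulant": more density, more contact opportunities) or favourable
  ("stimulant": e.g. more dwelling space per person).  Orientation decides
  which zero-unitarization formula is applied.
* ``nature`` — the thematic group: ``D`` demographic, ``S`` social,
  ``E`` economic, ``L`` land-use / spatial development.  Nature groups
  define the component indices Wd, Ws, Wg, Wzp.
* ``relations`` — the type(s) of interpersonal contact the indicator
  proxies: ``intended`` (deliberate, tie-maintaining: work, family,
  institutions) and/or ``unintended`` (incidental: shops, transit).
  Relation groups define the component indices Wz, Wn.  An indicator may
  carry both tags, so this is a set.
* ``paper_selection`` — the accept/reject outcome recorded in the source
  study for the Polish 2019 data.  Carried as provenance only: the
  pipeline recomputes its own accept/reject via :mod:`epivuln.screening`.

A 33-indicator reference registry (codes ``X1``–``X33``) is packaged with
the library and loaded with :func:`load_packaged_registry`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

ORIENTATIONS = frozenset({"stimulant", "destimulant"})
NATURES = frozenset({"D", "S", "E", "L"})
RELATIONS = frozenset({"intended", "unintended"})

_REQUIRED_COLUMNS = ("code", "label", "orientation", "nature", "relations")


class RegistryError(ValueError):
    """Raised when indicator metadata fails validation."""


@dataclass(frozen=True)
class IndicatorDefinition:
    """Metadata for a single diagnostic indicator."""

    code: str
    label: str
    orientation: str
    nature: str
    relations: frozenset[str]
    paper_selection: str | None = None

    def __post_init__(self) -> None:
        if not self.code:
            raise RegistryError("indicator code must be non-empty")
        if self.orientation not in ORIENTATIONS:
            raise RegistryError(
                f"indicator {self.code!r}: unknown orientation {self.orientation!r} "
                f"(expected one of {sorted(ORIENTATIONS)})"
            )
        if self.nature not in NATURES:
            raise RegistryError(
                f"indicator {self.code!r}: unknown nature {self.nature!r} "
                f"(expected one of {sorted(NATURES)})"
            )
        rel = frozenset(self.relations)
        if not rel or not rel <= RELATIONS:
            raise RegistryError(
                f"indicator {self.code!r}: relations must be a non-empty subset of "
                f"{sorted(RELATIONS)}, got {sorted(self.relations)}"
            )
        object.__setattr__(self, "relations", rel)
        if self.paper_selection is not None and self.paper_selection.lower() not in {
            "accept",
            "reject",
        }:
            raise RegistryError(
                f"indicator {self.code!r}: paper_selection must be accept/reject, "
                f"got {self.paper_selection!r}"
            )
        if self.paper_selection is not None:
            object.__setattr__(self, "paper_selection", self.paper_selection.lower())


@dataclass
class IndicatorRegistry:
    """Ordered, code-unique collection of :class:`IndicatorDefinition`."""

    definitions: list[IndicatorDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for d in self.definitions:
            if d.code in seen:
                raise RegistryError(f"duplicate indicator code {d.code!r}")
            seen.add(d.code)
        self._by_code = {d.code: d for d in self.definitions}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self) -> Iterator[IndicatorDefinition]:
        return iter(self.definitions)

    def __contains__(self, code: object) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> IndicatorDefinition:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"indicator code {code!r} not in registry") from None

    @property
    def codes(self) -> list[str]:
        return [d.code for d in self.definitions]

    # -- queries ------------------------------------------------------------
    def subset_codes(
        self, nature: str | None = None, relation: str | None = None
    ) -> list[str]:
        """Codes matching all given filters, in registry order.

        Parameters
        ----------
        nature
            One of ``D``, ``S``, ``E``, ``L``; ``None`` means no filter.
        relation
            ``"intended"`` or ``"unintended"``; an indicator tagged with both
            matches either filter.
        """
        if nature is not None and nature not in NATURES:
            raise RegistryError(f"unknown nature tag {nature!r}")
        if relation is not None and relation not in RELATIONS:
            raise RegistryError(f"unknown relation tag {relation!r}")
        out = []
        for d in self.definitions:
            if nature is not None and d.nature != nature:
                continue
            if relation is not None and relation not in d.relations:
                continue
            out.append(d.code)
        return out

    def orientation(self, code: str) -> str:
        return self[code].orientation

    def resolve(self, codes: Iterable[str]) -> None:
        """Raise if any of *codes* is absent from the registry."""
        missing = [c for c in codes if c not in self]
        if missing:
            raise RegistryError(f"codes not found in registry: {missing}")

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the registry as CSV (relations pipe-separated)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(list(_REQUIRED_COLUMNS) + ["paper_selection"])
            for d in self.definitions:
                writer.writerow(
                    [
                        d.code,
                        d.label,
                        d.orientation,
                        d.nature,
                        "|".join(sorted(d.relations)),
                        d.paper_selection or "",
                    ]
                )


def _parse_rows(rows: Iterable[dict[str, str]], source: str) -> IndicatorRegistry:
    definitions = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        for col in _REQUIRED_COLUMNS:
            if row.get(col) in (None, ""):
                raise RegistryError(
                    f"{source}: row {i} is missing required field {col!r}"
                )
        relations = frozenset(tok for tok in row["relations"].split("|") if tok)
        definitions.append(
            IndicatorDefinition(
                code=row["code"].strip(),
                label=row["label"].strip(),
                orientation=row["orientation"].strip().lower(),
                nature=row["nature"].strip(),
                relations=relations,
                paper_selection=(row.get("paper_selection") or "").strip() or None,
            )
        )
    return IndicatorRegistry(definitions)


def load_registry(source: str | Path | io.TextIOBase) -> IndicatorRegistry:
    """Load and validate an indicator registry from a CSV file.

    The CSV must have columns ``code,label,orientation,nature,relations``
    (and optionally ``paper_selection``), with relations as pipe-separated
    tokens, e.g. ``intended|unintended``.
    """
    if isinstance(source, io.TextIOBase):
        return _parse_rows(csv.DictReader(source), "<stream>")
    with open(source, newline="") as fh:
        return _parse_rows(csv.DictReader(fh), str(source))


def load_packaged_registry() -> IndicatorRegistry:
    """Load the packaged 33-indicator reference registry (X1..X33)."""
    text = resources.files("epivuln").joinpath("data/indicators.csv").read_text()
    return _parse_rows(csv.DictReader(io.StringIO(text)), "packaged indicators.csv")
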