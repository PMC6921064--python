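"""Declarative diagnostic-marker rules for ITS1 sequence typing.

A rule config is a plain-text table defining named sequence types on a
fixed alignment coordinate system (columns 1..L). Each type carries a list
of markers of four kinds:

``insertion``
    a motif occupying the stated columns (matched with one column of slack
    on either side, since published coordinates are frequently off by one);
``substitution``
    a stated residue at a stated column;
``reduction``
    a reduced motif (not the ancestral one) occupying the stated range
    exactly, written ``REDUCED<ANCESTRAL``;
``repeat``
    a tandem repeat ``UNIT*min-max`` whose consecutive copy count within
    the stated window must fall in [min, max].

Variant types name a ``parent`` base type; a variant marker whose stated
range overlaps a parent required marker *shadows* it (the parent marker is
not required for that variant), which accommodates variants that expand or
overwrite part of a parental diagnostic region.

File format (see ``data/af_its1_rules.txt``)::

    alignment_length = 669
    exclude = 1-109

    [TI]
    insertion    TCACATATA  301 310 required
    ...
    [TIa] parent=TI
    insertion    ATT        580 582 required
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

KINDS = ("insertion", "substitution", "reduction", "repeat")


@dataclass(frozen=True)
class Marker:
    kind: str
    motif: str  # for repeat: the unit; for reduction: the reduced motif
    start: int  # 1-based canonical alignment columns, inclusive
    end: int
    required: bool = True
    ancestral: str | None = None  # reduction only
    n_min: int | None = None  # repeat only
    n_max: int | None = None

    def window(self, L: int, slack: int = 1) -> tuple[int, int]:
        """Columns searched when matching this marker (1-based, inclusive)."""
        lo = max(1, self.start - slack)
        hi = self.end
        if self.kind == "repeat" and self.n_max is not None:
            hi = max(hi, self.start + len(self.motif) * self.n_max - 1)
        if self.kind == "reduction":
            return self.start, self.end  # exact range, no slack
        return lo, min(L, hi + slack)

    def overlaps(self, other: "Marker") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class SequenceTypeDefinition:
    """A named type's diagnostic markers; variants reference a parent."""

    name: str
    markers: list[Marker] = field(default_factory=list)
    parent: str | None = None

    @property
    def is_base(self) -> bool:
        return self.parent is None


@dataclass
class RuleConfig:
    """Ordered collection of type definitions on one alignment frame."""

    types: dict[str, SequenceTypeDefinition]
    alignment_length: int = 669
    excluded_ranges: list[tuple[int, int]] = field(default_factory=list)

    def base_types(self) -> list[SequenceTypeDefinition]:
        return [t for t in self.types.values() if t.is_base]

    def variants_of(self, name: str) -> list[SequenceTypeDefinition]:
        return [t for t in self.types.values() if t.parent == name]

    def is_excluded(self, col: int) -> bool:
        return any(lo <= col <= hi for lo, hi in self.excluded_ranges)

    def effective_markers(self, name: str) -> list[Marker]:
        """Markers checked for ``name``: its own plus the parent's required
        markers not shadowed by an overlapping own marker."""
        t = self.types[name]
        own = list(t.markers)
        if t.parent is None:
            return own
        inherited = []
        for pm in self.types[t.parent].markers:
            if pm.required and not any(m.overlaps(pm) for m in own):
                inherited.append(pm)
        return inherited + own

    def validate(self) -> None:
        seen: set[str] = set()
        for t in self.types.values():
            if t.parent is not None:
                if t.parent not in self.types:
                    raise ValueError(f"{t.name}: unknown parent {t.parent!r}")
                if t.parent not in seen:
                    raise ValueError(f"{t.name}: parent {t.parent!r} must be declared first")
            seen.add(t.name)
            for m in t.markers:
                if not (1 <= m.start <= m.end <= self.alignment_length):
                    raise ValueError(
                        f"{t.name}: marker range {m.start}-{m.end} outside "
                        f"[1, {self.alignment_length}]"
                    )
                if any(self.is_excluded(c) for c in (m.start, m.end)):
                    raise ValueError(
                        f"{t.name}: marker {m.motif} at {m.start}-{m.end} lies in an "
                        "excluded column range"
                    )
                if m.kind not in KINDS:
                    raise ValueError(f"{t.name}: unknown marker kind {m.kind!r}")


_RANGE_RE = re.compile(r"^(\d+)\s*-\s*(\d+)$")


def _parse_motif(kind: str, token: str) -> dict:
    if kind == "repeat":
        m = re.match(r"^([ACGT]+)\*(\d+)-(\d+)$", token)
        if not m:
            raise ValueError(f"repeat motif must look like UNIT*min-max, got {token!r}")
        return {"motif": m.group(1), "n_min": int(m.group(2)), "n_max": int(m.group(3))}
    if kind == "reduction":
        if "<" not in token:
            raise ValueError(f"reduction motif must look like REDUCED<ANCESTRAL, got {token!r}")
        reduced, ancestral = token.split("<", 1)
        return {"motif": reduced, "ancestral": ancestral}
    if not re.fullmatch(r"[ACGT]+", token):
        raise ValueError(f"motif must be plain DNA, got {token!r}")
    return {"motif": token}


def parse_rules(text: str) -> RuleConfig:
    types: dict[str, SequenceTypeDefinition] = {}
    alignment_length = 669
    excluded: list[tuple[int, int]] = []
    current: SequenceTypeDefinition | None = None

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line and not line.startswith("["):
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key == "alignment_length":
                alignment_length = int(val)
            elif key == "exclude":
                m = _RANGE_RE.match(val)
                if not m:
                    raise ValueError(f"line {lineno}: bad exclude range {val!r}")
                excluded.append((int(m.group(1)), int(m.group(2))))
            else:
                raise ValueError(f"line {lineno}: unknown setting {key!r}")
            continue
        if line.startswith("["):
            m = re.match(r"^\[(\S+)\]\s*(?:parent=(\S+))?$", line)
            if not m:
                raise ValueError(f"line {lineno}: bad type header {line!r}")
            name, parent = m.group(1), m.group(2)
            if name in types:
                raise ValueError(f"line {lineno}: duplicate type {name!r}")
            current = SequenceTypeDefinition(name=name, parent=parent)
            types[name] = current
            continue
        if current is None:
            raise ValueError(f"line {lineno}: marker before any [type] header")
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(
                f"line {lineno}: expected 'kind motif start end required|forbidden'"
            )
        kind, motif_token, start_s, end_s, flag = parts
        if flag not in ("required", "forbidden"):
            raise ValueError(f"line {lineno}: flag must be required|forbidden, got {flag!r}")
        fields = _parse_motif(kind, motif_token)
        current.markers.append(
            Marker(
                kind=kind,
                start=int(start_s),
                end=int(end_s),
                required=(flag == "required"),
                **fields,
            )
        )

    cfg = RuleConfig(types=types, alignment_length=alignment_length, excluded_ranges=excluded)
    cfg.validate()
    return cfg


def read_rules(path: str | Path) -> RuleConfig:
    return parse_rules(Path(path).read_text())


def default_rules() -> RuleConfig:
    """The bundled diagnostic-rule table for the *A. fraterculus* complex
    ITS1 types (TI/TIa-TIe, TII/TIIa-TIIc, TIIIA, TIV/TIVa)."""
    text = resources.files("morphoseq").joinpath("data/af_its1_rules.txt").read_text()
    return parse_rules(text)
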