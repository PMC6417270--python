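"""Motif registry and exact residue-class pattern scanning.

Heme-thiolate peroxidases are recognized here through a small grammar of
short, exact sequence motifs rather than probabilistic models.  A pattern
is a fixed-length string of residue classes: a plain letter matches only
itself, ``[ABC]`` matches any listed letter, and ``X`` is a wildcard that
matches every residue including the unknown letter ``X``.  An ``X`` *in
the sequence* matches only wildcard positions — an ambiguous residue is
never allowed to satisfy a specific residue class.

The default registry contains the previously known catalytic core (PCP,
the EGD/EHD distal tripeptides and their EAD/ETD variants) plus sixteen
newly reported conserved motifs: two present in essentially all UPOs
(S[IL]G and SXXRXD), the NHG variant family, and thirteen subfamily
signature motifs.  A disulfide-evidence rule (two cysteines outside the
PCP motif, weak evidence for Subfamily I) is carried as a registry entry
without a positional pattern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from upomine.io_formats import CANONICAL, ProteinRecord

SUBFAMILIES = ("I", "II", "III", "IV", "V")


class RegistryError(ValueError):
    """Raised for malformed patterns or inconsistent registry configs."""


def parse_pattern(pattern: str) -> tuple[frozenset | None, ...]:
    """Compile a pattern string into a tuple of residue classes.

    Returns one entry per position: a frozenset of allowed letters, or
    ``None`` for a wildcard (``X``).
    """
    positions: list[frozenset | None] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise RegistryError(f"pattern {pattern!r}: unterminated class at {i}")
            letters = pattern[i + 1 : j]
            if not letters:
                raise RegistryError(f"pattern {pattern!r}: empty class")
            bad = set(letters) - set(CANONICAL)
            if bad:
                raise RegistryError(
                    f"pattern {pattern!r}: non-canonical letters {sorted(bad)} in class"
                )
            positions.append(frozenset(letters))
            i = j + 1
        elif c == "X":
            positions.append(None)
            i += 1
        elif c in CANONICAL:
            positions.append(frozenset(c))
            i += 1
        else:
            raise RegistryError(f"pattern {pattern!r}: unexpected character {c!r}")
    if len(positions) < 2:
        raise RegistryError(f"pattern {pattern!r}: length must be >= 2")
    return tuple(positions)


def _pattern_regex(pattern: str) -> re.Pattern:
    """Compile a pattern string to an overlapping-match regex.

    A residue class ``[ABC]`` never lists ``X``, so a sequence ``X``
    cannot satisfy it; the wildcard compiles to ``.`` and matches
    everything.  A lookahead group makes overlapping hits visible.
    """
    parts = []
    for cls in parse_pattern(pattern):
        parts.append("." if cls is None else "[" + "".join(sorted(cls)) + "]")
    return re.compile("(?=(" + "".join(parts) + "))")


@dataclass(frozen=True)
class MotifHit:
    """A located motif match; coordinates are 1-based inclusive."""

    motif: str
    start: int
    end: int
    matched: str


@dataclass(frozen=True)
class MotifPattern:
    """A registry entry.

    Parameters
    ----------
    name : str
        Unique registry token (e.g. ``"S[IL]G"``, ``"NHG_family"``).
    patterns : tuple of str
        One or more alternative pattern strings; a hit on any alternative
        is a hit for the motif.  Empty for rule-type entries.
    scope : tuple of str
        ``("all",)`` for motifs present in essentially all UPOs,
        ``("core",)`` for the catalytic grammar elements, or a tuple of
        subfamily labels for signature motifs.
    novel : bool
        True for the newly reported motifs, False for the previously
        known catalytic core.
    kind : str
        ``"pattern"`` for scannable motifs, ``"rule"`` for evidence rules
        with no positional pattern (the Cys-Cys disulfide rule).
    note : str
        Free-text caveats (conflicting subfamily attributions etc.).
    """

    name: str
    patterns: tuple[str, ...]
    scope: tuple[str, ...]
    novel: bool
    kind: str = "pattern"
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("pattern", "rule"):
            raise RegistryError(f"motif {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "pattern" and not self.patterns:
            raise RegistryError(f"motif {self.name!r}: no pattern strings")
        for p in self.patterns:
            parse_pattern(p)  # validates

    @property
    def length(self) -> int:
        return len(parse_pattern(self.patterns[0])) if self.patterns else 0


CYS_PAIR_RULE = "CYS_CYS"

#: Per-subfamily allowed variants of the NHG family (the registry keeps
#: the family as a single motif; which variant counts as signature
#: evidence depends on the subfamily under consideration).
NHG_VARIANTS: Mapping[str, tuple[str, ...]] = {
    "I": ("[SN]HG",),
    "II": ("NHG",),
    "III": ("NHG",),
    "IV": ("NH[GN]", "NYG"),
    "V": ("NHG",),
}

_DEFAULT_ENTRIES: tuple[MotifPattern, ...] = (
    # --- previously known catalytic core ---
    MotifPattern("PCP", ("PCP",), ("core",), novel=False),
    MotifPattern("EGD", ("EGD",), ("core",), novel=False),
    MotifPattern("EHD", ("EHD",), ("core",), novel=False),
    MotifPattern("EAD", ("EAD",), ("core",), novel=False,
                 note="distal variant seen in UPO-like CPO sequences"),
    MotifPattern("ETD", ("ETD",), ("core",), novel=False,
                 note="distal variant seen in UPO-like CPO sequences"),
    # --- newly reported, present in (virtually) all UPOs ---
    MotifPattern("S[IL]G", ("S[IL]G",), ("all",), novel=True,
                 note="Leu observed in three species only; both accepted"),
    MotifPattern("SXXRXD", ("SXXRXD",), ("all",), novel=True,
                 note="absent in MroUPO; requirement relaxable"),
    MotifPattern("NHG_family", ("[SN]HG", "NH[GN]", "NYG"), ("all",), novel=True,
                 note="variants SHG/NHG/NHN/NYG; which variant counts per "
                      "subfamily follows NHG_VARIANTS"),
    # --- newly reported subfamily signatures ---
    MotifPattern("FXD", ("FXD",), ("I",), novel=True),
    MotifPattern(CYS_PAIR_RULE, (), ("I",), novel=True, kind="rule",
                 note="two Cys outside the PCP motif (disulfide evidence); "
                      "weak evidence only"),
    MotifPattern("HXXF", ("HXXF",), ("I", "II", "IV"), novel=True),
    MotifPattern("RGN", ("RGN",), ("II",), novel=True,
                 note="also attributed to Subfamily IV in one analysis; "
                      "the Subfamily II attribution is followed"),
    MotifPattern("IDG", ("IDG",), ("II",), novel=True),
    MotifPattern("TXXXXXXR", ("TXXXXXXR",), ("II",), novel=True),
    MotifPattern("VPPLPG", ("VPPLPG",), ("II",), novel=True),
    MotifPattern("G[ML]G", ("G[ML]G",), ("III",), novel=True,
                 note="also attributed to Subfamily IV in one analysis; "
                      "the Subfamily III attribution is followed"),
    MotifPattern("CDA", ("CDA",), ("IV",), novel=True),
    MotifPattern("FXXXDG", ("FXXXDG",), ("IV",), novel=True),
    MotifPattern("GAAXXXYE", ("GAAXXXYE",), ("IV",), novel=True),
    MotifPattern("EDXXH", ("EDXXH",), ("V",), novel=True),
    MotifPattern("GXG", ("GXG",), ("V",), novel=True),
)


class MotifRegistry:
    """A validated, ordered collection of :class:`MotifPattern` s."""

    def __init__(self, entries: Iterable[MotifPattern]):
        self.entries: tuple[MotifPattern, ...] = tuple(entries)
        names = [e.name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryError(f"duplicate motif names: {sorted(dupes)}")
        self._by_name = {e.name: e for e in self.entries}

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> MotifPattern:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __eq__(self, other) -> bool:
        return isinstance(other, MotifRegistry) and self.entries == other.entries

    @property
    def novel_count(self) -> int:
        """Number of newly reported conserved motifs in the registry."""
        return sum(1 for e in self.entries if e.novel)

    def signature_names(self, subfamily: str) -> tuple[str, ...]:
        """Names of the motifs that count as signatures for a subfamily.

        The NHG family is included for every subfamily (its allowed
        variant differs; see :data:`NHG_VARIANTS`).
        """
        if subfamily not in SUBFAMILIES:
            raise KeyError(f"unknown subfamily {subfamily!r}")
        names = ["NHG_family"] if "NHG_family" in self else []
        names += [
            e.name
            for e in self.entries
            if subfamily in e.scope and e.name != "NHG_family"
        ]
        return tuple(names)


def default_registry() -> MotifRegistry:
    """The built-in motif registry."""
    return MotifRegistry(_DEFAULT_ENTRIES)


def load_registry(config: str | Path | None = None) -> MotifRegistry:
    """Load the motif registry from a YAML config, or the default.

    The config is a list of mappings with keys ``name``, ``patterns``
    (list of pattern strings; may be empty for ``kind: rule``),
    ``scope`` (list), ``novel`` (bool), and optional ``kind``/``note``.
    """
    if config is None:
        return default_registry()
    with open(config) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list):
        raise RegistryError(f"{config}: expected a list of motif entries")
    entries = []
    for item in data:
        try:
            entries.append(
                MotifPattern(
                    name=item["name"],
                    patterns=tuple(item.get("patterns", ())),
                    scope=tuple(item["scope"]),
                    novel=bool(item["novel"]),
                    kind=item.get("kind", "pattern"),
                    note=item.get("note", ""),
                )
            )
        except RegistryError as exc:
            raise RegistryError(f"motif {item.get('name', '?')!r}: {exc}") from exc
    return MotifRegistry(entries)


def save_registry(registry: MotifRegistry, path: str | Path) -> None:
    """Write a registry as a YAML config loadable by :func:`load_registry`."""
    data = [
        {
            "name": e.name,
            "patterns": list(e.patterns),
            "scope": list(e.scope),
            "novel": e.novel,
            "kind": e.kind,
            "note": e.note,
        }
        for e in registry
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def scan_motif(pattern: MotifPattern, seq: ProteinRecord | str) -> list[MotifHit]:
    """Locate every (possibly overlapping) occurrence of a motif.

    Hits are returned ordered by start position (ties broken by the
    order of the motif's alternative patterns).  Rule-type entries have
    no positional pattern and yield no hits here.
    """
    residues = seq.residues if isinstance(seq, ProteinRecord) else seq
    hits: list[MotifHit] = []
    for k, p in enumerate(pattern.patterns):
        rx = _pattern_regex(p)
        for m in rx.finditer(residues):
            s = m.start() + 1
            matched = m.group(1)
            hits.append(MotifHit(pattern.name, s, s + len(matched) - 1, matched))
    hits.sort(key=lambda h: (h.start, h.matched))
    return hits


def scan_registry(
    registry: MotifRegistry, seq: ProteinRecord | str
) -> dict[str, list[MotifHit]]:
    """Scan every pattern motif of a registry against one sequence."""
    return {e.name: scan_motif(e, seq) for e in registry if e.kind == "pattern"}


def cys_pair_evidence(seq: ProteinRecord | str, pcp_start: int | None) -> bool:
    """Disulfide evidence rule: >= 2 cysteines outside the PCP motif.

    ``pcp_start`` is the 1-based start of the PCP hit to exclude (its
    central residue is the proximal heme-ligating Cys); ``None`` counts
    all cysteines.
    """
    residues = seq.residues if isinstance(seq, ProteinRecord) else seq
    excluded = range(pcp_start, pcp_start + 3) if pcp_start else range(0)
    n = sum(
        1 for i, c in enumerate(residues, start=1) if c == "C" and i not in excluded
    )
    return n >= 2


def matches_variant(hit: MotifHit, variant_patterns: Sequence[str]) -> bool:
    """Whether a hit's matched substring satisfies any of the given patterns."""
    for p in variant_patterns:
        classes = parse_pattern(p)
        if len(classes) != len(hit.matched):
            continue
        ok = True
        for c, cls in zip(hit.matched, classes):
            if cls is None:
                continue
            if c not in cls:
                ok = False
                break
        if ok:
            return True
    return False
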