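"""Homologous DEG pairing and multiplicity classification.

Pairing is symbol-level curation: a curated ortholog map (exact normalized
symbols plus explicit cross-species entries) decides orthology, a curated
family map decides paralog support, and a prefix heuristic is only a
fallback for symbols outside the curation. No sequence comparison happens
here.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core_model import DEGRecord, _fixture_text

__all__ = [
    "Relation",
    "MultiplicityClass",
    "HomologPair",
    "HomologyMaps",
    "normalize_symbol",
    "family_root",
    "pair_homologs",
    "classify_pairs",
    "load_maps",
    "default_maps",
]


class Relation(str, enum.Enum):
    ORTHOLOG = "ORTHOLOG"
    PARALOG_SUPPORT = "PARALOG_SUPPORT"


class MultiplicityClass(str, enum.Enum):
    ORTHOLOG_MULTI = "ORTHOLOG_MULTI"
    ORTHOLOG_SINGLE = "ORTHOLOG_SINGLE"
    PARALOG_SUPPORT = "PARALOG_SUPPORT"


@dataclass(frozen=True)
class HomologPair:
    focal: DEGRecord
    comparison: DEGRecord
    relation: Relation
    multiplicity_class: MultiplicityClass | None = None
    pair_id: int | None = None

    @property
    def sign_concordant(self) -> bool:
        return self.focal.log2fc * self.comparison.log2fc > 0

    def __post_init__(self) -> None:
        if self.multiplicity_class in (
            MultiplicityClass.ORTHOLOG_MULTI,
            MultiplicityClass.ORTHOLOG_SINGLE,
        ) and self.relation is not Relation.ORTHOLOG:
            raise ValueError("ortholog multiplicity classes require an ORTHOLOG relation")


@dataclass(frozen=True)
class HomologyMaps:
    """Curated symbol-level homology: aliases, ortholog sets, family roots."""

    alias_map: Mapping[str, str] = field(default_factory=dict)
    ortholog_map: Mapping[str, frozenset[str]] = field(default_factory=dict)
    family_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, dst in self.alias_map.items():
            if dst in self.alias_map and self.alias_map[dst] != dst:
                raise ValueError(f"alias_map is not idempotent at {src!r} -> {dst!r}")
        for sym, root in self.family_map.items():
            if not root:
                raise ValueError(f"empty family root for {sym!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "HomologyMaps":
        return cls(
            alias_map=dict(d.get("alias_map", {})),
            ortholog_map={k: frozenset(v) for k, v in d.get("ortholog_map", {}).items()},
            family_map=dict(d.get("family_map", {})),
        )

    def to_dict(self) -> dict:
        return {
            "alias_map": dict(self.alias_map),
            "ortholog_map": {k: sorted(v) for k, v in self.ortholog_map.items()},
            "family_map": dict(self.family_map),
        }


_MARKUP_RE = re.compile(r"[*_`\s]+")


def normalize_symbol(raw: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Lowercase, strip markup/whitespace and apply the alias map once."""
    if raw is None or not str(raw).strip():
        raise ValueError("empty gene symbol")
    sym = _MARKUP_RE.sub("", str(raw)).lower()
    if not sym:
        raise ValueError(f"symbol {raw!r} is empty after normalization")
    if alias_map:
        sym = alias_map.get(sym, sym)
    return sym


def _shared_alpha_prefix(a: str, b: str) -> str:
    out = []
    for ca, cb in zip(a, b):
        if ca != cb or not ca.isalpha():
            break
        out.append(ca)
    return "".join(out)


def family_root(symbol: str, family_map: Mapping[str, str]) -> str:
    """Curated family root, or the symbol itself when uncurated."""
    return family_map.get(symbol, symbol)


def _same_family(a: str, b: str, maps: HomologyMaps, *,
                 use_fallback: bool, min_prefix: int) -> bool:
    in_a, in_b = a in maps.family_map, b in maps.family_map
    if in_a and in_b:
        return maps.family_map[a] == maps.family_map[b]
    if in_a or in_b:
        # curation wins: a curated symbol never merges with an uncurated one
        # through the prefix heuristic
        curated = maps.family_map[a] if in_a else maps.family_map[b]
        other = b if in_a else a
        return other == curated
    if not use_fallback:
        return False
    prefix = _shared_alpha_prefix(a, b)
    return len(prefix) >= min_prefix and a != b


def pair_homologs(
    focal_degs: Sequence[DEGRecord],
    comparison_degs: Sequence[DEGRecord],
    maps: HomologyMaps,
    *,
    use_prefix_fallback: bool = True,
    min_prefix: int = 2,
) -> list[HomologPair]:
    """Cartesian symbol matching of focal against comparison DEGs.

    A pair is emitted with relation ORTHOLOG when the comparison symbol is in
    the curated ortholog set of the focal symbol (or the normalized symbols
    are identical), and with relation PARALOG_SUPPORT when the two symbols
    share a family root. Output order is deterministic: focal symbol,
    comparison symbol, then source.
    """
    pairs: list[HomologPair] = []
    seen: set[tuple] = set()
    for focal in focal_degs:
        fsym = normalize_symbol(focal.symbol, maps.alias_map)
        ortho_set = maps.ortholog_map.get(fsym, frozenset())
        for comp in comparison_degs:
            csym = normalize_symbol(comp.symbol, maps.alias_map)
            if csym in ortho_set or csym == fsym:
                relation = Relation.ORTHOLOG
            elif _same_family(fsym, csym, maps,
                              use_fallback=use_prefix_fallback, min_prefix=min_prefix):
                relation = Relation.PARALOG_SUPPORT
            else:
                continue
            key = (fsym, csym, comp.species, comp.tissue, comp.source_id,
                   comp.log2fc, focal.log2fc)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(HomologPair(focal=focal, comparison=comp, relation=relation))
    pairs.sort(key=_pair_sort_key)
    return [replace(p, pair_id=i + 1) for i, p in enumerate(pairs)]


def _pair_sort_key(p: HomologPair):
    return (
        normalize_symbol(p.focal.symbol),
        normalize_symbol(p.comparison.symbol),
        p.comparison.source_id,
        p.comparison.species,
        p.comparison.tissue,
        p.comparison.log2fc,
    )


def classify_pairs(pairs: Sequence[HomologPair]) -> list[HomologPair]:
    """Fill multiplicity classes from per-focal-gene pair counts.

    For each focal gene, k = number of pairs it participates in across all
    comparison studies and tissues pooled. ORTHOLOG pairs become
    ORTHOLOG_MULTI when k >= 2 and ORTHOLOG_SINGLE when k == 1;
    PARALOG_SUPPORT pairs keep their class.
    """
    counts: dict[str, int] = {}
    for p in pairs:
        fsym = normalize_symbol(p.focal.symbol)
        counts[fsym] = counts.get(fsym, 0) + 1
    out = []
    for p in pairs:
        if p.relation is Relation.PARALOG_SUPPORT:
            cls = MultiplicityClass.PARALOG_SUPPORT
        elif counts[normalize_symbol(p.focal.symbol)] >= 2:
            cls = MultiplicityClass.ORTHOLOG_MULTI
        else:
            cls = MultiplicityClass.ORTHOLOG_SINGLE
        out.append(replace(p, multiplicity_class=cls))
    return out


def load_maps(path: str | Path) -> HomologyMaps:
    with Path(path).open() as fh:
        return HomologyMaps.from_dict(json.load(fh))


def default_maps() -> HomologyMaps:
    """The packaged curated maps matching the bundled 54-pair table."""
    return HomologyMaps.from_dict(json.loads(_fixture_text("homology_maps.json")))
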