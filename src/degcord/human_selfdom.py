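"""Mapping animal DEG divergence directions to human gene-effect annotations.

Each animal DEG's log2 sign splits the divergence from the most recent
common ancestor into a deficit side and an excess side (the numerator of
the fold change is the domestic/tame group). The curated human annotation
then translates each side into a decreased/increased effect on
reproductive potential, and the resulting calls are tallied into a
domestic-vs-wild by decreased-vs-increased contingency table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .stats import (
    ContingencyTable2x2,
    TestResult,
    binomial_sign_test,
    chi2_2x2,
    fisher_exact_2x2,
)

__all__ = [
    "HumanEffectAnnotation",
    "DivergenceCall",
    "assign_divergence_sides",
    "map_to_human_effect",
    "build_reproductive_table",
    "read_annotations",
    "read_animal_rows",
]

_EFFECTS = ("decreased", "increased")


@dataclass(frozen=True)
class HumanEffectAnnotation:
    human_gene: str
    effect_of_deficit: str  # effect on reproductive potential when under-expressed
    effect_of_excess: str
    evidence_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for eff in (self.effect_of_deficit, self.effect_of_excess):
            if eff not in _EFFECTS:
                raise ValueError(f"effect must be one of {_EFFECTS}, got {eff!r}")


@dataclass(frozen=True)
class DivergenceCall:
    pair_id: str
    domestic_state: str  # "deficit" | "excess"
    wild_state: str
    domestic_effect: str  # "decreased" | "increased"
    wild_effect: str

    def __post_init__(self) -> None:
        if self.domestic_state == self.wild_state:
            raise ValueError("domestic and wild states must differ")


def assign_divergence_sides(log2fc: float) -> tuple[str, str]:
    """(domestic_state, wild_state) from the sign of the log2 fold change."""
    if log2fc == 0:
        raise ValueError("zero log2fc carries no divergence direction")
    return ("deficit", "excess") if log2fc < 0 else ("excess", "deficit")


def map_to_human_effect(
    sides: tuple[str, str], annotation: HumanEffectAnnotation, pair_id: str = ""
) -> DivergenceCall:
    """Translate deficit/excess sides through the annotation's arrows."""
    domestic_state, wild_state = sides
    lookup = {
        "deficit": annotation.effect_of_deficit,
        "excess": annotation.effect_of_excess,
    }
    return DivergenceCall(
        pair_id=pair_id or annotation.human_gene,
        domestic_state=domestic_state,
        wild_state=wild_state,
        domestic_effect=lookup[domestic_state],
        wild_effect=lookup[wild_state],
    )


def build_reproductive_table(calls: Sequence[DivergenceCall]) -> dict:
    """2x2 of divergence side (domestic/wild) by mapped effect, with tests.

    Every call contributes exactly one count to each row. Returns the
    table plus uncorrected chi-square, one-sided Fisher exact, and
    per-row majority-direction binomial sign tests.
    """
    if not calls:
        raise ValueError("no calls")
    dom_dec = sum(c.domestic_effect == "decreased" for c in calls)
    wild_dec = sum(c.wild_effect == "decreased" for c in calls)
    n = len(calls)
    table = ContingencyTable2x2(
        a=dom_dec, b=n - dom_dec, c=wild_dec, d=n - wild_dec,
        row_labels=("domestic", "wild"), col_labels=("decreased", "increased"),
    )
    try:
        chi2 = chi2_2x2(table, continuity_correction=False)
    except ValueError:
        chi2 = None
    return {
        "table": table,
        "chi2": chi2,
        "fisher": fisher_exact_2x2(table, sided="one"),
        "binomial_domestic": binomial_sign_test(max(table.a, table.b), n),
        "binomial_wild": binomial_sign_test(max(table.c, table.d), n),
    }


def read_annotations(path: str | Path) -> dict[str, HumanEffectAnnotation]:
    with Path(path).open(newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return {
        r["human_gene"]: HumanEffectAnnotation(
            human_gene=r["human_gene"],
            effect_of_deficit=r["effect_of_deficit"],
            effect_of_excess=r["effect_of_excess"],
            evidence_refs=tuple((r.get("evidence_refs") or "").split(";")),
        )
        for r in rows
    }


def read_animal_rows(path: str | Path) -> list[dict]:
    with Path(path).open(newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    for r in rows:
        r["log2fc"] = float(r["log2fc"].replace("−", "-"))
    return rows


def calls_from_animal_rows(
    animal_rows: Sequence[Mapping], annotations: Mapping[str, HumanEffectAnnotation]
) -> list[DivergenceCall]:
    calls = []
    for i, row in enumerate(animal_rows, start=1):
        gene = row["human_gene"]
        if gene not in annotations:
            raise KeyError(f"no effect annotation for human gene {gene!r}")
        sides = assign_divergence_sides(float(row["log2fc"]))
        calls.append(
            map_to_human_effect(sides, annotations[gene],
                                pair_id=f"{gene}:{row.get('animal_deg', i)}:{i}")
        )
    return calls
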