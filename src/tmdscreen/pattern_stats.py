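"""Charge-pattern statistics over isolated TMD pairs.

Classifies pairs by the charge relationship of their ionizable residues,
tabulates residue positions and spacings per affinity class, and computes
the overrepresentation of a sequence pattern among screen isolates against
its prior probability under uniform sampling of the enumerated library.
The prior is always obtained by exhaustive enumeration of the full ordered
pair space; closed forms are used only as cross-checks in the tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from tmdscreen.library_design import (
    RANDOMIZED_POSITIONS,
    TMDPair,
    enumerate_pairs,
)

__all__ = [
    "ChargePairClass",
    "PatternPredicate",
    "OverrepResult",
    "classify_charge_pair",
    "residue_spacing",
    "within_spacing",
    "positional_distribution",
    "count_matching",
    "overrepresentation",
    "summarize_by_class",
    "OPPOSITE_AT_6_7",
]

CHARGE_PAIR_CLASSES = ("opposite", "like", "single", "none")


@dataclass(frozen=True)
class ChargePairClass:
    value: str

    def __post_init__(self):
        if self.value not in CHARGE_PAIR_CLASSES:
            raise ValueError(f"unknown charge-pair class {self.value!r}")


def classify_charge_pair(pair: TMDPair) -> ChargePairClass:
    """opposite / like when both TMDs are charged, else single / none."""
    sn, sc = pair.n_variant.charge_sign, pair.c_variant.charge_sign
    if sn != 0 and sc != 0:
        return ChargePairClass("opposite" if sn != sc else "like")
    if sn != 0 or sc != 0:
        return ChargePairClass("single")
    return ChargePairClass("none")


def residue_spacing(pair: TMDPair) -> Optional[int]:
    """|position(N) - position(C)| when both TMDs are charged, else None."""
    pn, pc = pair.n_variant.position, pair.c_variant.position
    if pn is None or pc is None:
        return None
    return abs(pn - pc)


def within_spacing(
    pairs: Sequence[TMDPair], threshold: int = 5
) -> dict[str, Optional[float]]:
    """Per affinity class: fraction of both-charged pairs whose ionizable
    residues are within ``threshold`` positions of each other (inclusive).

    A class with no eligible (both-charged) pair maps to None, not 0.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    eligible: dict[str, list[int]] = {}
    for pair in pairs:
        if pair.affinity_class is None:
            raise ValueError(f"pair {pair.pair_id} carries no affinity class")
        spacing = residue_spacing(pair)
        if spacing is None:
            continue
        eligible.setdefault(pair.affinity_class, []).append(spacing)
    out: dict[str, Optional[float]] = {}
    classes = {p.affinity_class for p in pairs}
    for cls in classes:
        spacings = eligible.get(cls)
        out[cls] = (
            None
            if not spacings
            else sum(s <= threshold for s in spacings) / len(spacings)
        )
    return out


def positional_distribution(pairs: Sequence[TMDPair]) -> pd.DataFrame:
    """Counts of ionizable residues per position, split by plasmid side and
    affinity class.

    Returns a long-format frame with columns (affinity_class, side,
    position, count); sides are "N" and "C".  Pairs without an affinity
    class are tallied under the class "all".
    """
    counter: Counter[tuple[str, str, int]] = Counter()
    for pair in pairs:
        cls = pair.affinity_class or "all"
        if pair.n_variant.position is not None:
            counter[(cls, "N", pair.n_variant.position)] += 1
        if pair.c_variant.position is not None:
            counter[(cls, "C", pair.c_variant.position)] += 1
    classes = sorted({p.affinity_class or "all" for p in pairs})
    rows = [
        {
            "affinity_class": cls,
            "side": side,
            "position": pos,
            "count": counter.get((cls, side, pos), 0),
        }
        for cls in classes
        for side in ("N", "C")
        for pos in RANDOMIZED_POSITIONS
    ]
    return pd.DataFrame(
        rows, columns=["affinity_class", "side", "position", "count"]
    )


@dataclass(frozen=True)
class PatternPredicate:
    """A sequence pattern over a TMD pair.

    ``position_set`` restricts where the two ionizable residues may sit
    (None = anywhere); with exactly two positions given, one TMD must carry
    its residue at one position and the partner at the other.
    ``charge_relation`` is "opposite", "like" or "any".
    """

    position_set: Optional[frozenset[int]] = None
    charge_relation: str = "any"

    def __post_init__(self):
        if self.charge_relation not in ("opposite", "like", "any"):
            raise ValueError(
                f"unknown charge relation {self.charge_relation!r}"
            )
        if self.position_set is not None:
            object.__setattr__(
                self, "position_set", frozenset(self.position_set)
            )
            extra = self.position_set - set(RANDOMIZED_POSITIONS)
            if extra:
                raise ValueError(
                    f"positions {sorted(extra)} outside randomized set"
                )

    def matches(self, pair: TMDPair) -> bool:
        relation = classify_charge_pair(pair).value
        if self.charge_relation != "any":
            if relation != self.charge_relation:
                return False
        if self.position_set is not None:
            pn = pair.n_variant.position
            pc = pair.c_variant.position
            if pn is None or pc is None:
                return False
            if pn not in self.position_set or pc not in self.position_set:
                return False
            # with two distinct positions required, each TMD takes one
            if len(self.position_set) == 2 and pn == pc:
                return False
        return True


# the headline pattern: oppositely charged residues, one at position 6 and
# the other at position 7
OPPOSITE_AT_6_7 = PatternPredicate(
    position_set=frozenset({6, 7}), charge_relation="opposite"
)


def count_matching(
    predicate: PatternPredicate,
    library: Optional[Sequence[TMDPair]] = None,
) -> int:
    """Exhaustive count of library pairs satisfying the predicate."""
    if library is None:
        library = enumerate_pairs()
    return sum(predicate.matches(pair) for pair in library)


@dataclass(frozen=True)
class OverrepResult:
    """Observed-vs-expected abundance of a pattern among screen isolates."""

    matching_pairs: int
    total_pairs: int
    p_prior: float
    n_isolates: int
    expected: float
    observed: int
    factor_raw: Optional[float]
    factor_rounded: Optional[int]

    def report(self) -> dict:
        """Values at the precision used for reporting (raw values kept)."""
        return {
            "matching_pairs": self.matching_pairs,
            "total_pairs": self.total_pairs,
            "p_prior": round(self.p_prior, 4),
            "n_isolates": self.n_isolates,
            "expected": round(self.expected, 2),
            "observed": self.observed,
            "factor": self.factor_rounded,
            "p_prior_raw": self.p_prior,
            "expected_raw": self.expected,
            "factor_raw": self.factor_raw,
        }


def overrepresentation(
    predicate: PatternPredicate,
    n_isolates: int,
    observed: int,
    library: Optional[Sequence[TMDPair]] = None,
) -> OverrepResult:
    """Observed count of a pattern among ``n_isolates`` sequenced pairs
    versus the count expected under uniform sampling of the library."""
    if observed < 0 or n_isolates < observed:
        raise ValueError("need n_isolates >= observed >= 0")
    if library is None:
        library = enumerate_pairs()
    matching = count_matching(predicate, library)
    total = len(library)
    p_prior = matching / total
    expected = p_prior * n_isolates
    if expected > 0:
        factor_raw: Optional[float] = observed / expected
        factor_rounded: Optional[int] = round(factor_raw)
    elif observed == 0:
        factor_raw, factor_rounded = 0.0, 0
    else:
        factor_raw, factor_rounded = None, None  # undefined, flagged by None
    return OverrepResult(
        matching_pairs=matching,
        total_pairs=total,
        p_prior=p_prior,
        n_isolates=n_isolates,
        expected=expected,
        observed=observed,
        factor_raw=factor_raw,
        factor_rounded=factor_rounded,
    )


def summarize_by_class(pairs: Sequence[TMDPair]) -> pd.DataFrame:
    """Charge-pair category counts and fractions per affinity class.

    Duplicate isolates are weighted by ``observed_count`` when set (a count
    of 0 is treated as a single observation).  Fractions sum to 1 within
    each non-empty class.
    """
    counter: Counter[tuple[str, str]] = Counter()
    for pair in pairs:
        if pair.affinity_class is None:
            raise ValueError(f"pair {pair.pair_id} carries no affinity class")
        weight = pair.observed_count if pair.observed_count > 0 else 1
        category = classify_charge_pair(pair).value
        counter[(pair.affinity_class, category)] += weight
    totals: Counter[str] = Counter()
    for (cls, _), n in counter.items():
        totals[cls] += n
    rows = []
    for cls in sorted(totals):
        for category in CHARGE_PAIR_CLASSES:
            n = counter.get((cls, category), 0)
            rows.append(
                {
                    "affinity_class": cls,
                    "category": category,
                    "count": n,
                    "fraction": n / totals[cls],
                }
            )
    return pd.DataFrame(
        rows, columns=["affinity_class", "category", "count", "fraction"]
    )


def load_isolates(path) -> list[TMDPair]:
    """Read an isolate TSV (n_position, n_residue, c_position, c_residue,
    observed_count, optional percent_of_reference) into TMDPair objects."""
    from tmdscreen.dose_response import classify_affinity
    from tmdscreen.library_design import WILD_TYPE, make_variant

    df = pd.read_csv(path, sep="\t")
    required = {"n_position", "n_residue", "c_position", "c_residue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"isolate table missing columns {sorted(missing)}")

    def _variant(pos, res):
        if pd.isna(pos) or pos in ("", None):
            return WILD_TYPE
        return make_variant(int(pos), str(res))

    pairs = []
    for _, row in df.iterrows():
        percent = row.get("percent_of_reference")
        percent = None if pd.isna(percent) else float(percent)
        pairs.append(
            TMDPair(
                n_variant=_variant(row["n_position"], row["n_residue"]),
                c_variant=_variant(row["c_position"], row["c_residue"]),
                observed_count=int(row.get("observed_count", 1) or 1),
                percent_of_reference=percent,
                affinity_class=(
                    classify_affinity(percent) if percent is not None else None
                ),
            )
        )
    return pairs


def isolates_to_frame(pairs: Iterable[TMDPair]) -> pd.DataFrame:
    """Inverse of :func:`load_isolates` (for writing isolate TSVs)."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "n_position": p.n_variant.position,
                "n_residue": p.n_variant.residue,
                "c_position": p.c_variant.position,
                "c_residue": p.c_variant.residue,
                "observed_count": p.observed_count,
                "percent_of_reference": p.percent_of_reference,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "n_position",
            "n_residue",
            "c_position",
            "c_residue",
            "observed_count",
            "percent_of_reference",
        ],
    )
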