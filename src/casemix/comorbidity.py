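"""Charlson comorbidity scoring from ICD-10 co-existing diagnosis codes.

ICD-10 codes are mapped to the 17 Charlson condition categories with Quan's
ICD-10 coding algorithm (prefix matching on normalized codes), scored with the
original Charlson weights (1/2/3/6), and the total is collapsed into the five
bands used by the case-mix mortality model: 0, 1-2, 3-6, 7-12, 13 and over.

Hierarchy rules are applied before scoring so that a dominant condition
suppresses its milder counterpart (metastatic solid tumor > any malignancy,
moderate/severe liver disease > mild liver disease, diabetes with chronic
complication > uncomplicated diabetes).  Only co-existing diagnoses — never
the primary diagnosis — should be fed to these functions.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "BANDS",
    "CharlsonMap",
    "CharlsonResult",
    "load_quan_map",
    "map_codes",
    "charlson_score",
    "band",
    "score_codes",
    "score_code_strings",
]

#: Charlson score bands, ordered.  "13-" means 13 and over.
BANDS = ("0", "1-2", "3-6", "7-12", "13-")

_RESOURCE = "quan_icd10.tsv"
_RESOURCE_SHA256 = "d09886d19b197717a06e5d899fa1ac28f843dc88387a99c403e571e4f597ba87"

#: (dominant, suppressed): the dominant condition removes the suppressed one
#: from the scored set.  Dominant weights always exceed suppressed weights,
#: so scores are monotone in the code list.
HIERARCHY_PAIRS = (
    ("metastatic_solid_tumor", "malignancy"),
    ("moderate_severe_liver", "mild_liver_disease"),
    ("diabetes_complicated", "diabetes_uncomplicated"),
)

_ALLOWED_WEIGHTS = frozenset({1, 2, 3, 6})


class ResourceError(RuntimeError):
    """The embedded coding table failed its integrity check."""


@dataclass(frozen=True)
class CharlsonMap:
    """Quan's ICD-10 → Charlson condition table plus hierarchy rules.

    ``entries`` holds one ``(condition, prefixes, weight)`` triple per
    condition; prefixes are uppercase, dot-stripped, 3-4 characters.
    """

    entries: tuple[tuple[str, frozenset[str], int], ...]
    hierarchy_pairs: tuple[tuple[str, str], ...] = HIERARCHY_PAIRS

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.entries)

    @property
    def weights(self) -> dict[str, int]:
        return {name: w for name, _, w in self.entries}

    def prefixes_of(self, condition: str) -> frozenset[str]:
        for name, prefixes, _ in self.entries:
            if name == condition:
                return prefixes
        raise KeyError(condition)

    def prefix_lookup(self) -> dict[str, str]:
        """Flat prefix → condition dictionary (prefixes are unique overall)."""
        table: dict[str, str] = {}
        for name, prefixes, _ in self.entries:
            for p in prefixes:
                table[p] = name
        return table

    def to_tsv(self) -> str:
        lines = ["condition\tweight\tprefixes"]
        for name, prefixes, w in self.entries:
            lines.append(f"{name}\t{w}\t{','.join(sorted(prefixes))}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CharlsonResult:
    """Outcome of scoring one diagnosis-code list."""

    conditions: frozenset[str]
    score: int
    band: str
    unmatched: tuple[str, ...] = field(default=())


@lru_cache(maxsize=1)
def load_quan_map() -> CharlsonMap:
    """Load the embedded Quan 2005 coding table (original Charlson weights).

    Raises
    ------
    ResourceError
        If the packaged TSV does not match its recorded sha256 checksum or
        violates the structural invariants (17 conditions, weights in
        {1,2,3,6}, no duplicate prefixes).
    """
    raw = resources.files("casemix").joinpath("data", _RESOURCE).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _RESOURCE_SHA256:
        raise ResourceError(
            f"coding table {_RESOURCE} is corrupted: sha256 {digest} != "
            f"expected {_RESOURCE_SHA256}"
        )
    entries = []
    seen_prefixes: set[str] = set()
    lines = raw.decode("utf-8").strip().splitlines()
    if lines[0] != "condition\tweight\tprefixes":
        raise ResourceError(f"unexpected header in {_RESOURCE}: {lines[0]!r}")
    for line in lines[1:]:
        name, weight_s, prefixes_s = line.split("\t")
        weight = int(weight_s)
        prefixes = prefixes_s.split(",")
        if weight not in _ALLOWED_WEIGHTS:
            raise ResourceError(f"{name}: weight {weight} outside {{1,2,3,6}}")
        if len(set(prefixes)) != len(prefixes):
            raise ResourceError(f"{name}: duplicate prefixes")
        dupes = seen_prefixes.intersection(prefixes)
        if dupes:
            raise ResourceError(f"{name}: prefixes shared across conditions: {dupes}")
        seen_prefixes.update(prefixes)
        entries.append((name, frozenset(prefixes), weight))
    if len(entries) != 17:
        raise ResourceError(f"expected 17 conditions, found {len(entries)}")
    return CharlsonMap(entries=tuple(entries))


def normalize_code(code: str) -> str:
    """Uppercase an ICD-10 code and strip dots and surrounding whitespace."""
    return code.strip().upper().replace(".", "")


def map_codes(
    codes: Iterable[str],
    cmap: Optional[CharlsonMap] = None,
    tally: Optional[Counter] = None,
) -> frozenset[str]:
    """Map ICD-10 codes to the set of Charlson conditions present.

    Matching is case-insensitive prefix matching on dot-stripped codes
    (4-character prefixes take precedence over 3-character ones).  Unrecognized
    codes are silently ignored; pass a :class:`collections.Counter` as
    ``tally`` to have them counted.  Hierarchy suppression is applied.
    """
    cmap = cmap or load_quan_map()
    lookup = _lookup_for(cmap)
    found: set[str] = set()
    for code in codes:
        norm = normalize_code(code)
        if not norm:
            continue
        cond = lookup.get(norm[:4]) or lookup.get(norm[:3])
        if cond is None:
            if tally is not None:
                tally[norm] += 1
        else:
            found.add(cond)
    for dominant, suppressed in cmap.hierarchy_pairs:
        if dominant in found:
            found.discard(suppressed)
    return frozenset(found)


@lru_cache(maxsize=4)
def _lookup_for(cmap: CharlsonMap) -> dict[str, str]:
    return cmap.prefix_lookup()


def charlson_score(conditions: Iterable[str], cmap: Optional[CharlsonMap] = None) -> int:
    """Sum the Charlson weights of a (hierarchy-reduced) condition set."""
    cmap = cmap or load_quan_map()
    weights = cmap.weights
    total = 0
    for cond in set(conditions):
        if cond not in weights:
            raise ValueError(f"unknown Charlson condition: {cond!r}")
        total += weights[cond]
    return total


def band(score: int) -> str:
    """Collapse a Charlson score into the five analytic bands."""
    if score < 0:
        raise ValueError(f"Charlson score must be non-negative, got {score}")
    if score == 0:
        return "0"
    if score <= 2:
        return "1-2"
    if score <= 6:
        return "3-6"
    if score <= 12:
        return "7-12"
    return "13-"


def score_codes(
    codes: Iterable[str],
    cmap: Optional[CharlsonMap] = None,
    tally: Optional[Counter] = None,
) -> CharlsonResult:
    """Full pipeline for one record: codes → conditions → score → band."""
    cmap = cmap or load_quan_map()
    local_tally: Counter = Counter()
    conditions = map_codes(codes, cmap, local_tally)
    if tally is not None:
        tally.update(local_tally)
    score = charlson_score(conditions, cmap)
    return CharlsonResult(
        conditions=conditions,
        score=score,
        band=band(score),
        unmatched=tuple(sorted(local_tally)),
    )


def score_code_strings(
    joined: pd.Series,
    cmap: Optional[CharlsonMap] = None,
    sep: str = ";",
) -> pd.DataFrame:
    """Score a Series of ``sep``-joined code strings (one per discharge).

    Distinct strings are scored once and broadcast, which makes scoring large
    simulated cohorts (many repeated code lists) cheap.  Returns a DataFrame
    aligned to the input index with columns ``charlson_score`` and
    ``charlson_band``.
    """
    cmap = cmap or load_quan_map()
    filled = joined.fillna("").astype(str)
    uniques = pd.unique(filled)
    cond_of: dict[str, str] = {}
    score_of: dict[str, int] = {}
    band_of: dict[str, str] = {}
    for s in uniques:
        codes = [c for c in s.split(sep) if c.strip()]
        res = score_codes(codes, cmap)
        cond_of[s] = ";".join(sorted(res.conditions))
        score_of[s] = res.score
        band_of[s] = res.band
    return pd.DataFrame(
        {
            "charlson_conditions": filled.map(cond_of),
            "charlson_score": filled.map(score_of).astype(int),
            "charlson_band": filled.map(band_of),
        },
        index=joined.index,
    )
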