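"""Education-level coding and mobility classification.

Educational attainment is collapsed onto an ordered three-level scale
(low < medium < high) built from ISCED 2011 codes: categories 1-2 map to
*low*, 3-4 to *medium* and 6-8 to *high*.  ISCED 0 (early childhood) and 5
(short-cycle tertiary) sit outside that collapse; the defaults assign
0 -> low and 5 -> high — short-cycle tertiary is still tertiary — and emit a
warning so the choice is explicit and overridable.

Origin is the social position of the family of upbringing (highest parental
education, with a father-only sensitivity variant); destination is the
respondent's own attained level.  Comparing the two ordinal ranks classifies
each person as immobile, upwardly mobile or downwardly mobile.
"""

from __future__ import annotations

import warnings

LOW = "low"
MEDIUM = "medium"
HIGH = "high"

#: Ordered education levels, rank 1 < 2 < 3.
LEVELS: tuple[str, ...] = (LOW, MEDIUM, HIGH)

#: Ordinal rank of each level (1-based).
RANK: dict[str, int] = {lvl: r for r, lvl in enumerate(LEVELS, start=1)}

#: Marital-status categories; the first is the regression reference.
MARITAL_LEVELS: tuple[str, ...] = (
    "no_partner",
    "married_cohab",
    "unmarried_cohab",
    "no_cohabitation",
)

MOBILITY_LEVELS: tuple[str, ...] = ("immobile", "upward", "downward")


class InvalidISCEDError(ValueError):
    """Raised for an ISCED code outside 0-8."""


class MissingOriginError(ValueError):
    """Raised when no parental education level is available."""


def recode_isced(isced_code: int, *, isced0: str = LOW, isced5: str = HIGH,
                 warn: bool = True) -> str:
    """Collapse an ISCED 2011 code (0-8) to low/medium/high.

    Codes 0 and 5 are not covered by the 1-2 / 3-4 / 6-8 collapse; they map
    to ``isced0`` / ``isced5`` (defaults low / high) with a warning.
    """
    code = int(isced_code)
    if code != isced_code or not 0 <= code <= 8:
        raise InvalidISCEDError(f"ISCED code must be an integer in [0, 8], got {isced_code!r}")
    if code == 0:
        if warn:
            warnings.warn(f"ISCED 0 mapped to {isced0!r} by default policy", stacklevel=2)
        return isced0
    if code == 5:
        if warn:
            warnings.warn(f"ISCED 5 mapped to {isced5!r} by default policy", stacklevel=2)
        return isced5
    if code <= 2:
        return LOW
    if code <= 4:
        return MEDIUM
    return HIGH


def derive_parental_education(mother: str | None, father: str | None,
                              mode: str = "highest") -> str:
    """Parental (origin) education from the two parents' levels.

    mode="highest" takes the higher-ranked non-missing level; mode="father_only"
    is the sensitivity variant using the father's level alone.
    """
    if mode == "father_only":
        if father is None:
            raise MissingOriginError("father's education required in father_only mode")
        _check_level(father)
        return father
    if mode != "highest":
        raise ValueError(f"unknown mode {mode!r}")
    present = [lvl for lvl in (mother, father) if lvl is not None]
    if not present:
        raise MissingOriginError("both parental education levels missing")
    for lvl in present:
        _check_level(lvl)
    return max(present, key=RANK.__getitem__)


def classify_mobility(origin: str, destination: str) -> str:
    """immobile if origin == destination, upward/downward by ordinal rank."""
    _check_level(origin)
    _check_level(destination)
    if RANK[destination] > RANK[origin]:
        return "upward"
    if RANK[destination] < RANK[origin]:
        return "downward"
    return "immobile"


def _check_level(level: str) -> None:
    if level not in RANK:
        raise ValueError(f"unknown education level {level!r}; expected one of {LEVELS}")
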