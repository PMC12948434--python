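"""ACMG/AMP evidence combining engine.

Maps a set of per-variant evidence codes (PVS1, PS1-4, PM1-6, PP1-5,
BA1, BS1-4, BP1-7) to the 5-tier classification (pathogenic, likely
pathogenic, uncertain significance, likely benign, benign) through the
published combining rules.  Evidence codes are inputs — they come from
curation, never from sequence context — and each code may be used at a
modified strength (e.g. computationally calibrated PP3/BP4), supplied
through ``strength_overrides``.

Conflicting pathogenic and benign evidence yields VUS.  A variant whose
combined class is VUS but which carries published functional support may
be upgraded to likely pathogenic, only through the explicit
``apply_functional_override`` path, never silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import total_ordering
from typing import Iterable, Mapping, Optional


@total_ordering
class AcmgClass(Enum):
    """5-tier variant classification, ordered B < LB < VUS < LP < P."""

    B = "B"
    LB = "LB"
    VUS = "VUS"
    LP = "LP"
    P = "P"

    def __lt__(self, other: "AcmgClass") -> bool:
        order = [AcmgClass.B, AcmgClass.LB, AcmgClass.VUS, AcmgClass.LP,
                 AcmgClass.P]
        return order.index(self) < order.index(other)

    @property
    def is_lp_p(self) -> bool:
        return self in (AcmgClass.LP, AcmgClass.P)


class Strength(str, Enum):
    STAND_ALONE = "stand_alone"  # benign family only (BA1)
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


_PATHOGENIC_CODES = {
    "PVS1": Strength.VERY_STRONG,
    **{f"PS{i}": Strength.STRONG for i in range(1, 5)},
    **{f"PM{i}": Strength.MODERATE for i in range(1, 7)},
    **{f"PP{i}": Strength.SUPPORTING for i in range(1, 6)},
}
_BENIGN_CODES = {
    "BA1": Strength.STAND_ALONE,
    **{f"BS{i}": Strength.STRONG for i in range(1, 5)},
    **{f"BP{i}": Strength.SUPPORTING for i in range(1, 8)},
}
VALID_CODES = frozenset(_PATHOGENIC_CODES) | frozenset(_BENIGN_CODES)

_CODE_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)\d$")


@dataclass
class EvidenceSet:
    """Validated set of evidence codes with optional strength overrides."""

    codes: frozenset[str]
    strength_overrides: Mapping[str, Strength] = field(default_factory=dict)
    functional_support: bool = False


def validate_evidence(
    codes: Iterable[str],
    strength_overrides: Optional[Mapping[str, str | Strength]] = None,
    functional_support: bool = False,
) -> EvidenceSet:
    """Normalize case, reject unknown codes, return the canonical set."""
    normalized = frozenset(str(c).strip().upper() for c in codes)
    unknown = sorted(normalized - VALID_CODES)
    if unknown:
        raise ValueError(f"unknown ACMG evidence codes: {unknown}")
    overrides: dict[str, Strength] = {}
    for code, strength in (strength_overrides or {}).items():
        code = str(code).strip().upper()
        if code not in normalized:
            raise ValueError(
                f"strength override for absent code {code!r}"
            )
        strength = Strength(strength)
        if code in _PATHOGENIC_CODES and strength is Strength.STAND_ALONE:
            raise ValueError("stand_alone strength is benign-family only")
        overrides[code] = strength
    return EvidenceSet(
        codes=normalized,
        strength_overrides=overrides,
        functional_support=functional_support,
    )


def _effective_strength(code: str, e: EvidenceSet) -> Strength:
    if code in e.strength_overrides:
        return e.strength_overrides[code]
    return _PATHOGENIC_CODES.get(code) or _BENIGN_CODES[code]


def _tally(e: EvidenceSet) -> tuple[dict[Strength, int], dict[Strength, int]]:
    path: dict[Strength, int] = {s: 0 for s in Strength}
    benign: dict[Strength, int] = {s: 0 for s in Strength}
    for code in e.codes:
        bucket = path if code in _PATHOGENIC_CODES else benign
        bucket[_effective_strength(code, e)] += 1
    return path, benign


def _pathogenic_tier(path: dict[Strength, int]) -> Optional[AcmgClass]:
    """Combining rules for the pathogenic family, on strength counts."""
    pvs = path[Strength.VERY_STRONG]
    ps = path[Strength.STRONG]
    pm = path[Strength.MODERATE]
    pp = path[Strength.SUPPORTING]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1)
                       or pp >= 2))
        or pvs >= 2
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2)
                         or (pm >= 1 and pp >= 4)))
    )
    if pathogenic:
        return AcmgClass.P
    likely = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and pm >= 1)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    if likely:
        return AcmgClass.LP
    return None


def _benign_tier(benign: dict[Strength, int]) -> Optional[AcmgClass]:
    ba = benign[Strength.STAND_ALONE]
    bs = benign[Strength.STRONG]
    bp = benign[Strength.SUPPORTING]
    if ba >= 1 or bs >= 2:
        return AcmgClass.B
    if (bs >= 1 and bp >= 1) or bp >= 2:
        return AcmgClass.LB
    return None


def combine(
    e: EvidenceSet, apply_functional_override: bool = False
) -> AcmgClass:
    """Combine evidence into a 5-tier class.

    Deterministic and total: evidence matching both a pathogenic and a
    benign rule, or matching neither, is VUS.  When
    ``apply_functional_override`` is set and the evidence carries
    ``functional_support``, a VUS is upgraded to LP (published functional
    data taken into account explicitly).
    """
    path_counts, benign_counts = _tally(e)
    p_tier = _pathogenic_tier(path_counts)
    b_tier = _benign_tier(benign_counts)
    if p_tier is not None and b_tier is not None:
        result = AcmgClass.VUS
    elif p_tier is not None:
        result = p_tier
    elif b_tier is not None:
        result = b_tier
    else:
        result = AcmgClass.VUS
    if (
        result is AcmgClass.VUS
        and apply_functional_override
        and e.functional_support
    ):
        result = AcmgClass.LP
    return result


def classify(
    codes: Iterable[str],
    strength_overrides: Optional[Mapping[str, str | Strength]] = None,
    functional_support: bool = False,
    apply_functional_override: bool = False,
) -> AcmgClass:
    """Validate and combine in one call."""
    return combine(
        validate_evidence(codes, strength_overrides, functional_support),
        apply_functional_override=apply_functional_override,
    )


def aggregate_individual_class(
    classes: Iterable[AcmgClass],
) -> Optional[AcmgClass]:
    """Most severe class across an individual's retained variants.

    Precedence P > LP > VUS > LB > B; an individual with no retained
    variant maps to ``None`` (the "no variant" category).
    """
    classes = list(classes)
    if not classes:
        return None
    return max(classes)
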