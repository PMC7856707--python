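"""The SLK-581 statistical linkage key.

SLK-581 is the 14-character quasi-identifier defined by the Australian
Institute of Health and Welfare: characters 2, 3 and 5 of the family name,
characters 2 and 3 of the given name, the date of birth as DDMMYYYY, and a
one-digit sex code.  It lets deidentified registries be linked without
releasing names, at the cost of sensitivity to spelling variants.

Layout of ``Slk581Key.value``::

    positions  1-3   family-name letters (or padding digits)
    positions  4-5   given-name letters (or padding digits)
    positions  6-13  date of birth, DDMMYYYY
    position   14    sex: 1 male, 2 female, 9 other/unknown

National conventions for degenerate names: positions past the end of a
short name are filled with the digit ``2``; a wholly missing family name
becomes ``999`` and a wholly missing given name ``99``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

from .records import PersonIdentity, Sex

_NON_ALPHA = re.compile(r"[^A-Z]")

#: sex code at position 14
_SEX_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "9"}

# (0-based) character indices taken from the normalized names
_FAMILY_POSITIONS = (1, 2, 4)
_GIVEN_POSITIONS = (1, 2)


class SlkError(ValueError):
    """The key cannot be built (missing or invalid date of birth)."""


@dataclass(frozen=True)
class Slk581Key:
    value: str

    def __post_init__(self) -> None:
        if len(self.value) != 14:
            raise ValueError(f"SLK-581 must have 14 characters, got {self.value!r}")
        if not self.value[5:].isdigit():
            raise ValueError(f"SLK-581 positions 6-14 must be digits: {self.value!r}")

    def __str__(self) -> str:
        return self.value


def normalize_name(name: str) -> str:
    """Uppercase and strip everything non-alphabetic (spaces, hyphens,
    apostrophes, accents are not folded).  Applied identically on both
    registries before any character position is indexed, so spelling-level
    noise like ``O'Brien`` vs ``OBRIEN`` or hyphenation cannot split keys.
    """
    return _NON_ALPHA.sub("", name.upper())


def _name_part(name: str, positions: tuple[int, ...], missing: str) -> str:
    norm = normalize_name(name)
    if not norm:
        return missing
    return "".join(norm[p] if p < len(norm) else "2" for p in positions)


def build_slk(identity: PersonIdentity) -> Slk581Key:
    """Build the 14-character SLK-581 from one registry's identity fields.

    Deterministic and pure; requires a valid date of birth (raises
    :class:`SlkError` without one, in which case the record keeps an empty
    key).  Sex may be unknown (code 9).
    """
    if identity.dob is None:
        raise SlkError("cannot build SLK-581 without a date of birth")
    family = _name_part(identity.surname, _FAMILY_POSITIONS, "999")
    given = _name_part(identity.forename, _GIVEN_POSITIONS, "99")
    d = identity.dob
    dob = f"{d.day:02d}{d.month:02d}{d.year:04d}"
    return Slk581Key(family + given + dob + _SEX_CODE[identity.sex])


def slk_agree(a: str, b: str) -> Literal["agree", "disagree", "missing"]:
    """Exact comparison of two keys; either side empty -> ``"missing"``."""
    if not a or not b:
        return "missing"
    return "agree" if a == b else "disagree"


def slk_partial_agreement(a: str, b: str) -> float:
    """Fraction of the 14 character positions that agree (0..1).

    Character-level relaxed comparison, tolerant of single typographical
    errors.  Off by default everywhere: no shipped strategy uses it, it is
    provided only as an exploratory comparison mode.
    """
    if len(a) != 14 or len(b) != 14:
        raise ValueError("partial agreement is defined for two complete 14-character keys")
    return sum(x == y for x, y in zip(a, b)) / 14.0
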