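"""Systematic Svennerholm and IUPAC ganglioside naming.

The systematic Svennerholm name (SSN) is assembled as

    "G" + sialic-acid-count letter + core number + series letter + "α"

where the letter encodes the total Neu5Ac count (A = 0, M = 1, D = 2,
T = 3, Q = 4, P = 5, H = 6, S = 7), the core number is 5 − n for a
Glc-based backbone of n residues (1 = fully extended) and 4 for
galactosylceramide cores, the series letter a/b/c (only on the fully
extended core) gives the number of sialic acids branching from position
II (the inner galactose), and a trailing Greek α marks an α2,6-linked
Neu5Ac on position III (the core GalNAc).  With no sialic acid on
position II the fully extended core takes no series letter (the
0-series: GA1, GM1, GD1 …).

Bare ceramide and glucosylceramide precede the naming system's cores and
receive no SSN.  The Greek letter α is the only accepted alpha marker: a
trailing ASCII "a" is always the series letter (GD1a is an a-series
ganglioside; GD1α is the α2,6 variant of GD1).

The IUPAC names list the sialylated core positions from the non-reducing
end, e.g. GP1cα → ``IV3Neu5Ac,III6Neu5Ac,II3(Neu5Ac)3-Gg4Cer`` (with
``markup=True``: ``IV^3^Neu5Ac,III^6^Neu5Ac,II^3^(Neu5Ac)_3_-Gg_4_Cer``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .errors import NameParseError, NoNameError
from .structures import CoreInfo, Structure

#: Sialic-acid count letters, index = count.
SIALO_LETTERS = "AMDTQPHS"
ALPHA = "α"  # α

_SERIES_FROM_II = {0: None, 1: "a", 2: "b", 3: "c"}
_II_FROM_SERIES = {v: k for k, v in _SERIES_FROM_II.items() if v}


@dataclass(frozen=True)
class SvennerholmName:
    """Decomposed systematic Svennerholm name."""

    sialo_count: int
    core_number: int
    series_letter: str | None = None
    alpha: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.sialo_count < len(SIALO_LETTERS):
            raise NameParseError(
                f"no letter is defined for {self.sialo_count} sialic acids "
                f"(supported: 0-{len(SIALO_LETTERS) - 1})")
        if not 1 <= self.core_number <= 4:
            raise NameParseError(f"core number {self.core_number} out of range")
        if self.series_letter is not None and self.core_number != 1:
            raise NameParseError(
                "a series letter requires the fully extended core (core 1)")
        if self.alpha and self.core_number != 1:
            raise NameParseError(
                f"{ALPHA} requires the fully extended core (core 1)")

    @property
    def sialo_letter(self) -> str:
        return SIALO_LETTERS[self.sialo_count]

    def render(self) -> str:
        return ("G" + self.sialo_letter + str(self.core_number)
                + (self.series_letter or "") + (ALPHA if self.alpha else ""))

    def __str__(self) -> str:
        return self.render()


def _core_info_for_naming(s: Structure) -> CoreInfo:
    info = s.core_info()
    if info.base_kind is None:
        raise NoNameError("bare ceramide has no Svennerholm name")
    if info.base_kind == "Glc" and info.core_length == 1:
        raise NoNameError("glucosylceramide has no Svennerholm name")
    return info


def systematic_svennerholm(s: Structure | str) -> SvennerholmName:
    """Assign the systematic Svennerholm name of a structure.

    >>> str(systematic_svennerholm("S3L3[S6]Vb4[S8S8S3]L4GT"))
    'GP1cα'
    """
    s = s if isinstance(s, Structure) else Structure.parse(s)
    info = _core_info_for_naming(s)
    count = s.count_residues("S")
    if count >= len(SIALO_LETTERS):
        raise NoNameError(f"no letter is defined for {count} sialic acids")
    series = None
    alpha = False
    if info.base_kind == "Glc" and info.core_length == 4:
        series = _SERIES_FROM_II[info.sialo_ii]
        alpha = bool(info.sialo_iii)
    return SvennerholmName(count, info.core_number, series, alpha)


_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}


def _sialo_term(roman: str, linkage: int, count: int, markup: bool) -> str:
    sup = f"^{linkage}^" if markup else str(linkage)
    if count == 1:
        return f"{roman}{sup}Neu5Ac"
    sub = f"_{count}_" if markup else str(count)
    return f"{roman}{sup}(Neu5Ac){sub}"


def iupac_ganglioside_name(s: Structure | str, markup: bool = False) -> str:
    """IUPAC ganglioside name built on the Gg_n/GalCer core descriptor.

    Sialylation terms are listed from the non-reducing end; ``markup``
    selects caret/underscore super-/subscripts over plain digits.

    >>> iupac_ganglioside_name("L3Vb4[S3]L4GT")
    'II3Neu5Ac-Gg4Cer'
    """
    s = s if isinstance(s, Structure) else Structure.parse(s)
    info = _core_info_for_naming(s)
    terms: list[str] = []
    if info.base_kind == "Gal":
        # GalCer cores: the lone galactose is position I by convention here
        if info.sialo_ii:
            terms.append(_sialo_term("I", 3, info.sialo_ii, markup))
        core = "GalCer"
    else:
        if info.sialo_iv:
            terms.append(_sialo_term("IV", 3, info.sialo_iv, markup))
        if info.sialo_iii:
            terms.append(_sialo_term("III", 6, info.sialo_iii, markup))
        if info.sialo_ii:
            terms.append(_sialo_term("II", 3, info.sialo_ii, markup))
        n = f"_{info.core_length}_" if markup else str(info.core_length)
        core = f"Gg{n}Cer"
    if not terms:
        return core
    return ",".join(terms) + "-" + core


# ---------------------------------------------------------------------------
# legacy Svennerholm names

#: Common names whose traditional use differs from the systematic system.
LEGACY_TO_SSN = {"GM1b": "GM1", "GM1": "GM1a", "GD1c": "GD1",
                 "GD1a" + ALPHA: "GD1" + ALPHA}
SSN_TO_LEGACY = {v: k for k, v in LEGACY_TO_SSN.items()}

_SSN_RE = re.compile(rf"G([{SIALO_LETTERS}])([1-4])([abc])?({ALPHA})?$")


def legacy_mapping(name: str, direction: str = "legacy_to_ssn") -> tuple[str, ...]:
    """Translate between legacy and systematic Svennerholm names.

    Only four common names differ between the systems; every other
    well-formed name maps to itself.  Returns a tuple of candidates —
    usually one; the traditional name "GM1" is ambiguous (it was used
    both for II3Neu5Ac-Gg4Cer, systematically GM1a, and for the 0-series
    GM1), so it maps to ("GM1a", "GM1") with a warning.
    """
    if direction not in ("legacy_to_ssn", "ssn_to_legacy"):
        raise NameParseError(f"unknown direction {direction!r}")
    if not _SSN_RE.match(name):
        raise NameParseError(f"unparseable Svennerholm name {name!r}")
    table = LEGACY_TO_SSN if direction == "legacy_to_ssn" else SSN_TO_LEGACY
    if name not in table:
        return (name,)
    if direction == "legacy_to_ssn" and name == "GM1":
        warnings.warn(
            'the traditional name "GM1" is ambiguous: read as II3Neu5Ac-'
            "Gg4Cer it is systematically GM1a, but GM1 is also the valid "
            "systematic name of the 0-series IV3Neu5Ac-Gg4Cer",
            stacklevel=2)
        return ("GM1a", "GM1")
    return (table[name],)


# ---------------------------------------------------------------------------
# SSN -> structure

_BRANCH = {0: "", 1: "[S3]", 2: "[S8S3]", 3: "[S8S8S3]"}
_TERMINAL = {0: "", 1: "S3", 2: "S8S3", 3: "S8S8S3"}


def parse_ssn(name: str) -> Structure:
    """Reconstruct the unique structure named by a systematic Svennerholm name.

    Inverts :func:`systematic_svennerholm`: the series letter fixes the
    position II branch, α fixes position III, and the remaining sialic
    acids form the terminal chain on position IV (validated to lie in
    0–3).  Internally inconsistent names — e.g. "GM1b" read as an SSN,
    whose series letter implies more sialic acids than its count letter
    allows — are rejected.
    """
    m = _SSN_RE.match(name)
    if not m:
        raise NameParseError(f"unparseable Svennerholm name {name!r}")
    letter, core_s, series, alpha_s = m.groups()
    count = SIALO_LETTERS.index(letter)
    core = int(core_s)
    ssn = SvennerholmName(count, core, series, bool(alpha_s))  # validates shape
    if core == 4:
        if count > 3:
            raise NameParseError(
                f"{name!r}: a galactosylceramide core carries at most 3 "
                "sialic acids")
        return Structure.parse(_BRANCH[count] + "LT")
    if core in (2, 3):
        if count > 3:
            raise NameParseError(
                f"{name!r}: position II carries at most 3 sialic acids")
        stem = _BRANCH[count] + "L4GT"
        return Structure.parse(stem if core == 3 else "Vb4" + stem)
    ii = _II_FROM_SERIES[series] if series else 0
    iii = 1 if ssn.alpha else 0
    iv = count - ii - iii
    if iv < 0 or iv > 3:
        raise NameParseError(
            f"{name!r}: series letter and {ALPHA} imply {ii + iii} sialic "
            f"acids, leaving an impossible terminal chain of {iv}")
    if ssn.alpha and iv == 0:
        raise NameParseError(
            f"{name!r}: the {ALPHA} decoration requires a sialylated "
            "position IV")
    return Structure.parse(_TERMINAL[iv] + "L3" + ("[S6]" if iii else "")
                           + "Vb4" + _BRANCH[ii] + "L4GT")


def series_of(s: Structure | str) -> str | None:
    """Biosynthetic series of a structure: "Gala", "0", "a", "b", "c",
    or None for core intermediates without a series assignment."""
    s = s if isinstance(s, Structure) else Structure.parse(s)
    info = s.core_info()
    if info.base_kind == "Gal":
        return "Gala"
    if info.base_kind == "Glc" and info.core_length == 4:
        return _SERIES_FROM_II[info.sialo_ii] or "0"
    return None
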