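"""Glycosyltransferase activities as string-rewrite rules.

Each of the ten enzyme activities of the model transfers one sugar from a
nucleotide donor (UDP-Glc, UDP-Gal, UDP-GalNAc or CMP-Neu5Ac) onto an
acceptor glycolipid, releasing the nucleotide.  An activity is encoded as
one or more :class:`AcceptorPattern` rewrites over canonical abbreviated
structure identifiers:

* ``prefix`` patterns are anchored at the non-reducing end (the start of
  the identifier) and, through the implicit terminal ``T``, consume the
  whole string; a ``*`` wildcard matches any bracket-balanced substring.
  Prefix anchoring of the GD3-synthase pattern encodes the assumption
  that that sialylation happens before core extension with GalNAc.
* ``internal`` patterns are bracket-delimited literals that may match any
  occurrence inside the identifier; bracket characters must align, so
  ``[S8S3]`` does not match inside ``[S8S8S3]`` — which is what caps
  sialyl chains at three residues.

Two reaction shapes occur: linear insertion (chain *extension*,
``Ax + yB = xyB + A``) and bracketed insertion (branch *decoration*,
``Ax + yB = [x]yB + A``).  Functionally the activities are classified as
extension, decoration, termination, or the mixed categories
decoration-with-extension and termination-with-extension.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from .errors import GangliosimError, InvalidKnockoutError, PatternError
from .structures import SUGAR_CODES, Structure

PREFIX = "prefix"
INTERNAL = "internal"

EXTENSION = "extension"
DECORATION = "decoration"
DECORATION_WITH_EXTENSION = "decoration-with-extension"
TERMINATION = "termination"
TERMINATION_WITH_EXTENSION = "termination-with-extension"

CATEGORIES = (EXTENSION, DECORATION, DECORATION_WITH_EXTENSION,
              TERMINATION, TERMINATION_WITH_EXTENSION)


def _check_balanced(text: str, what: str) -> None:
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise PatternError(f"unbalanced brackets in {what}: {text!r}")
    if depth:
        raise PatternError(f"unbalanced brackets in {what}: {text!r}")


def _is_balanced(text: str) -> bool:
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
            if depth < 0:
                return False
    return depth == 0


@lru_cache(maxsize=None)
def _prefix_regex(pattern: str) -> re.Pattern[str]:
    parts = pattern.split("*")
    return re.compile("(.*)".join(re.escape(p) for p in parts))


@dataclass(frozen=True)
class AcceptorPattern:
    """One acceptor-recognition-and-rewrite pattern of an enzyme activity.

    ``pattern`` and ``replacement`` are texts over the abbreviated
    identifier alphabet plus ``*``; ``anchor`` is ``"prefix"`` or
    ``"internal"`` (see module docstring for the matching semantics).
    """

    pattern: str
    replacement: str
    anchor: str = PREFIX

    def __post_init__(self) -> None:
        if self.anchor not in (PREFIX, INTERNAL):
            raise PatternError(f"unknown anchor {self.anchor!r}")
        for text in (self.pattern, self.replacement):
            _check_balanced(text, "pattern")
            depth = 0
            for ch in text:
                if ch == "[":
                    depth += 1
                elif ch == "]":
                    depth -= 1
                elif ch == "*" and depth:
                    raise PatternError(
                        f"wildcard inside brackets in {text!r}")
        if self.anchor == PREFIX:
            if not self.pattern.endswith("T") or not self.replacement.endswith("T"):
                raise PatternError(
                    "prefix patterns run through the reducing-end T")
            if self.pattern.count("*") != self.replacement.count("*"):
                raise PatternError(
                    "pattern and replacement must use the same wildcards")
        else:
            if "*" in self.pattern or "*" in self.replacement:
                raise PatternError("internal patterns are literal (no '*')")
            if not (self.pattern.startswith("[") and self.pattern.endswith("]")):
                raise PatternError(
                    "internal patterns are bracket-delimited branches")

    def sites(self, acceptor: str) -> list[tuple[str, ...] | int]:
        """Match sites on a canonical abbreviated identifier.

        Prefix patterns yield zero or one site (the tuple of wildcard
        captures); internal patterns yield the character offset of every
        occurrence of the literal branch.
        """
        if self.anchor == PREFIX:
            m = _prefix_regex(self.pattern).fullmatch(acceptor)
            if m is None:
                return []
            groups = m.groups()
            if any(not _is_balanced(g) for g in groups):
                return []
            return [groups]
        out: list[tuple[str, ...] | int] = []
        start = 0
        while True:
            i = acceptor.find(self.pattern, start)
            if i < 0:
                return out
            out.append(i)
            start = i + 1

    def rewrite(self, acceptor: str) -> list[str]:
        """All distinct product strings from rewriting the match sites."""
        products: list[str] = []
        if self.anchor == PREFIX:
            for groups in self.sites(acceptor):
                parts = self.replacement.split("*")
                text = parts[0]
                for g, part in zip(groups, parts[1:]):  # type: ignore[arg-type]
                    text += g + part
                products.append(text)
        else:
            for i in self.sites(acceptor):
                products.append(acceptor[:i] + self.replacement
                                + acceptor[i + len(self.pattern):])  # type: ignore[operator]
        seen: set[str] = set()
        return [p for p in products if not (p in seen or seen.add(p))]


@dataclass(frozen=True)
class EnzymeRule:
    """One enzyme activity: a donor plus ordered acceptor patterns."""

    number: int
    ec: str
    short_name: str
    long_name: str
    donor: str          # "UDP-G", "UDP-L", "UDP-V" or "CMP-S"
    byproduct: str      # "UDP" or "CMP"
    patterns: tuple[AcceptorPattern, ...]
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise GangliosimError(f"unknown category {self.category!r}")
        if self.byproduct != self.donor.split("-")[0]:
            raise GangliosimError(
                f"byproduct {self.byproduct} inconsistent with donor {self.donor}")

    @property
    def donor_sugar(self) -> str:
        """Single-letter code of the transferred sugar."""
        return self.donor.split("-")[1]


@dataclass(frozen=True)
class ReactionEvent:
    """One enzymatic transfer: substrate + donor → product + nucleotide."""

    substrate: Structure
    product: Structure
    enzyme_number: int
    donor: str
    byproduct: str

    @property
    def triple(self) -> tuple[str, int, str]:
        return (self.substrate.abbreviated, self.enzyme_number,
                self.product.abbreviated)


def _P(pattern: str, replacement: str) -> AcceptorPattern:
    return AcceptorPattern(pattern, replacement, PREFIX)


def _I(pattern: str, replacement: str) -> AcceptorPattern:
    return AcceptorPattern(pattern, replacement, INTERNAL)


def default_ruleset() -> tuple[EnzymeRule, ...]:
    """The ten enzyme activities of ganglioside biosynthesis.

    Patterns are in the abbreviated dialect.  Beyond the minimal
    literature patterns, the set includes the variants needed for the
    known product families: the initiating α2,8 extension of a terminal
    sialic acid (activity 6), the GalCer-branch sialylation of activity
    5, and the di-/tri-sialyl acceptor variants of activity 7 (GM2/GD2
    synthase acts on GD3 and GT3 as well); activity 6's bracketed pattern
    matches internally so that every b-series branch can convert to its
    c-series counterpart.
    """
    return (
        EnzymeRule(1, "EC 2.4.1.80", "UGCG", "ceramide glucosyltransferase",
                   "UDP-G", "UDP", (_P("T", "GT"),), EXTENSION),
        EnzymeRule(2, "EC 2.4.1.47", "β1Gal-T3",
                   "N-acylsphingosine galactosyltransferase",
                   "UDP-L", "UDP", (_P("T", "LT"),), EXTENSION),
        EnzymeRule(3, "EC 2.4.1.274", "β4Gal-T6",
                   "glucosylceramide β-1,4-galactosyltransferase",
                   "UDP-L", "UDP", (_P("GT", "L4GT"),), EXTENSION),
        EnzymeRule(4, "EC 2.4.99.9", "ST3Gal-V",
                   "lactosylceramide α-2,3-sialyltransferase",
                   "CMP-S", "CMP",
                   (_P("L4GT", "[S3]L4GT"), _P("LT", "[S3]LT")),
                   DECORATION_WITH_EXTENSION),
        EnzymeRule(5, "EC 2.4.99.8", "ST8Sia-I",
                   "α-N-acetylneuraminate α-2,8-sialyltransferase",
                   "CMP-S", "CMP",
                   (_P("[S3]L4*T", "[S8S3]L4*T"), _P("[S3]LT", "[S8S3]LT")),
                   EXTENSION),
        EnzymeRule(6, "EC 2.4.99.-", "ST8Sia-V",
                   "α-2,8-N-acetylneuraminate α-2,8-sialyltransferase",
                   "CMP-S", "CMP",
                   (_P("S3*T", "S8S3*T"), _P("S8S3*T", "S8S8S3*T"),
                    _I("[S8S3]", "[S8S8S3]")),
                   TERMINATION),
        EnzymeRule(7, "EC 2.4.1.92", "β4GalNAc-T1",
                   "(N-acetylneuraminyl)-galactosylglucosylceramide "
                   "N-acetylgalactosaminyltransferase",
                   "UDP-V", "UDP",
                   (_P("L4*T", "Vb4L4*T"), _P("[S3]L4*T", "Vb4[S3]L4*T"),
                    _P("[S8S3]L4*T", "Vb4[S8S3]L4*T"),
                    _P("[S8S8S3]L4*T", "Vb4[S8S8S3]L4*T")),
                   EXTENSION),
        EnzymeRule(8, "EC 2.4.1.68", "β3Gal-T4",
                   "ganglioside galactosyltransferase",
                   "UDP-L", "UDP", (_P("Vb4*T", "L3Vb4*T"),), EXTENSION),
        EnzymeRule(9, "EC 2.4.99.-", "ST3Gal-II",
                   "β-1,3-galactosyl-ceramide α-2,3-sialyltransferase",
                   "CMP-S", "CMP", (_P("L3Vb4*T", "S3L3Vb4*T"),),
                   TERMINATION_WITH_EXTENSION),
        EnzymeRule(10, "EC 2.4.99.-", "ST6GalNAc-V",
                   "α1,3-Sia-β1,3-Gal-β1,3-GalNAc α-2,6-sialyltransferase",
                   "CMP-S", "CMP",
                   (_P("S3L3Vb4*T", "S3L3[S6]Vb4*T"),), DECORATION),
    )


def match_pattern(pattern: AcceptorPattern, acceptor: Structure) -> list:
    """Match sites of one pattern on a structure (see AcceptorPattern.sites)."""
    return pattern.sites(acceptor.abbreviated)


def apply_rule(rule: EnzymeRule, acceptor: Structure) -> set[ReactionEvent]:
    """All distinct reaction events of one enzyme on one acceptor.

    Identical products arising from different patterns of the same rule
    collapse to a single event.  Products are canonicalized by re-parsing.
    """
    events: dict[str, ReactionEvent] = {}
    for pattern in rule.patterns:
        for text in pattern.rewrite(acceptor.abbreviated):
            product = Structure.parse(text)
            if product.abbreviated not in events:
                events[product.abbreviated] = ReactionEvent(
                    acceptor, product, rule.number, rule.donor, rule.byproduct)
    return set(events.values())


def apply_ruleset_step(rules: Sequence[EnzymeRule], acceptor: Structure,
                       knockouts: Iterable[int] = ()) -> set[ReactionEvent]:
    """Union of apply_rule over all rules not knocked out."""
    ko = frozenset(knockouts)
    numbers = {r.number for r in rules}
    bad = ko - numbers
    if bad:
        raise InvalidKnockoutError(
            f"knockout of unknown enzyme number(s) {sorted(bad)}")
    events: set[ReactionEvent] = set()
    for rule in rules:
        if rule.number not in ko:
            events |= apply_rule(rule, acceptor)
    return events


def _sugar_counts(text: str) -> dict[str, int]:
    return {c: text.count(c) for c in SUGAR_CODES}


def classify_activity(rule: EnzymeRule) -> str:
    """Validate the rewrite shape of every pattern and return the category.

    Each rewrite must add exactly one residue, equal to the donor sugar.
    Decoration categories must create a new bracketed branch (the
    branch-insertion shape); the others must insert linearly.  Raises on
    shape/declaration mismatch.
    """
    decorating = "decoration" in rule.category
    for p in rule.patterns:
        before = _sugar_counts(p.pattern)
        after = _sugar_counts(p.replacement)
        added = {c: after[c] - before[c] for c in after if after[c] != before[c]}
        if added != {rule.donor_sugar: 1}:
            raise GangliosimError(
                f"rule {rule.number}: rewrite {p.pattern!r} -> "
                f"{p.replacement!r} must add exactly one {rule.donor_sugar}")
        bracket_delta = p.replacement.count("[") - p.pattern.count("[")
        if bracket_delta != (1 if decorating else 0):
            raise GangliosimError(
                f"rule {rule.number}: rewrite shape does not match the "
                f"declared category {rule.category!r}")
    return rule.category


# ---------------------------------------------------------------------------
# plain-text rule-set config (for user-defined "wild type" sets)

_ANCHOR_CODE = {PREFIX: "P", INTERNAL: "I"}
_ANCHOR_FROM_CODE = {v: k for k, v in _ANCHOR_CODE.items()}


def ruleset_to_text(rules: Sequence[EnzymeRule]) -> str:
    """Serialize a rule set, one record per line.

    Fields are '|'-separated: number, EC, short name, long name, donor,
    byproduct, category, then ';'-separated anchored rewrites written as
    ``P:pattern>replacement`` or ``I:pattern>replacement``.
    """
    lines = ["# gangliosim enzyme rule set",
             "# number|EC|short|long|donor|byproduct|category|patterns"]
    for r in rules:
        pats = ";".join(
            f"{_ANCHOR_CODE[p.anchor]}:{p.pattern}>{p.replacement}"
            for p in r.patterns)
        lines.append("|".join([str(r.number), r.ec, r.short_name, r.long_name,
                               r.donor, r.byproduct, r.category, pats]))
    return "\n".join(lines) + "\n"


def ruleset_from_text(text: str) -> tuple[EnzymeRule, ...]:
    """Inverse of :func:`ruleset_to_text` (comments and blank lines ignored)."""
    rules: list[EnzymeRule] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("|")
        if len(fields) != 8:
            raise GangliosimError(
                f"rule-set line {lineno}: expected 8 fields, got {len(fields)}")
        number, ec, short, long_, donor, byproduct, category, pats = fields
        patterns = []
        for spec in pats.split(";"):
            try:
                anchor_code, rewrite = spec.split(":", 1)
                pattern, replacement = rewrite.split(">", 1)
            except ValueError:
                raise GangliosimError(
                    f"rule-set line {lineno}: malformed pattern {spec!r}")
            patterns.append(AcceptorPattern(
                pattern, replacement, _ANCHOR_FROM_CODE[anchor_code]))
        rules.append(EnzymeRule(int(number), ec, short, long_, donor,
                                byproduct, tuple(patterns), category))
    return tuple(rules)
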