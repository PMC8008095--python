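"""Linear-notation model of ganglioside carbohydrates.

A ganglioside carbohydrate is represented as a rooted tree of residues
attached to a ceramide anchor.  Its canonical text form is the *structure
identifier*: a compressed single-letter notation read right to left from
the ceramide end, with square brackets delimiting branches, e.g. GM1a is

    ``L3Vb4[S3]L4GT``   (abbreviated)
    ``Lb3Vb4[Sa3]Lb4GbT``  (full, every anomer written)

Single-letter codes: G = Glc, L = Gal, S = Neu5Ac (sialic acid),
V = GalNAc, T = ceramide.  ``a``/``b`` mark the α/β anomers; digits give
the linkage position on the residue to the right.  The bond between the
base sugar and ceramide (1↔1) is never written, and T is always the final
character.

Each sugar has a default anomer (Glc, Gal → β; Neu5Ac, GalNAc → α) that
the abbreviated dialect drops.  GalNAc occurs here exclusively as the β
anomer, which is therefore non-default and always written (``Vb``).

Brackets are structurally significant: ``[S3]L4GT`` (GM3, sialic acid as
a *decoration branch* on the inner galactose) is a different identifier
from the linear ``S3L4GT``, which no biosynthetic rule produces.  A node
therefore has at most one unbracketed "chain" child — the continuation of
the main chain — plus any number of bracketed branch children.  Canonical
serialization writes the chain continuation leftmost and orders bracketed
branches by ascending linkage position, lowest nearest the parent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

from .errors import GlycanParseError, GangliosimError, UnclassifiableStructureError

#: Monosaccharide codes (T, ceramide, is the tree root and not a sugar).
SUGAR_CODES = "GLSV"
CERAMIDE = "T"

#: Anomer filled in when the notation omits it.  GalNAc is β in every
#: ganglioside context, so the model-level default for V is b even though
#: the general notation's droppable default for V is a.
FILL_ANOMER = {"G": "b", "L": "b", "S": "a", "V": "b"}

IUPAC_NAMES = {"G": "Glc", "L": "Gal", "S": "Neu5Ac", "V": "GalNAc"}
_IUPAC_CODES = {v: k for k, v in IUPAC_NAMES.items()}

#: Anomeric carbon written in IUPAC linkages (Neu5Ac is a 2-ketose).
ANOMERIC_POSITION = {"G": 1, "L": 1, "S": 2, "V": 1}

#: Fixed symbol map for Linear Code export.
LINEAR_CODE_SYMBOLS = {"L": "A", "G": "G", "V": "GN", "S": "NN"}


@dataclass(eq=False)
class Residue:
    """One monosaccharide (or the ceramide terminus) in a structure tree.

    ``linkage`` is the position on the parent to which this residue is
    attached; it is ``None`` for the root (T) and for the residue bonded
    directly to T (the implicit 1↔1 bond).  ``is_branch`` is True when the
    residue heads a bracket-delimited branch rather than continuing the
    main chain.
    """

    code: str
    anomer: str | None = None
    linkage: int | None = None
    is_branch: bool = False
    children: list["Residue"] = field(default_factory=list)

    @property
    def chain_child(self) -> "Residue | None":
        for c in self.children:
            if not c.is_branch:
                return c
        return None

    @property
    def branch_children(self) -> list["Residue"]:
        return sorted((c for c in self.children if c.is_branch),
                      key=lambda r: (r.linkage or 0))


@dataclass
class CoreInfo:
    """Classification of a structure against the ganglioside core.

    ``base_kind`` is "Glc" for the Glc–Gal–GalNAc–Gal backbone series and
    "Gal" for galactosylceramide-based (Gala) structures; ``None`` for
    bare ceramide.  ``core_length`` (n) counts backbone residues present
    (0–4; the fully extended core Galβ3GalNAcβ4Galβ4Glc has n = 4).
    ``positions`` maps Roman numerals I–IV to backbone residues.  The
    three sialylation slots: ``sialo_ii`` — length of the α2,3/α2,8 chain
    branching from position II (for Gal-based cores, from the base
    galactose); ``sialo_iv`` — length of the terminal chain on position
    IV; ``sialo_iii`` — 1 if an α2,6 Neu5Ac decorates position III.
    """

    base_kind: str | None
    core_length: int
    positions: dict[str, Residue]
    sialo_ii: int
    sialo_iv: int
    sialo_iii: int

    @property
    def core_number(self) -> int:
        """Svennerholm core number: 1 = fully extended; GalCer cores are 4."""
        if self.base_kind == "Gal":
            return 4
        return 5 - self.core_length


# ---------------------------------------------------------------------------
# tokenizer / parser

_TOKEN_RE = re.compile(r"([GLSVT])([ab])?([1-9])?|(\[)|(\])")


@dataclass(frozen=True)
class _Token:
    kind: str  # "res", "open", "close"
    pos: int
    code: str = ""
    anomer: str | None = None
    linkage: int | None = None


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i = 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if m is None:
            raise GlycanParseError(f"unexpected character {text[i]!r}", text, i)
        if m.group(4):
            tokens.append(_Token("open", i))
        elif m.group(5):
            tokens.append(_Token("close", i))
        else:
            code, anomer, digit = m.group(1), m.group(2), m.group(3)
            if code == CERAMIDE and (anomer or digit):
                raise GlycanParseError("ceramide (T) carries no anomer or linkage",
                                       text, i)
            tokens.append(_Token("res", i, code, anomer,
                                 int(digit) if digit else None))
        i = m.end()
    return tokens


class Structure:
    """A ganglioside carbohydrate: a residue tree rooted at ceramide (T).

    Equality and hashing are by canonical abbreviated identifier, so two
    structures parsed from texts differing only in sibling branch order or
    in written default anomers compare equal.
    """

    __slots__ = ("root", "_abbrev", "_full")

    def __init__(self, root: Residue):
        _validate_tree(root)
        self.root = root
        self._abbrev: str | None = None
        self._full: str | None = None

    # -- construction -------------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "Structure":
        """Parse a structure identifier in either dialect.

        Missing anomers are filled with model defaults; the result is
        canonical, so ``parse(serialize(x)) == x``.
        """
        if not text:
            raise GlycanParseError("empty identifier", text)
        tokens = _tokenize(text)
        last = tokens[-1]
        if last.kind != "res" or last.code != CERAMIDE:
            raise GlycanParseError("identifier must end with the ceramide code T",
                                   text, tokens[-1].pos if tokens else 0)
        root = _parse_segment(tokens, 0, len(tokens), text, top_level=True)
        return cls(root)

    # -- serialization ------------------------------------------------------

    def serialize(self, dialect: str = "abbreviated") -> str:
        """Render the canonical identifier. ``dialect``: "abbreviated" | "full"."""
        if dialect not in ("abbreviated", "full"):
            raise GangliosimError(f"unknown dialect {dialect!r}")
        return _serialize(self.root, full=(dialect == "full"))

    @property
    def abbreviated(self) -> str:
        if self._abbrev is None:
            self._abbrev = self.serialize("abbreviated")
        return self._abbrev

    @property
    def full(self) -> str:
        if self._full is None:
            self._full = self.serialize("full")
        return self._full

    # -- interrogation ------------------------------------------------------

    def residues(self) -> Iterator[Residue]:
        """Preorder traversal, root (T) first."""
        stack = [self.root]
        while stack:
            r = stack.pop()
            yield r
            stack.extend(reversed(r.children))

    def __len__(self) -> int:
        return sum(1 for _ in self.residues())

    def count_residues(self, code: str) -> int:
        """Number of residues with the given single-letter code."""
        if code not in SUGAR_CODES + CERAMIDE:
            raise GangliosimError(f"unknown residue code {code!r}")
        return sum(1 for r in self.residues() if r.code == code)

    def core_info(self) -> CoreInfo:
        """Classify against the ganglioside core (see :class:`CoreInfo`).

        Raises :class:`UnclassifiableStructureError`, naming the offending
        feature, for trees outside the ganglioside grammar.
        """
        return _core_info(self)

    # -- external notations -------------------------------------------------

    def to_iupac_condensed(self) -> str:
        """IUPAC condensed linear form, e.g. GM1a →
        ``Galb1-3GalNAcb1-4[Neu5Aca2-3]Galb1-4GlcCer``."""
        return _to_iupac(self.root)

    @classmethod
    def from_iupac_condensed(cls, text: str) -> "Structure":
        """Parse an IUPAC condensed string (inverse of
        :meth:`to_iupac_condensed`; also accepts the ``Lac`` shorthand)."""
        return cls(_parse_iupac(text))

    def to_linear_code(self) -> str:
        """Linear Code export (Gal→A, Glc→G, GalNAc→GN, Neu5Ac→NN,
        ceramide → ``Cer``; branches parenthesized).  Export only."""
        return _to_linear_code(self.root)

    # -- identity -----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return self.abbreviated == other.abbreviated

    def __hash__(self) -> int:
        return hash(self.abbreviated)

    def __repr__(self) -> str:
        return f"Structure({self.abbreviated!r})"

    def __str__(self) -> str:
        return self.abbreviated


def _parse_segment(tokens: list[_Token], lo: int, hi: int, text: str,
                   top_level: bool = False) -> Residue:
    """Parse tokens[lo:hi] right to left; the rightmost token is the segment base.

    An unbracketed residue attaches to the current residue and becomes the
    new attachment point; a bracketed group attaches as a branch without
    moving it.
    """
    if hi <= lo:
        raise GlycanParseError("empty branch", text)
    base_tok = tokens[hi - 1]
    if base_tok.kind != "res":
        raise GlycanParseError("branch must end with a residue", text, base_tok.pos)
    if base_tok.code == CERAMIDE and not top_level:
        raise GlycanParseError("ceramide (T) may appear only once, at the end",
                               text, base_tok.pos)
    base = _make_residue(base_tok, text)
    current = base
    j = hi - 2
    while j >= lo:
        tok = tokens[j]
        if tok.kind == "close":
            depth = 1
            k = j - 1
            while k >= lo and depth:
                if tokens[k].kind == "close":
                    depth += 1
                elif tokens[k].kind == "open":
                    depth -= 1
                k -= 1
            if depth:
                raise GlycanParseError("unbalanced brackets", text, tok.pos)
            branch = _parse_segment(tokens, k + 2, j, text)
            branch.is_branch = True
            _attach(current, branch, text, tokens[j - 1].pos if j > 0 else tok.pos)
            j = k
        elif tok.kind == "open":
            raise GlycanParseError("unbalanced brackets", text, tok.pos)
        else:
            if tok.code == CERAMIDE:
                raise GlycanParseError("ceramide (T) must be the final residue",
                                       text, tok.pos)
            res = _make_residue(tok, text)
            _attach(current, res, text, tok.pos)
            current = res
            j -= 1
    return base


def _make_residue(tok: _Token, text: str) -> Residue:
    if tok.code == CERAMIDE:
        return Residue(CERAMIDE)
    anomer = tok.anomer or FILL_ANOMER[tok.code]
    return Residue(tok.code, anomer, tok.linkage)


def _attach(parent: Residue, child: Residue, text: str, pos: int) -> None:
    if parent.code == CERAMIDE:
        if child.is_branch:
            raise GlycanParseError("ceramide cannot carry a bracketed branch",
                                   text, pos)
        if child.linkage is not None:
            raise GlycanParseError(
                "the residue bonded to ceramide carries no linkage digit",
                text, pos)
    else:
        if child.linkage is None:
            raise GlycanParseError("missing linkage digit", text, pos)
        if any(c.linkage == child.linkage for c in parent.children):
            raise GlycanParseError(
                f"two substituents at position {child.linkage} of {parent.code}",
                text, pos)
    parent.children.append(child)


def _validate_tree(root: Residue) -> None:
    if root.code != CERAMIDE:
        raise GangliosimError("structure root must be ceramide (T)")
    seen_t = 0
    stack = [(root, True)]
    while stack:
        r, at_root = stack.pop()
        if r.code == CERAMIDE:
            seen_t += 1
            if not at_root:
                raise GangliosimError("ceramide may occur only as the root")
        elif r.code not in SUGAR_CODES:
            raise GangliosimError(f"unknown residue code {r.code!r}")
        elif r.anomer not in ("a", "b"):
            raise GangliosimError(f"invalid anomer {r.anomer!r} on {r.code}")
        chains = [c for c in r.children if not c.is_branch]
        if len(chains) > 1:
            raise GangliosimError("a residue has at most one chain continuation")
        linkages = [c.linkage for c in r.children]
        if len(set(linkages)) != len(linkages):
            raise GangliosimError("duplicate linkage positions among siblings")
        for c in r.children:
            if r.code == CERAMIDE:
                if c.linkage is not None or c.is_branch:
                    raise GangliosimError("ceramide bond is implicit (no linkage)")
            elif c.linkage is None:
                raise GangliosimError("non-root residues require a linkage")
            stack.append((c, False))
    if seen_t != 1:
        raise GangliosimError("ceramide (T) must occur exactly once")


def _token_text(res: Residue, full: bool) -> str:
    if res.code == CERAMIDE:
        return CERAMIDE
    # abbreviated: drop the anomer unless it is GalNAc (always written) or
    # differs from the fill default (keeps odd-but-valid inputs round-tripping)
    write_anomer = full or res.code == "V" or res.anomer != FILL_ANOMER[res.code]
    out = res.code
    if write_anomer:
        out += res.anomer or ""
    if res.linkage is not None:
        out += str(res.linkage)
    return out


def _serialize(res: Residue, full: bool) -> str:
    parts: list[str] = []
    chain = res.chain_child
    if chain is not None:
        parts.append(_serialize(chain, full))
    # lowest-linkage branch nearest the parent, i.e. rightmost
    for b in reversed(res.branch_children):
        parts.append("[" + _serialize(b, full) + "]")
    parts.append(_token_text(res, full))
    return "".join(parts)


# ---------------------------------------------------------------------------
# core classification

def _core_info(s: Structure) -> CoreInfo:
    t = s.root
    if not t.children:
        return CoreInfo(None, 0, {}, 0, 0, 0)
    base = t.children[0]
    if base.code == "L":
        return _core_info_gal(base)
    if base.code == "G":
        return _core_info_glc(base)
    raise UnclassifiableStructureError(
        f"residue {base.code} cannot be bonded directly to ceramide")


def _sialo_chain(first: Residue, first_linkage: int, where: str) -> int:
    """Validate a linear Neu5Ac chain (first residue α-`first_linkage`, the
    rest α2,8) and return its length (≤ 3)."""
    if first.code != "S" or first.linkage != first_linkage:
        raise UnclassifiableStructureError(
            f"unexpected substituent {first.code}{first.linkage} on {where}")
    length = 0
    res: Residue | None = first
    while res is not None:
        if res.code != "S":
            raise UnclassifiableStructureError(
                f"non-sialic residue {res.code} inside the sialyl chain on {where}")
        if length and res.linkage != 8:
            raise UnclassifiableStructureError(
                f"sialyl chain on {where} extended through position {res.linkage}")
        if res.branch_children:
            raise UnclassifiableStructureError(
                f"branched sialyl chain on {where}")
        length += 1
        res = res.chain_child
    if length > 3:
        raise UnclassifiableStructureError(
            f"sialyl chain of length {length} on {where} (maximum 3)")
    return length


def _single_branch(res: Residue, where: str) -> Residue | None:
    branches = res.branch_children
    if len(branches) > 1:
        raise UnclassifiableStructureError(f"multiple branches on {where}")
    return branches[0] if branches else None


def _core_info_gal(base: Residue) -> CoreInfo:
    # Gala series: GalCer optionally decorated with a sialyl chain.
    if base.chain_child is not None:
        raise UnclassifiableStructureError(
            "galactosylceramide cannot be chain-extended in this grammar")
    branch = _single_branch(base, "the base galactose")
    sialo = _sialo_chain(branch, 3, "the base galactose") if branch else 0
    return CoreInfo("Gal", 1, {"I": base}, sialo, 0, 0)


def _core_info_glc(base: Residue) -> CoreInfo:
    positions: dict[str, Residue] = {"I": base}
    ii = iv = iii = 0
    if base.branch_children:
        raise UnclassifiableStructureError("branch on the base glucose")
    gal2 = base.chain_child
    if gal2 is None:
        return CoreInfo("Glc", 1, positions, 0, 0, 0)
    if gal2.code != "L" or gal2.linkage != 4:
        raise UnclassifiableStructureError(
            f"position II must be Gal β1-4 (found {gal2.code}{gal2.linkage})")
    positions["II"] = gal2
    branch = _single_branch(gal2, "position II")
    if branch is not None:
        ii = _sialo_chain(branch, 3, "position II")
    nxt = gal2.chain_child
    if nxt is None:
        return CoreInfo("Glc", 2, positions, ii, 0, 0)
    if nxt.code == "S":
        raise UnclassifiableStructureError(
            "unbracketed sialyl chain on position II")
    if nxt.code != "V" or nxt.linkage != 4 or nxt.anomer != "b":
        raise UnclassifiableStructureError(
            f"position III must be GalNAc β1-4 (found {nxt.code}{nxt.linkage})")
    positions["III"] = nxt
    branch = _single_branch(nxt, "position III")
    if branch is not None:
        if branch.code != "S" or branch.linkage != 6 or branch.children:
            raise UnclassifiableStructureError(
                "position III accepts only a single α2,6 Neu5Ac branch")
        iii = 1
    gal4 = nxt.chain_child
    if gal4 is None:
        return CoreInfo("Glc", 3, positions, ii, 0, iii)
    if gal4.code == "S":
        raise UnclassifiableStructureError(
            "unbracketed sialyl chain on position III")
    if gal4.code != "L" or gal4.linkage != 3:
        raise UnclassifiableStructureError(
            f"position IV must be Gal β1-3 (found {gal4.code}{gal4.linkage})")
    positions["IV"] = gal4
    if gal4.branch_children:
        raise UnclassifiableStructureError("branch on position IV")
    tail = gal4.chain_child
    if tail is not None:
        iv = _sialo_chain(tail, 3, "position IV")
    return CoreInfo("Glc", 4, positions, ii, iv, iii)


# ---------------------------------------------------------------------------
# IUPAC condensed

def _iupac_token(res: Residue) -> str:
    if res.code == CERAMIDE:
        return "Cer"
    name = IUPAC_NAMES[res.code]
    if res.linkage is None:
        return name
    return f"{name}{res.anomer}{ANOMERIC_POSITION[res.code]}-{res.linkage}"


def _to_iupac(res: Residue) -> str:
    parts: list[str] = []
    chain = res.chain_child
    if chain is not None:
        parts.append(_to_iupac(chain))
    for b in reversed(res.branch_children):
        parts.append("[" + _to_iupac(b) + "]")
    parts.append(_iupac_token(res))
    return "".join(parts)


_IUPAC_TOKEN_RE = re.compile(
    r"(Neu5Ac|GalNAc|Gal|Glc|Lac|Cer)(?:([ab])([12])-([1-9]))?|(\[)|(\])")


def _parse_iupac(text: str) -> Residue:
    if not text:
        raise GlycanParseError("empty IUPAC string", text)
    tokens: list[_Token] = []
    i = 0
    while i < len(text):
        m = _IUPAC_TOKEN_RE.match(text, i)
        if m is None:
            raise GlycanParseError("unknown sugar token", text, i)
        if m.group(5):
            tokens.append(_Token("open", i))
        elif m.group(6):
            tokens.append(_Token("close", i))
        else:
            name = m.group(1)
            if name == "Cer":
                tokens.append(_Token("res", i, CERAMIDE))
            elif name == "Lac":
                # lactose shorthand: Gal β1-4 Glc on the reducing end
                if m.group(2):
                    raise GlycanParseError("Lac takes no linkage", text, i)
                tokens.append(_Token("res", i, "L", "b", 4))
                tokens.append(_Token("res", i, "G", None, None))
            else:
                code = _IUPAC_CODES[name]
                anomer, apos, linkage = m.group(2), m.group(3), m.group(4)
                if anomer is not None and int(apos) != ANOMERIC_POSITION[code]:
                    raise GlycanParseError(
                        f"malformed linkage: {name} bonds through carbon "
                        f"{ANOMERIC_POSITION[code]}", text, i)
                tokens.append(_Token("res", i, code, anomer,
                                     int(linkage) if linkage else None))
        i = m.end()
    if tokens[-1].kind != "res" or tokens[-1].code != CERAMIDE:
        raise GlycanParseError("IUPAC condensed form must end with Cer", text)
    return _parse_segment(tokens, 0, len(tokens), text, top_level=True)


# ---------------------------------------------------------------------------
# Linear Code (export only)

def _linear_code_token(res: Residue) -> str:
    if res.code == CERAMIDE:
        return "Cer"
    sym = LINEAR_CODE_SYMBOLS[res.code]
    if res.linkage is None:
        return sym
    return f"{sym}{res.anomer}{res.linkage}"


def _to_linear_code(res: Residue) -> str:
    parts: list[str] = []
    chain = res.chain_child
    if chain is not None:
        parts.append(_to_linear_code(chain))
    for b in reversed(res.branch_children):
        parts.append("(" + _to_linear_code(b) + ")")
    parts.append(_linear_code_token(res))
    return "".join(parts)


def parse_identifier(text: str) -> Structure:
    """Module-level convenience alias for :meth:`Structure.parse`."""
    return Structure.parse(text)
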