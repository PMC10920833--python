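"""Parser for IUPAC-condensed-style repeat-unit strings.

Grammar (written non-reducing end → reducing end, as in the literature)::

    repeat   := "→" CARBON ")" "-" chain "-(" CARBON "→"
    chain    := residue ( "-(" CARBON "→" [ branch ] CARBON ")" "-" residue )*
    branch   := "[" chain "-(" CARBON "→" CARBON ")" "]" "-"
    residue  := [ ("α"|"β"|"a"|"b") "-" ] [ ("D"|"L") "-" ] NAME

``NAME`` is a parent sugar (``Glc``, ``Gal``, ``Man``, ``Rha`` …, or an
open-chain polyol such as ``Gro``/``Rbo``), an optional ring letter ``p``/``f``,
and an optional trailing substituent label (``NAc``, ``6Ac`` …) that is
carried through but never scored.  ``->`` is accepted for ``→``.

The leading ``→y)`` names the carbon at which the polymerase attaches the
previous repeat to the first (non-reducing, +1) residue; the trailing
``(x→`` is the anomeric carbon of the last (reducing-end, −1) residue, which
is the one linked to the Und-PP lipid carrier.
"""

from __future__ import annotations

import re

from ..errors import GlycanParseError, UnknownResidueError
from .model import Bond, PolymeraseBond, RepeatUnit, Residue
from .stereo import OPEN_CHAIN_PARENTS, PARENT_ALIASES, _D_RING_PATTERNS

_KNOWN_PARENTS = sorted(
    {p for p, _ in _D_RING_PATTERNS} | set(PARENT_ALIASES) | set(OPEN_CHAIN_PARENTS),
    key=len,
    reverse=True,
)

_ANOMER = {"α": "alpha", "a": "alpha", "β": "beta", "b": "beta"}

_NAME_RE = re.compile(r"[A-Za-z][A-Za-z0-9]*")
_SUBST_RE = re.compile(r"(\d*)([A-Za-z0-9]+)")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.residues: list[Residue] = []
        self.bonds: list[Bond] = []

    # -- low-level helpers -------------------------------------------------

    def fail(self, message: str) -> GlycanParseError:
        return GlycanParseError(message, self.pos)

    def peek(self, n: int = 1) -> str:
        return self.text[self.pos : self.pos + n]

    def at_end(self) -> bool:
        return self.pos >= len(self.text)

    def expect(self, literal: str) -> None:
        if not self.text.startswith(literal, self.pos):
            raise self.fail(f"expected {literal!r}")
        self.pos += len(literal)

    def expect_arrow(self) -> None:
        for arrow in ("→", "->"):
            if self.text.startswith(arrow, self.pos):
                self.pos += len(arrow)
                return
        raise self.fail("expected '→'")

    def parse_int(self) -> int:
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos].isdigit():
            self.pos += 1
        if self.pos == start:
            raise self.fail("expected a carbon index")
        return int(self.text[start : self.pos])

    # -- residues ----------------------------------------------------------

    def parse_residue(self, sidechain: bool) -> Residue:
        anomeric = "none"
        config = "none"
        if self.peek() in _ANOMER and self.peek(2)[1:] == "-":
            anomeric = _ANOMER[self.peek()]
            self.pos += 2
        if self.peek() in ("D", "L") and self.peek(2)[1:] == "-":
            config = self.peek()
            self.pos += 2
        match = _NAME_RE.match(self.text, self.pos)
        if not match:
            raise self.fail("expected a residue name")
        name = match.group(0)
        parent = next((p for p in _KNOWN_PARENTS if name.startswith(p)), None)
        if parent is None:
            raise UnknownResidueError(f"unknown parent sugar in token {name!r}")
        rest = name[len(parent) :]
        if parent in OPEN_CHAIN_PARENTS or PARENT_ALIASES.get(parent) in OPEN_CHAIN_PARENTS:
            ring_form = "open"
            if anomeric != "none":
                raise self.fail(f"open-chain residue {parent!r} cannot be α/β")
        else:
            if not rest or rest[0] not in ("p", "f"):
                raise self.fail(f"residue {name!r} lacks a ring letter p/f")
            ring_form = rest[0]
            rest = rest[1:]
        substituents: list[tuple[int, str]] = []
        if rest:
            m = _SUBST_RE.fullmatch(rest)
            if not m:
                raise self.fail(f"unrecognized substituent {rest!r}")
            substituents.append((int(m.group(1)) if m.group(1) else 0, m.group(2)))
        self.pos = match.end()
        residue = Residue(
            index=len(self.residues),
            parent_sugar=parent,
            absolute_config=config,
            ring_form=ring_form,
            anomeric_config=anomeric,
            substituents=substituents,
            sidechain=sidechain,
        )
        self.residues.append(residue)
        return residue

    # -- chains ------------------------------------------------------------

    def parse_chain(self, sidechain: bool) -> tuple[Residue, Residue, int, int]:
        """Parse a chain; returns (first, last, last_donor_carbon, final_acceptor).

        For the main chain the trailing linkage is the repeat boundary
        ``-(x→`` and ``final_acceptor`` is unused (−1); inside a branch it is
        the fully specified attach bond ``-(x→y)`` and ``final_acceptor`` is
        the carbon on the upcoming main-chain residue.
        """
        first = self.parse_residue(sidechain)
        prev = first
        pending_branches: list[tuple[Residue, int, int]] = []
        while True:
            self.expect("-(")
            donor_carbon = self.parse_int()
            self.expect_arrow()
            if not sidechain and self.at_end():
                # repeat boundary "(x→" ends the string
                self._attach_pending(pending_branches, None)
                return first, prev, donor_carbon, -1
            branch: tuple[Residue, int, int] | None = None
            if self.peek() == "[":
                self.expect("[")
                b_first, b_last, b_donor, b_acceptor = self.parse_chain(sidechain=True)
                self.expect("]")
                self.expect("-")
                branch = (b_last, b_donor, b_acceptor)
            acceptor_carbon = self.parse_int()
            self.expect(")")
            if sidechain and self.peek() != "-":
                # "-(x→y)" directly before "]" closes the branch
                if branch is not None:
                    raise self.fail("branch may not end in another branch")
                self._attach_pending(pending_branches, None)
                return first, prev, donor_carbon, acceptor_carbon
            self.expect("-")
            nxt = self.parse_residue(sidechain)
            self.bonds.append(
                Bond(
                    donor=prev.index,
                    donor_carbon=donor_carbon,
                    acceptor=nxt.index,
                    acceptor_carbon=acceptor_carbon,
                    anomeric_config=prev.anomeric_config,
                )
            )
            if branch is not None:
                pending_branches.append(branch)
            self._attach_pending(pending_branches, nxt)
            prev = nxt

    def _attach_pending(
        self, pending: list[tuple[Residue, int, int]], acceptor: Residue | None
    ) -> None:
        if not pending:
            return
        if acceptor is None:
            raise self.fail("branch has no following residue to attach to")
        for b_last, b_donor, b_acceptor in pending:
            self.bonds.append(
                Bond(
                    donor=b_last.index,
                    donor_carbon=b_donor,
                    acceptor=acceptor.index,
                    acceptor_carbon=b_acceptor,
                    anomeric_config=b_last.anomeric_config,
                )
            )
        pending.clear()


def parse_repeat_unit(text: str) -> RepeatUnit:
    """Parse one repeat-unit string into a :class:`RepeatUnit`.

    Raises :class:`GlycanParseError` (with a character position) on malformed
    input, :class:`UnknownResidueError` for unrecognized parent sugars, and
    :class:`StructuralError` if the bonds do not form a tree.
    """
    parser = _Parser(text.strip())
    parser.expect_arrow()
    boundary_acceptor_carbon = parser.parse_int()
    parser.expect(")")
    parser.expect("-")
    first, last, boundary_donor_carbon, _ = parser.parse_chain(sidechain=False)
    if not parser.at_end():
        raise parser.fail("unexpected trailing text")
    return RepeatUnit(
        residues={r.index: r for r in parser.residues},
        bonds=parser.bonds,
        und_pp_residue=last.index,
        polymerase_bond=PolymeraseBond(
            anomeric_config=last.anomeric_config,
            donor_carbon=boundary_donor_carbon,
            acceptor=first.index,
            acceptor_carbon=boundary_acceptor_carbon,
        ),
    )
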