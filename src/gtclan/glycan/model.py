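"""Domain model for repeat units and their backbone translations."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import StructuralError, UnsupportedInputError
from .stereo import StereoTable, bond_axiality


@dataclass
class Residue:
    """One monosaccharide (or open-chain polyol) of a repeat unit."""

    index: int  # position in the parsed main/branch order, used as identity
    parent_sugar: str
    absolute_config: str  # "D" | "L" | "none"
    ring_form: str  # "p" | "f" | "open"
    anomeric_config: str  # "alpha" | "beta" | "none"
    substituents: list[tuple[int, str]] = field(default_factory=list)
    sidechain: bool = False

    def __post_init__(self) -> None:
        if self.ring_form == "open" and self.anomeric_config != "none":
            raise StructuralError(
                f"open-chain residue {self.parent_sugar} cannot carry an anomeric configuration"
            )

    def label(self) -> str:
        cfg = f"{self.absolute_config}-" if self.absolute_config != "none" else ""
        ring = self.ring_form if self.ring_form != "open" else ""
        return f"{cfg}{self.parent_sugar}{ring}"


@dataclass
class Bond:
    """Intramolecular glycosidic bond: donor's anomeric carbon to an acceptor carbon."""

    donor: int  # residue index
    donor_carbon: int
    acceptor: int  # residue index
    acceptor_carbon: int
    anomeric_config: str  # of the donor


@dataclass
class PolymeraseBond:
    """The inter-repeat bond formed by the polymerase."""

    anomeric_config: str  # of the reducing-end (donor) residue
    donor_carbon: int
    acceptor: int  # residue index of the +1 residue
    acceptor_carbon: int


@dataclass
class RepeatUnit:
    """A parsed repeat unit: residues plus its bond tree and boundary bond."""

    residues: dict[int, Residue]
    bonds: list[Bond]
    und_pp_residue: int
    polymerase_bond: PolymeraseBond

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = set(self.residues)
        if self.und_pp_residue not in ids:
            raise StructuralError("reducing-end residue missing from the unit")
        if self.polymerase_bond.acceptor not in ids:
            raise StructuralError("polymerase-bond acceptor residue missing from the unit")
        # the intramolecular bonds must form a tree over all residues
        if len(self.bonds) != len(ids) - 1:
            raise StructuralError(
                f"{len(self.bonds)} bonds over {len(ids)} residues do not form a tree"
            )
        seen: set[int] = set()
        adj = self.adjacency()
        stack = [self.und_pp_residue]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(n for n, _ in adj[node] if n not in seen)
        if seen != ids:
            raise StructuralError("bond specification is cyclic or disconnected")

    def adjacency(self) -> dict[int, list[tuple[int, Bond]]]:
        adj: dict[int, list[tuple[int, Bond]]] = {i: [] for i in self.residues}
        for bond in self.bonds:
            if bond.donor not in adj or bond.acceptor not in adj:
                raise StructuralError("bond references an unknown residue")
            adj[bond.donor].append((bond.acceptor, bond))
            adj[bond.acceptor].append((bond.donor, bond))
        return adj


def extract_backbone(unit: RepeatUnit) -> list[Residue]:
    """Unique tree path from the reducing-end residue to the polymerase acceptor.

    Residues off the path (branches) are excluded; a path of length 1 (the
    degenerate acceptor == reducing-end case) is returned and rejected later
    by translation-dependent scoring.
    """
    target = unit.polymerase_bond.acceptor
    adj = unit.adjacency()
    prev: dict[int, int] = {unit.und_pp_residue: -1}
    stack = [unit.und_pp_residue]
    while stack:
        node = stack.pop()
        if node == target:
            break
        for nxt, _ in adj[node]:
            if nxt not in prev:
                prev[nxt] = node
                stack.append(nxt)
    if target not in prev:
        raise StructuralError("polymerase acceptor unreachable from the reducing end")
    path = [target]
    while path[-1] != unit.und_pp_residue:
        path.append(prev[path[-1]])
    path.reverse()
    return [unit.residues[i] for i in path]


@dataclass(frozen=True)
class BackboneUnit:
    """Geometric translation of one backbone residue.

    ``token`` is the canonical rendering ``class:donor_carbon+orient:
    acceptor_carbon+orient``; two units contribute to the similarity score
    only when their tokens are identical in full.
    """

    ring_class: str  # "P" | "F" | "L"
    donor_carbon: int
    donor_orient: str  # "U" | "D" | "N"
    acceptor_carbon: int
    acceptor_orient: str

    @property
    def token(self) -> str:
        return (
            f"{self.ring_class}:{self.donor_carbon}{self.donor_orient}"
            f":{self.acceptor_carbon}{self.acceptor_orient}"
        )


class BackboneString:
    """Ordered backbone units from the reducing end to the non-reducing end.

    Subsites are addressed with 1-based signed indices: ``minus(k)`` is the
    k-th unit from the reducing end (the −k subsite), ``plus(k)`` the k-th
    from the non-reducing end (the +k subsite); ``plus(k)`` aliases
    ``minus(n−k+1)``.
    """

    def __init__(self, units: list[BackboneUnit], id: str | None = None):
        if len(units) < 2:
            raise UnsupportedInputError(
                f"backbone of length {len(units)} is unsupported (need ≥ 2 subsites)"
            )
        self.units = list(units)
        self.id = id

    def __len__(self) -> int:
        return len(self.units)

    def minus(self, k: int) -> BackboneUnit:
        if not 1 <= k <= len(self.units):
            raise IndexError(f"subsite -{k} out of range")
        return self.units[k - 1]

    def plus(self, k: int) -> BackboneUnit:
        if not 1 <= k <= len(self.units):
            raise IndexError(f"subsite +{k} out of range")
        return self.units[len(self.units) - k]

    @property
    def tokens(self) -> list[str]:
        return [u.token for u in self.units]

    def __repr__(self) -> str:  # pragma: no cover
        return f"BackboneString({' '.join(self.tokens)})"


_RING_CLASS = {"p": "P", "f": "F", "open": "L"}


def translate(unit: RepeatUnit, table: StereoTable) -> BackboneString:
    """Translate a repeat unit to its backbone geometric token string.

    One unit per backbone residue, ordered reducing → non-reducing end.
    Donor fields come from the bond each residue donates toward the reducing
    end (for the −1 residue, the polymerase bond); acceptor fields from the
    carbon at which the next backbone residue (or, for +1, the polymerase
    bond) attaches.  Substituents and sidechain branches never influence any
    token.
    """
    path = extract_backbone(unit)
    bond_lookup = {(b.donor, b.acceptor): b for b in unit.bonds}
    units: list[BackboneUnit] = []
    for i, res in enumerate(path):
        if i == 0:
            donor_carbon = unit.polymerase_bond.donor_carbon
            donor_anomer = unit.polymerase_bond.anomeric_config
        else:
            bond = bond_lookup.get((res.index, path[i - 1].index))
            if bond is None:
                raise StructuralError(
                    f"backbone residue {res.label()} does not donate to its reducing-side neighbour"
                )
            donor_carbon = bond.donor_carbon
            donor_anomer = bond.anomeric_config
        if i == len(path) - 1:
            acceptor_carbon = unit.polymerase_bond.acceptor_carbon
        else:
            bond = bond_lookup.get((path[i + 1].index, res.index))
            if bond is None:
                raise StructuralError(
                    f"backbone residue {res.label()} does not accept from its non-reducing-side neighbour"
                )
            acceptor_carbon = bond.acceptor_carbon
        units.append(
            BackboneUnit(
                ring_class=_RING_CLASS[res.ring_form],
                donor_carbon=donor_carbon,
                donor_orient=table.anomeric_orientation(
                    res.absolute_config, donor_anomer, res.ring_form
                ),
                acceptor_carbon=acceptor_carbon,
                acceptor_orient=table.ring_orientation(
                    res.parent_sugar, res.ring_form, acceptor_carbon, res.absolute_config
                ),
            )
        )
    return BackboneString(units)


@dataclass(frozen=True)
class Mechanism:
    """Inferred reaction stereochemistry of the polymerase."""

    value: str  # "retaining" | "inverting"
    bond_geometry: str  # "axial" | "equatorial"


def infer_mechanism(unit: RepeatUnit, table: StereoTable) -> Mechanism:
    """Axial polymerase bond ⇒ retaining; equatorial ⇒ inverting.

    The bond is axial for alpha linkages of D-sugars and beta linkages of
    L-sugars (the configuration of the reducing-end donor residue).
    """
    donor = unit.residues[unit.und_pp_residue]
    geometry = bond_axiality(donor.absolute_config, unit.polymerase_bond.anomeric_config)
    value = "retaining" if geometry == "axial" else "inverting"
    return Mechanism(value=value, bond_geometry=geometry)
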