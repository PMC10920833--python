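"""Stereochemistry table for backbone translation.

Ring hydroxyl orientations are taken from the standard Haworth projection of
the D-enantiomer (ring oxygen back-right, C1 rightmost): a hydroxyl drawn on
the right in the Fischer projection points below the ring plane (``D``), on
the left above it (``U``).  L-sugars are the exact mirror, so their entries
are obtained by flipping ``U`` and ``D``.  Exocyclic carbons (C6 of a
hexopyranose, C5/C6 of a furanose) and every carbon of an open-chain polyol
are conformationally flexible and map to ``N``.

The table is deliberately explicit and user-overridable: uronic acids and
deoxy/amino variants reuse the ring pattern of their neutral parent sugar.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from ..errors import ConfigurationError, StereoTableError, UndeterminedMechanismError

# Fischer right/left pattern of the *D*-enantiomer, encoded as Haworth U/D for
# the ring hydroxyl at each carbon.  Keyed by (parent, ring_form).
_D_RING_PATTERNS: dict[tuple[str, str], dict[int, str]] = {
    # hexopyranoses (ring C1-C5, exocyclic C6)
    ("Glc", "p"): {2: "D", 3: "U", 4: "D"},
    ("Gal", "p"): {2: "D", 3: "U", 4: "U"},
    ("Man", "p"): {2: "U", 3: "U", 4: "D"},
    ("All", "p"): {2: "D", 3: "D", 4: "D"},
    ("Alt", "p"): {2: "U", 3: "D", 4: "D"},
    ("Gul", "p"): {2: "D", 3: "D", 4: "U"},
    ("Ido", "p"): {2: "U", 3: "D", 4: "U"},
    ("Tal", "p"): {2: "U", 3: "U", 4: "U"},
    # 6-deoxyhexoses share the ring pattern of their hexose parent
    ("Rha", "p"): {2: "U", 3: "U", 4: "D"},  # 6-deoxy-Man
    ("Fuc", "p"): {2: "D", 3: "U", 4: "U"},  # 6-deoxy-Gal
    ("Qui", "p"): {2: "D", 3: "U", 4: "D"},  # 6-deoxy-Glc
    # pentopyranoses (ring C1-C5, no exocyclic carbon)
    ("Xyl", "p"): {2: "D", 3: "U", 4: "D"},
    ("Rib", "p"): {2: "D", 3: "D", 4: "D"},
    ("Ara", "p"): {2: "U", 3: "D", 4: "D"},
    ("Lyx", "p"): {2: "U", 3: "U", 4: "D"},
    # furanoses (ring C1-C4, exocyclic C5 and, for hexoses, C6)
    ("Rib", "f"): {2: "D", 3: "D"},
    ("Ara", "f"): {2: "U", 3: "D"},
    ("Xyl", "f"): {2: "D", 3: "U"},
    ("Gal", "f"): {2: "D", 3: "U"},
    ("Glc", "f"): {2: "D", 3: "U"},
    ("Fuc", "f"): {2: "D", 3: "U"},
}

# total carbon count per parent, used to bound exocyclic N assignments
_N_CARBONS: dict[str, int] = {
    "Glc": 6, "Gal": 6, "Man": 6, "All": 6, "Alt": 6, "Gul": 6, "Ido": 6,
    "Tal": 6, "Rha": 6, "Fuc": 6, "Qui": 6,
    "Xyl": 5, "Rib": 5, "Ara": 5, "Lyx": 5,
    "Gro": 3, "Rbo": 5,
}

#: uronic acids and common aliases resolved to their neutral ring parent
PARENT_ALIASES: dict[str, str] = {
    "GlcA": "Glc", "GalA": "Gal", "ManA": "Man", "IdoA": "Ido", "GulA": "Gul",
    "GlcN": "Glc", "GalN": "Gal", "ManN": "Man",
    "Glycerol": "Gro", "Ribitol": "Rbo",
}

#: open-chain polyols: class L, every position N
OPEN_CHAIN_PARENTS = frozenset({"Gro", "Rbo"})

_RING_SIZE = {"p": 5, "f": 4}  # ring carbons C1..size

_FLIP = {"U": "D", "D": "U", "N": "N"}


def _anomeric_orientation(absolute_config: str, anomeric_config: str) -> str:
    # Haworth of the D-sugar: alpha anomeric oxygen below the ring, beta above
    if absolute_config == "D":
        return "D" if anomeric_config == "alpha" else "U"
    return "U" if anomeric_config == "alpha" else "D"


def bond_axiality(absolute_config: str, anomeric_config: str) -> str:
    """Axial vs equatorial geometry of a glycosidic bond.

    Alpha bonds of D-sugars and beta bonds of L-sugars are axial; the other
    two combinations are equatorial.
    """
    if anomeric_config not in ("alpha", "beta"):
        raise UndeterminedMechanismError(
            "bond geometry undefined without an anomeric configuration"
        )
    if absolute_config not in ("D", "L"):
        raise UndeterminedMechanismError(
            "bond geometry undefined without an absolute configuration"
        )
    axial = (absolute_config == "D") == (anomeric_config == "alpha")
    return "axial" if axial else "equatorial"


@dataclass
class StereoTable:
    """Orientation lookups for ring oxygens and anomeric bonds.

    ``ring_patterns`` holds D-enantiomer Haworth orientations; lookups for
    L-sugars mirror them.  ``overrides`` (from :meth:`load_overrides`) win
    over the built-in entries and are keyed by the config they were declared
    for (no mirroring applied).
    """

    ring_patterns: dict[tuple[str, str], dict[int, str]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _D_RING_PATTERNS.items()}
    )
    n_carbons: dict[str, int] = field(default_factory=lambda: dict(_N_CARBONS))
    overrides: dict[tuple[str, str, int, str], str] = field(default_factory=dict)

    def resolve_parent(self, parent: str) -> str:
        return PARENT_ALIASES.get(parent, parent)

    def knows(self, parent: str, ring_form: str) -> bool:
        parent = self.resolve_parent(parent)
        if ring_form == "open":
            return parent in OPEN_CHAIN_PARENTS
        return (parent, ring_form) in self.ring_patterns

    def ring_orientation(
        self, parent: str, ring_form: str, carbon: int, absolute_config: str
    ) -> str:
        """U/D/N orientation of the oxygen at ``carbon`` used as an acceptor."""
        key_parent = self.resolve_parent(parent)
        override = self.overrides.get((key_parent, ring_form, carbon, absolute_config))
        if override is not None:
            return override
        if ring_form == "open":
            if key_parent not in OPEN_CHAIN_PARENTS:
                raise StereoTableError(
                    f"no open-chain entry for sugar {parent!r}"
                )
            return "N"
        pattern = self.ring_patterns.get((key_parent, ring_form))
        if pattern is None:
            raise StereoTableError(
                f"no stereochemistry entry for sugar {parent!r} ({ring_form})"
            )
        if carbon in pattern:
            orient = pattern[carbon]
            return _FLIP[orient] if absolute_config == "L" else orient
        total = self.n_carbons.get(key_parent, 6)
        ring_size = _RING_SIZE[ring_form]
        if ring_size < carbon <= total:
            return "N"  # exocyclic: conformationally flexible
        raise StereoTableError(
            f"carbon {carbon} of sugar {parent!r} ({ring_form}) cannot accept a bond"
        )

    def anomeric_orientation(
        self, absolute_config: str, anomeric_config: str, ring_form: str
    ) -> str:
        """U/D/N orientation of the anomeric (donor) oxygen."""
        if ring_form == "open" or anomeric_config == "none":
            return "N"
        return _anomeric_orientation(absolute_config, anomeric_config)

    def load_overrides(self, path: str) -> None:
        """Apply a TSV of columns parent_sugar, ring_form, carbon, config, orientation."""
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"parent_sugar", "ring_form", "carbon", "config", "orientation"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ConfigurationError(
                    f"stereo override TSV must have columns {sorted(required)}"
                )
            for row in reader:
                orient = row["orientation"].strip().upper()
                if orient not in ("U", "D", "N"):
                    raise ConfigurationError(
                        f"invalid orientation {row['orientation']!r} in {path}"
                    )
                key = (
                    self.resolve_parent(row["parent_sugar"].strip()),
                    row["ring_form"].strip(),
                    int(row["carbon"]),
                    row["config"].strip(),
                )
                self.overrides[key] = orient


DEFAULT_STEREO_TABLE = StereoTable()
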