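import pytest

from gtclan.align import blosum62
from gtclan.glycan import BackboneString, BackboneUnit

# canonical worked trisaccharide: Gal + 2 Glc, intramolecular beta1->3 and
# alpha1->4, polymerase bond alpha1->3
FIG_TRISACCHARIDE = "→3)-β-D-Galp-(1→3)-α-D-Glcp-(1→4)-α-D-Glcp-(1→"

# three distinct, structurally valid backbone tokens for synthetic strings
TOKEN_UNITS = {
    "A": BackboneUnit("P", 1, "U", 3, "U"),
    "B": BackboneUnit("P", 1, "D", 3, "U"),
    "C": BackboneUnit("P", 1, "U", 4, "D"),
    "D": BackboneUnit("P", 1, "D", 4, "D"),
    "E": BackboneUnit("P", 1, "U", 4, "U"),
    "F": BackboneUnit("P", 1, "D", 4, "U"),
    "G": BackboneUnit("P", 1, "D", 2, "D"),
}


def backbone(letters: str) -> BackboneString:
    """Build a backbone string (reducing → non-reducing) from token letters."""
    return BackboneString([TOKEN_UNITS[ch] for ch in letters])


@pytest.fixture(scope="session")
def matrix():
    return blosum62()
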