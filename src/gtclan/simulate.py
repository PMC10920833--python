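"""Seeded generators for protein families, glycan repeat units, and
hierarchical point clouds with known ground truth.

All generators are pure functions of (spec, seed): rerunning with the same
spec reproduces identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .align import (
    AMINO_ACIDS,
    BACKGROUND_FREQS,
    DistanceMatrix,
    SequenceRecord,
    blosum62,
    smith_waterman,
)
from .errors import ConfigurationError
from .glycan.stereo import DEFAULT_STEREO_TABLE, _D_RING_PATTERNS

# ---------------------------------------------------------------------------
# protein families
# ---------------------------------------------------------------------------


@dataclass
class ProteinFamilySpec:
    n_families: int = 3
    sequences_per_family: int = 20
    ancestor_length: int = 150
    within_identity: float = 0.45
    between_identity: float = 0.06
    indel_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.ancestor_length < 50:
            raise ConfigurationError("ancestor_length must be >= 50")
        if not 0 < self.within_identity < 1:
            raise ConfigurationError("within_identity must be in (0, 1)")
        if not self.between_identity < self.within_identity:
            raise ConfigurationError("between_identity must be below within_identity")
        if self.between_identity > 0.25:
            raise ConfigurationError(
                "between-family identity above 0.25 is unattainable with independent ancestors"
            )


@dataclass
class ProteinDataset:
    records: list[SequenceRecord]
    labels: dict[str, str]
    stats: dict = field(default_factory=dict)


def _blosum_substitution_probs() -> np.ndarray:
    """P(b | a, b != a) implied by BLOSUM62 half-bit scores and backgrounds."""
    m = blosum62()
    bg = np.array([BACKGROUND_FREQS[a] for a in AMINO_ACIDS])
    probs = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                probs[i, j] = bg[j] * 2.0 ** (m.score(a, b) / 2.0)
        probs[i] /= probs[i].sum()
    return probs


def _coincidence_prob(sub_probs: np.ndarray, bg: np.ndarray) -> float:
    # probability that two independent substitutions of the same residue agree
    per_residue = (sub_probs**2).sum(axis=1)
    return float((bg * per_residue).sum())


def generate_protein_families(spec: ProteinFamilySpec) -> ProteinDataset:
    """Families of seeded homologs hitting the within-identity target.

    Each family descends from an independent random ancestor; members are
    produced by per-site substitution (targets drawn from BLOSUM62-implied
    conditional frequencies) at the rate that makes the *pairwise* member
    identity match ``within_identity``, plus short random indels.  Between
    families, identity sits near the random expectation.  Realized identity
    statistics over sampled pairs are reported in ``stats``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bg = np.array([BACKGROUND_FREQS[a] for a in AMINO_ACIDS])
    bg = bg / bg.sum()
    sub_probs = _blosum_substitution_probs()
    c = _coincidence_prob(sub_probs, bg)
    # pairwise identity w = (1-p)^2 + c p^2  =>  solve for per-site rate p
    w = spec.within_identity
    disc = 1.0 - (1.0 + c) * (1.0 - w)
    if disc < 0:
        raise ConfigurationError("within_identity target unattainable")
    p = (1.0 - math.sqrt(disc)) / (1.0 + c)

    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    alphabet = np.array(list(AMINO_ACIDS))
    for fam in range(spec.n_families):
        family = f"fam{fam + 1}"
        ancestor = rng.choice(20, size=spec.ancestor_length, p=bg)
        for member in range(spec.sequences_per_family):
            seq = ancestor.copy()
            mutate = rng.random(len(seq)) < p
            for pos in np.where(mutate)[0]:
                seq[pos] = rng.choice(20, p=sub_probs[seq[pos]])
            chars = list(alphabet[seq])
            n_indels = rng.poisson(spec.indel_rate * len(chars))
            for _ in range(n_indels):
                length = int(rng.integers(1, 4))
                pos = int(rng.integers(0, max(1, len(chars) - length)))
                if rng.random() < 0.5 and len(chars) > 60 + length:
                    del chars[pos : pos + length]
                else:
                    insert = alphabet[rng.choice(20, size=length, p=bg)]
                    chars[pos:pos] = list(insert)
            rec = SequenceRecord(id=f"{family}_s{member + 1}", sequence="".join(chars))
            records.append(rec)
            labels[rec.id] = family

    stats = _identity_stats(records, labels, rng)
    return ProteinDataset(records=records, labels=labels, stats=stats)


def _identity_stats(
    records: list[SequenceRecord], labels: dict[str, str], rng: np.random.Generator,
    max_pairs: int = 30,
) -> dict:
    m = blosum62()
    within: list[float] = []
    between: list[float] = []
    pairs = [
        (i, j)
        for i in range(len(records))
        for j in range(i + 1, len(records))
    ]
    rng.shuffle(pairs)
    for i, j in pairs:
        same = labels[records[i].id] == labels[records[j].id]
        bucket = within if same else between
        if len(bucket) >= max_pairs:
            continue
        bucket.append(smith_waterman(records[i], records[j], m).identity_fraction)
        if len(within) >= max_pairs and len(between) >= max_pairs:
            break
    return {
        "within_identity_mean": float(np.mean(within)) if within else None,
        "between_identity_mean": float(np.mean(between)) if between else None,
        "n_within_sampled": len(within),
        "n_between_sampled": len(between),
    }


# ---------------------------------------------------------------------------
# glycan repeat units
# ---------------------------------------------------------------------------


@dataclass
class GlycanFamilySpec:
    n_families: int = 3
    units_per_family: int = 8
    min_length: int = 3
    max_length: int = 7
    end_conservation: float = 1.0
    middle_variability: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 2 <= self.min_length <= self.max_length <= 12:
            raise ConfigurationError("backbone length range must lie within [2, 12]")
        for name in ("end_conservation", "middle_variability"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")


@dataclass
class _ResidueDraw:
    anomer: str  # "a" | "b" | "" (open chain)
    config: str  # "D" | "L" | ""
    name: str  # e.g. "Glcp"
    acceptor_carbon: int

    def render(self) -> str:
        parts = []
        if self.anomer:
            parts.append("α" if self.anomer == "a" else "β")
        if self.config:
            parts.append(self.config)
        parts.append(self.name)
        return "-".join(parts)


@dataclass
class GlycanDataset:
    ids: list[str]
    strings: list[str]
    labels: dict[str, str]


def _residue_catalog() -> list[tuple[str, str, list[int]]]:
    """(name, ring, acceptor carbons) choices reachable in the built-in table."""
    catalog: list[tuple[str, str, list[int]]] = []
    for (parent, ring), pattern in sorted(_D_RING_PATTERNS.items()):
        carbons = sorted(pattern)
        total = DEFAULT_STEREO_TABLE.n_carbons.get(parent, 6)
        if ring == "p" and total >= 6:
            carbons = carbons + [6]
        if ring == "f":
            carbons = carbons + [5]
        catalog.append((parent + ring, ring, carbons))
    return catalog


_CATALOG = _residue_catalog()


def _draw_residue(rng: np.random.Generator, open_ok: bool = False) -> _ResidueDraw:
    if open_ok and rng.random() < 0.08:
        name, carbons = ("Rbo", [2, 3, 4]) if rng.random() < 0.5 else ("Gro", [2, 3])
        return _ResidueDraw("", "", name, int(rng.choice(carbons)))
    name, _, carbons = _CATALOG[int(rng.integers(len(_CATALOG)))]
    return _ResidueDraw(
        anomer="a" if rng.random() < 0.5 else "b",
        config="D" if rng.random() < 0.75 else "L",
        name=name,
        acceptor_carbon=int(rng.choice(carbons)),
    )


def render_repeat_unit(residues: list[_ResidueDraw]) -> str:
    """Render a non-reducing→reducing residue chain as a repeat-unit string.

    ``residues[0]`` is the +1 (polymerase acceptor) residue; its
    ``acceptor_carbon`` becomes the leading boundary carbon.  Every residue
    donates from C1.
    """
    out = [f"→{residues[0].acceptor_carbon})-"]
    for i, res in enumerate(residues):
        out.append(res.render())
        if i + 1 < len(residues):
            out.append(f"-(1→{residues[i + 1].acceptor_carbon})-")
        else:
            out.append("-(1→")
    return "".join(out)


def generate_glycan_families(spec: GlycanFamilySpec) -> GlycanDataset:
    """Repeat-unit families with conserved ends and variable middles.

    Each family draws a template chain; members keep the template's terminal
    residues with probability ``end_conservation`` and resample interior
    residues with probability ``middle_variability``.  The reducing-end
    anomeric configuration (hence the inferred mechanism) is conserved within
    each family.  All emitted strings parse and translate cleanly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ids: list[str] = []
    strings: list[str] = []
    labels: dict[str, str] = {}
    for fam in range(spec.n_families):
        family = f"gfam{fam + 1}"
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        template = [_draw_residue(rng) for _ in range(length)]
        for member in range(spec.units_per_family):
            chain: list[_ResidueDraw] = []
            for pos, res in enumerate(template):
                terminal = pos == 0 or pos == length - 1
                if terminal:
                    keep = rng.random() < spec.end_conservation
                else:
                    keep = rng.random() >= spec.middle_variability
                if keep:
                    chain.append(res)
                else:
                    chain.append(_draw_residue(rng, open_ok=not terminal))
            # conserve the polymerase bond's anomeric configuration per family
            last = chain[-1]
            chain[-1] = _ResidueDraw(
                anomer=template[-1].anomer,
                config=last.config,
                name=last.name,
                acceptor_carbon=last.acceptor_carbon,
            )
            gid = f"{family}_g{member + 1}"
            ids.append(gid)
            strings.append(render_repeat_unit(chain))
            labels[gid] = family
    return GlycanDataset(ids=ids, strings=strings, labels=labels)


# ---------------------------------------------------------------------------
# hierarchical point clouds
# ---------------------------------------------------------------------------


def _random_unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.normal(size=dim)
    return v / np.linalg.norm(v)


def _place(
    names: list[str],
    center: np.ndarray,
    scale: float,
    ratio: float,
    rng: np.random.Generator,
    coords: dict[str, np.ndarray],
) -> str:
    if len(names) == 1:
        coords[names[0]] = center
        return names[0]
    half = len(names) // 2
    direction = _random_unit(rng, len(center))
    left = _place(names[:half], center - direction * scale / 2, scale / ratio, ratio, rng, coords)
    right = _place(names[half:], center + direction * scale / 2, scale / ratio, ratio, rng, coords)
    return f"({left},{right})"


def generate_hierarchical_points(
    n_clades: int = 3,
    points_per_clade: int = 8,
    separation: float = 10.0,
    seed: int = 0,
    dim: int = 5,
) -> tuple[DistanceMatrix, str, dict[str, str]]:
    """Euclidean point clouds with a planted, fully resolved binary topology.

    Clade centers and within-clade points are both placed by recursive
    bisection with geometrically shrinking displacement scales; clades sit
    ``separation`` apart while the within-clade spread is of order 1.
    Returns the exact Euclidean distance matrix, the planted topology as
    newick, and a point → clade label map.
    """
    if separation <= 2.0:
        raise ConfigurationError("separation must exceed the within-clade spread")
    rng = np.random.default_rng(seed)
    coords: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}

    clade_centers: dict[str, np.ndarray] = {}
    placeholders = [f"\x00{i}\x00" for i in range(n_clades)]
    clade_newick = _place(
        placeholders, np.zeros(dim), separation * max(1, n_clades - 1), 2.0, rng,
        clade_centers,
    )
    for i, token in enumerate(placeholders):
        clade = f"c{i + 1}"
        names = [f"{clade}_p{j + 1}" for j in range(points_per_clade)]
        sub_newick = _place(names, clade_centers[token], 1.0, 3.0, rng, coords)
        clade_newick = clade_newick.replace(token, sub_newick)
        for name in names:
            labels[name] = clade

    ids = sorted(coords)
    pts = np.array([coords[i] for i in ids])
    diff = pts[:, None, :] - pts[None, :, :]
    d = DistanceMatrix(ids, np.sqrt((diff**2).sum(axis=-1)))
    return d, clade_newick + ";", labels
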