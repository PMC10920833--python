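"""Local pairwise alignment, bit scores, and the Scoredist-variant distance.

The aligner is a thin, validated wrapper around Biopython's
:class:`Bio.Align.PairwiseAligner` (exact affine-gap Smith–Waterman in local
mode); scoring constants follow the BLAST defaults so that bit scores live
on the familiar scale.  A gap of length ``g`` costs ``gap_open +
gap_extend * g`` (existence plus per-residue), i.e. the BLAST convention for
open 11 / extend 1.

The evolutionary distance normalizes the alignment score to the *shorter*
sequence length: with expected random score ``sigma_r = min(len_a, len_b) *
E[s]`` under the matrix's background frequencies, ``sigma_n = raw -
sigma_r`` and ``sigma_u = (self_a + self_b) / 2 - sigma_r``, the distance is
``-ln(sigma_n / sigma_u) * 100`` capped at ``d_max``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align as _bio_align
from Bio.Align import substitution_matrices as _submat

from .errors import ConfigurationError, DegenerateInputError, InputError

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
ALPHABET = AMINO_ACIDS + "X"

#: Robinson & Robinson background amino-acid frequencies (documented constant)
BACKGROUND_FREQS: dict[str, float] = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.sequence):
            if ch not in ALPHABET:
                raise InputError(
                    f"illegal residue {ch!r} at position {pos} of sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SubstitutionMatrix:
    """Integer substitution scores plus Karlin–Altschul statistics.

    ``lambda_`` is in nats per unit raw score; together with ``K`` it converts
    raw scores to bits.  ``background`` holds the frequencies used for the
    expected-random-score term of the distance.
    """

    name: str
    scores: dict[tuple[str, str], float]
    lambda_: float | None = None
    K: float | None = None
    background: dict[str, float] = field(default_factory=lambda: dict(BACKGROUND_FREQS))

    def score(self, a: str, b: str) -> float:
        return self.scores[(a, b)]

    def expected_score(self) -> float:
        """Per-position expected score under background frequencies (negative)."""
        total = 0.0
        for a, pa in self.background.items():
            for b, pb in self.background.items():
                total += pa * pb * self.scores[(a, b)]
        return total

    def to_biopython(self):
        arr = _submat.Array(alphabet=ALPHABET, dims=2)
        for a in ALPHABET:
            for b in ALPHABET:
                arr[a, b] = self.scores[(a, b)]
        return arr


def blosum62() -> SubstitutionMatrix:
    """BLOSUM62 with the standard gapped-regime parameters (λ=0.267, K=0.041)."""
    raw = _submat.load("BLOSUM62")
    scores = {
        (a, b): float(raw[a, b]) for a in ALPHABET for b in ALPHABET
    }
    return SubstitutionMatrix(name="BLOSUM62", scores=scores, lambda_=0.267, K=0.041)


@dataclass
class AlignmentResult:
    raw_score: int
    identity_fraction: float
    alignment_length: int
    aligned_pairs: list[tuple[int, int]]
    bit_score: float | None = None


def _make_aligner(m: SubstitutionMatrix, gap_open: float, gap_extend: float, mode: str):
    if not (gap_open >= gap_extend > 0):
        raise ConfigurationError("require gap_open >= gap_extend > 0")
    aligner = _bio_align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = m.to_biopython()
    # Biopython charges open_gap_score for the first gap position; our model
    # charges existence + per-residue, hence the sum below.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(
    a: SequenceRecord,
    b: SequenceRecord,
    m: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal affine-gap local alignment with one traceback.

    Returns the raw score, the identity fraction over aligned (non-gap)
    columns, the total column count of the local alignment, and the aligned
    index pairs.  An all-negative scoring situation yields the empty
    alignment with score 0.
    """
    m = m or blosum62()
    aligner = _make_aligner(m, gap_open, gap_extend, mode="local")
    score = aligner.score(a.sequence, b.sequence)
    if score <= 0:
        return AlignmentResult(0, 0.0, 0, [], bit_score=bit_score(0, m))
    alignment = next(iter(aligner.align(a.sequence, b.sequence)))
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    matches = sum(1 for i, j in pairs if a.sequence[i] == b.sequence[j])
    identity = matches / len(pairs) if pairs else 0.0
    return AlignmentResult(
        raw_score=int(round(score)),
        identity_fraction=identity,
        alignment_length=int(alignment.length),
        aligned_pairs=pairs,
        bit_score=bit_score(int(round(score)), m),
    )


def bit_score(raw: float, m: SubstitutionMatrix) -> float:
    """Karlin–Altschul bit score ``(λ·raw − ln K) / ln 2``."""
    if m.lambda_ is None or m.K is None:
        raise ConfigurationError(f"matrix {m.name!r} lacks λ/K parameters")
    return (m.lambda_ * raw - math.log(m.K)) / math.log(2.0)


def scoredist_variant(
    raw: float,
    aa_self: float,
    bb_self: float,
    len_a: int,
    len_b: int,
    m: SubstitutionMatrix,
    d_max: float = 300.0,
    expected_per_position: float | None = None,
) -> float:
    """Scoredist-style distance normalized to the shorter sequence length.

    ``expected_per_position`` overrides the matrix-derived expected random
    score per aligned position (a configurable calibration constant).
    """
    per_pos = m.expected_score() if expected_per_position is None else expected_per_position
    sigma_r = min(len_a, len_b) * per_pos
    sigma_n = raw - sigma_r
    sigma_u = (aa_self + bb_self) / 2.0 - sigma_r
    if sigma_u <= 0:
        raise DegenerateInputError(
            "self-scores do not exceed the expected random score (sigma_u <= 0)"
        )
    if sigma_n <= 0:
        return d_max
    ratio = sigma_n / sigma_u
    if ratio >= 1.0:
        return 0.0
    return min(-math.log(ratio) * 100.0, d_max)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a saturation cap ``d_max``."""

    ids: list[str]
    values: np.ndarray
    d_max: float = 300.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise InputError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise InputError("distances must be nonnegative")

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(rows, rows)], self.d_max)


def all_vs_all(
    seqs: list[SequenceRecord],
    m: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    d_max: float = 300.0,
) -> tuple[np.ndarray, DistanceMatrix]:
    """All-vs-all bit-score matrix and Scoredist-variant distance matrix."""
    if len(seqs) < 2:
        raise InputError("all-vs-all needs at least two sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sequence ids")
    m = m or blosum62()
    aligner = _make_aligner(m, gap_open, gap_extend, mode="local")
    n = len(seqs)
    raw = np.zeros((n, n))
    for i in range(n):
        raw[i, i] = aligner.score(seqs[i].sequence, seqs[i].sequence)
        for j in range(i + 1, n):
            raw[i, j] = raw[j, i] = aligner.score(seqs[i].sequence, seqs[j].sequence)
    bits = np.vectorize(lambda r: bit_score(r, m))(raw)
    per_pos = m.expected_score()
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = scoredist_variant(
                raw[i, j], raw[i, i], raw[j, j], len(seqs[i]), len(seqs[j]),
                m, d_max=d_max, expected_per_position=per_pos,
            )
    return bits, DistanceMatrix(ids, dist, d_max)


@dataclass
class Msa:
    """A gapped multiple sequence alignment (rows of equal length)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise InputError("MSA ids and rows differ in count")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise InputError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def center_star_msa(
    seqs: list[SequenceRecord],
    m: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Msa:
    """Center-star multiple alignment ("once a gap, always a gap").

    The center is the sequence with the highest summed pairwise bit score;
    every other sequence is merged via its global pairwise alignment to the
    center.  Input row order is preserved.  This is a desk-scale stand-in
    for an external MSA tool, adequate for profile building on clustered
    (similar) sequences.
    """
    if len(seqs) < 2:
        if len(seqs) == 1:
            return Msa([seqs[0].id], [seqs[0].sequence])
        raise InputError("MSA needs at least one sequence")
    m = m or blosum62()
    local = _make_aligner(m, gap_open, gap_extend, mode="local")
    n = len(seqs)
    sums = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = bit_score(local.score(seqs[i].sequence, seqs[j].sequence), m)
            sums[i] += s
            sums[j] += s
    center_idx = int(np.argmax(sums))
    center = seqs[center_idx].sequence
    glob = _make_aligner(m, gap_open, gap_extend, mode="global")

    # per sequence: chars aligned to each center position, plus insertions
    # in the len(center)+1 slots between/around center positions
    matches: dict[int, list[str]] = {}
    inserts: dict[int, list[str]] = {}
    for k, rec in enumerate(seqs):
        if k == center_idx:
            continue
        alignment = next(iter(glob.align(center, rec.sequence)))
        c_row, s_row = str(alignment[0]), str(alignment[1])
        match_row = [""] * len(center)
        ins_row = [""] * (len(center) + 1)
        ci = 0
        for cc, sc in zip(c_row, s_row):
            if cc == "-":
                ins_row[ci] += sc
            else:
                match_row[ci] = sc if sc != "-" else "-"
                ci += 1
        matches[k] = match_row
        inserts[k] = ins_row

    max_ins = [0] * (len(center) + 1)
    for ins_row in inserts.values():
        for slot, chunk in enumerate(ins_row):
            max_ins[slot] = max(max_ins[slot], len(chunk))

    def build_row(match_row: list[str], ins_row: list[str]) -> str:
        parts = []
        for slot in range(len(center) + 1):
            parts.append(ins_row[slot].ljust(max_ins[slot], "-"))
            if slot < len(center):
                parts.append(match_row[slot])
        return "".join(parts)

    rows: list[str] = []
    for k, rec in enumerate(seqs):
        if k == center_idx:
            rows.append(build_row(list(center), [""] * (len(center) + 1)))
        else:
            rows.append(build_row(matches[k], inserts[k]))
    return Msa([s.id for s in seqs], rows)
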