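"""Per-cluster frequency profiles and directional profile–profile scoring.

Frequency profiles with background-mix pseudocounts stand in for full HMMs:
column frequencies are ``(count + β·bg) / (observed + β)`` with gaps excluded
from the residue count.  Profile pairs are compared by local affine-gap
alignment over columns with the (asymmetric) log-odds column score
``s(q→t) = Σ_a f_q(a) · log2(f_t(a) / bg(a))`` in bits, so score(q→t) need
not equal score(t→q).

Adapters ingest externally computed pairwise scores (BLAST outfmt-6 tabular
hits, and pre-extracted profile-score TSVs), so the thresholded networks can
be reproduced exactly from real tool output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .align import ALPHABET, AMINO_ACIDS, BACKGROUND_FREQS, Msa
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def default_background() -> np.ndarray:
    return np.array([BACKGROUND_FREQS[a] for a in AMINO_ACIDS])


@dataclass
class Profile:
    """Column-wise amino-acid frequency model of a sequence cluster."""

    cluster_id: str
    frequencies: np.ndarray  # (columns, 20), rows sum to 1
    gap_fractions: np.ndarray  # (columns,)
    n_sequences: int
    beta: float
    background: np.ndarray

    @property
    def n_columns(self) -> int:
        return int(self.frequencies.shape[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "cluster_id": self.cluster_id,
                "alphabet": AMINO_ACIDS,
                "frequencies": self.frequencies.tolist(),
                "gap_fractions": self.gap_fractions.tolist(),
                "n_sequences": self.n_sequences,
                "beta": self.beta,
                "background": self.background.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Profile":
        data = json.loads(text)
        return cls(
            cluster_id=data["cluster_id"],
            frequencies=np.array(data["frequencies"]),
            gap_fractions=np.array(data["gap_fractions"]),
            n_sequences=data["n_sequences"],
            beta=data["beta"],
            background=np.array(data["background"]),
        )


@dataclass(frozen=True)
class ProfileHit:
    """One directional profile-comparison score."""

    query: str
    target: str
    score: float
    query_span: tuple[int, int] = (0, 0)
    target_span: tuple[int, int] = (0, 0)


def build_profile(
    msa: Msa,
    cluster_id: str = "",
    beta: float = 5.0,
    background: np.ndarray | None = None,
) -> Profile:
    """Column frequencies with background-mix pseudocounts (weight ``beta``).

    Columns consisting entirely of gaps fall back to the background
    distribution (their gap fraction is 1).  Row order never matters.
    """
    if not msa.rows:
        raise InputError("cannot build a profile from an empty alignment")
    bg = default_background() if background is None else np.asarray(background, dtype=float)
    n_cols = msa.n_columns
    counts = np.zeros((n_cols, 20))
    gaps = np.zeros(n_cols)
    for row in msa.rows:
        for col, ch in enumerate(row):
            if ch == "-" or ch == ".":
                gaps[col] += 1
            elif ch == "X":
                counts[col] += bg  # ambiguous: spread over the background
            else:
                if ch not in _AA_INDEX:
                    raise InputError(f"illegal alignment character {ch!r}")
                counts[col, _AA_INDEX[ch]] += 1
    observed = counts.sum(axis=1)
    if beta > 0:
        freqs = (counts + beta * bg) / (observed + beta)[:, None]
    else:
        safe = np.maximum(observed, 1.0)
        freqs = counts / safe[:, None]
        all_gap = observed == 0
        freqs[all_gap] = bg
    return Profile(
        cluster_id=cluster_id,
        frequencies=freqs,
        gap_fractions=gaps / len(msa.rows),
        n_sequences=len(msa.rows),
        beta=beta,
        background=bg,
    )


def column_scores(query: Profile, target: Profile) -> np.ndarray:
    """Matrix of directional column scores s(q_i→t_j) in bits."""
    if not np.allclose(query.background, target.background):
        raise ConfigurationError("profiles were built with different backgrounds")
    log_odds = np.log2(np.maximum(target.frequencies, 1e-12) / target.background)
    return query.frequencies @ log_odds.T


def profile_score(
    query: Profile,
    target: Profile,
    gap_open_bits: float = 3.0,
    gap_extend_bits: float = 0.3,
) -> ProfileHit:
    """Directional local profile alignment score (bits).

    Affine gaps: the first gapped column costs ``gap_open_bits +
    gap_extend_bits``, subsequent ones ``gap_extend_bits``.  A comparison
    with no positive-scoring local path reports score 0 with empty spans.
    """
    if query.n_columns == 0 or target.n_columns == 0:
        raise InputError("cannot score an empty profile")
    s = column_scores(query, target)
    nq, nt = s.shape
    open_cost = gap_open_bits + gap_extend_bits
    neg_inf = -np.inf
    # H: best path ending in a match at (i, j); E/F: ending in a gap
    H = np.zeros((nq + 1, nt + 1))
    E = np.full(nt + 1, neg_inf)  # gap in query (move along target)
    best, best_pos = 0.0, (0, 0)
    F_prev = np.full(nt + 1, neg_inf)
    for i in range(1, nq + 1):
        E_run = neg_inf
        F_row = np.maximum(H[i - 1] - open_cost, F_prev - gap_extend_bits)
        for j in range(1, nt + 1):
            E_run = max(H[i, j - 1] - open_cost, E_run - gap_extend_bits)
            h = max(
                0.0,
                H[i - 1, j - 1] + s[i - 1, j - 1],
                E_run,
                F_row[j],
            )
            H[i, j] = h
            if h > best:
                best, best_pos = h, (i, j)
        F_prev = F_row
    return ProfileHit(
        query=query.cluster_id,
        target=target.cluster_id,
        score=float(best),
        query_span=(0, best_pos[0]),
        target_span=(0, best_pos[1]),
    )


@dataclass
class ParseReport:
    n_rows: int = 0
    n_kept: int = 0
    n_skipped: int = 0
    skipped_lines: list[int] = field(default_factory=list)


def parse_blast_tab(path: str) -> tuple[list[tuple[str, str, float]], ParseReport]:
    """Read BLAST outfmt-6-like tabular hits → (query, subject, bitscore) edges.

    Keeps the best bit score per ordered pair (self-hits included); malformed
    rows are skipped with a warning and counted in the report.
    """
    best: dict[tuple[str, str], float] = {}
    report = ParseReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            report.n_rows += 1
            fields = line.split("\t")
            if len(fields) < 12:
                logger.warning("skipping malformed BLAST row at line %d", lineno)
                report.n_skipped += 1
                report.skipped_lines.append(lineno)
                continue
            try:
                bits = float(fields[11])
            except ValueError:
                logger.warning("non-numeric bitscore at line %d", lineno)
                report.n_skipped += 1
                report.skipped_lines.append(lineno)
                continue
            key = (fields[0], fields[1])
            if key not in best or bits > best[key]:
                best[key] = bits
            report.n_kept += 1
    edges = [(q, s, b) for (q, s), b in best.items()]
    return edges, report


def parse_profile_scores(path: str) -> list[ProfileHit]:
    """Read a TSV of directional profile scores (query, target, score).

    A header row named ``query``/``target``/``score`` is allowed and skipped.
    Both directions of a pair are preserved as distinct hits.
    """
    hits: list[ProfileHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"profile-score TSV line {lineno}: expected 3 columns, got {len(fields)}"
                )
            if lineno == 1 and fields[0].lower() == "query":
                continue
            try:
                score = float(fields[2])
            except ValueError as exc:
                raise InputError(
                    f"profile-score TSV line {lineno}: non-numeric score {fields[2]!r}"
                ) from exc
            hits.append(ProfileHit(query=fields[0], target=fields[1], score=score))
    return hits
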