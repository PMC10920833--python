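"""Pairwise backbone similarity score between translated repeat units.

A non-zero score requires full token identity at both the −1 (reducing-end
donor) and +1 (acceptor) subsites, which yields the minimum score of 2.  The
comparison then extends outward in rounds k = 2, 3, …, testing subsite +k
before −k; each identical token pair adds one point and marks the underlying
backbone residues of both glycans as used.  The whole comparison stops at
the first token mismatch, the first out-of-range subsite, or the first
attempt to re-use an already-counted backbone position in either glycan.
"""

from __future__ import annotations

import numpy as np

from ..errors import UnsupportedInputError
from .model import BackboneString


def similarity_score(a: BackboneString, b: BackboneString) -> int:
    """Backbone similarity score; symmetric, in {0} ∪ {2, …, min(n_a, n_b)}."""
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise UnsupportedInputError("similarity is undefined for backbones shorter than 2")
    if a.minus(1).token != b.minus(1).token or a.plus(1).token != b.plus(1).token:
        return 0
    # used positions tracked as 0-based reducing-end indices, per glycan
    used_a = {0, n_a - 1}
    used_b = {0, n_b - 1}
    score = 2
    for k in range(2, max(n_a, n_b) + 1):
        for side in ("+", "-"):
            if k > n_a or k > n_b:
                return score
            idx_a = n_a - k if side == "+" else k - 1
            idx_b = n_b - k if side == "+" else k - 1
            if idx_a in used_a or idx_b in used_b:
                return score
            if a.units[idx_a].token != b.units[idx_b].token:
                return score
            used_a.add(idx_a)
            used_b.add(idx_b)
            score += 1
    return score


def score_matrix(strings: list[BackboneString], ids: list[str] | None = None) -> np.ndarray:
    """Symmetric integer matrix of pairwise scores; diagonal holds self-scores."""
    n = len(strings)
    if ids is None:
        ids = [s.id or f"g{i}" for i, s in enumerate(strings)]
    matrix = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            try:
                value = similarity_score(strings[i], strings[j])
            except UnsupportedInputError as exc:
                raise UnsupportedInputError(
                    f"cannot score pair ({ids[i]}, {ids[j]}): {exc}"
                ) from exc
            matrix[i, j] = matrix[j, i] = value
    return matrix
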