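"""Intra- vs inter-family summaries of a glycan score matrix."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InputError


@dataclass
class FamilyScoreSummary:
    """Off-diagonal score means stratified by family labels.

    ``intra_means`` maps family → mean score over within-family pairs (absent,
    not zero, for single-member families).  ``inter_mean`` is the global mean
    over cross-family pairs; ``None`` when every label is identical (flagged
    via ``inter_empty``).
    """

    intra_means: dict[str, float | None] = field(default_factory=dict)
    intra_counts: dict[str, int] = field(default_factory=dict)
    inter_mean: float | None = None
    inter_count: int = 0
    inter_empty: bool = False


def intra_inter_summary(matrix: np.ndarray, labels: list[str]) -> FamilyScoreSummary:
    """Summarize a symmetric score matrix against family labels.

    Means use unordered off-diagonal pairs only; the diagonal (self-scores)
    never contributes.
    """
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise InputError("score matrix must be square")
    if len(labels) != n:
        raise InputError(f"{len(labels)} labels do not match a {n}x{n} matrix")
    summary = FamilyScoreSummary()
    inter_values: list[float] = []
    per_family: dict[str, list[float]] = {lab: [] for lab in labels}
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                per_family[labels[i]].append(float(matrix[i, j]))
            else:
                inter_values.append(float(matrix[i, j]))
    for family, values in per_family.items():
        summary.intra_counts[family] = len(values)
        summary.intra_means[family] = float(np.mean(values)) if values else None
    summary.inter_count = len(inter_values)
    if inter_values:
        summary.inter_mean = float(np.mean(inter_values))
    else:
        summary.inter_empty = True
    return summary
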