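"""Pairwise global alignment, percent identity, and paralog assignment.

A deliberately small Needleman–Wunsch implementation with linear gap scoring
and a fixed tie-break (diagonal, then up), so alignments — and therefore
identity values — are deterministic. Identity is computed over alignment
columns excluding terminal gaps, the convention under which a perfect prefix
match scores 100%. Used to assign a query sequence to its nearest labelled
reference (e.g. deciding whether a plastidial desaturase is the FAD7 or FAD8
paralog).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Scores:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float


def global_align(a: str, b: str, scores: Scores = Scores()) -> Alignment:
    """Optimal global alignment under linear gap scores.

    Ties broken deterministically: diagonal first, then up (gap in ``b``),
    then left.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    dp = np.empty((n + 1, m + 1))
    dp[0, :] = np.arange(m + 1) * scores.gap
    dp[:, 0] = np.arange(n + 1) * scores.gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = scores.match if a[i - 1] == b[j - 1] else scores.mismatch
            dp[i, j] = max(dp[i - 1, j - 1] + sub, dp[i - 1, j] + scores.gap,
                           dp[i, j - 1] + scores.gap)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = scores.match if a[i - 1] == b[j - 1] else scores.mismatch
            if dp[i, j] == dp[i - 1, j - 1] + sub:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and dp[i, j] == dp[i - 1, j] + scores.gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(dp[n, m]))


def _core_columns(aln: Alignment) -> tuple[int, int]:
    """[start, end) column range after stripping terminal gap runs of either row."""
    cols = len(aln.aligned_a)
    start = 0
    while start < cols and (aln.aligned_a[start] == "-" or aln.aligned_b[start] == "-"):
        start += 1
    end = cols
    while end > start and (aln.aligned_a[end - 1] == "-" or aln.aligned_b[end - 1] == "-"):
        end -= 1
    return start, end


def percent_identity(a: str, b: str, scores: Scores = Scores()) -> float:
    """100 x matches / alignment columns, terminal-gap columns excluded."""
    aln = global_align(a, b, scores)
    start, end = _core_columns(aln)
    if end <= start:
        return 0.0
    matches = sum(
        1 for x, y in zip(aln.aligned_a[start:end], aln.aligned_b[start:end]) if x == y
    )
    return 100.0 * matches / (end - start)


def identity_matrix(
    sequences: Mapping[str, str], scores: Scores = Scores()
) -> pd.DataFrame:
    """Symmetric percent-identity matrix over named sequences (diagonal = 100)."""
    ids = list(sequences)
    mat = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            pid = percent_identity(sequences[x], sequences[y], scores)
            mat.loc[x, y] = mat.loc[y, x] = pid
    return mat


AMBIGUITY_MARGIN = 0.05  # percentage points


def classify_paralog(
    query: str, labeled_references: Mapping[str, str], scores: Scores = Scores()
) -> tuple[str, float]:
    """Assign ``query`` to the reference label with highest percent identity.

    Returns (label, margin) where margin = best - second-best identity; a
    margin below 0.05 points yields the label ``"ambiguous"``.
    """
    if len(labeled_references) < 2:
        raise ValueError("need at least 2 labelled references")
    idents = sorted(
        ((percent_identity(query, seq, scores), label)
         for label, seq in labeled_references.items()),
        key=lambda t: (-t[0], t[1]),
    )
    margin = idents[0][0] - idents[1][0]
    label = idents[0][1] if margin >= AMBIGUITY_MARGIN else "ambiguous"
    return label, margin
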