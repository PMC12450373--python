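"""MSA quality metrics: column occupancy and mean mutual information.

Occupancy of a column is the fraction of rows with a residue (non-gap) at
that position.  Mutual information between two columns,
MI = sum_{a,b} p(a,b) * log2[p(a,b) / (p(a) p(b))] in bits, is estimated
from empirical frequencies over the rows that are non-gapped at both
columns (no pseudocounts).  The mean MI averages over all unordered column
pairs, optionally truncated deterministically for very wide alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .data import GAP, AlignedFamily


@dataclass
class MSAQualityReport:
    mean_mutual_information: float | None
    mean_occupancy: float
    per_column_occupancy: list[float] = field(default_factory=list)
    column_pairs_evaluated: int = 0

    def summary(self) -> dict:
        return {
            "mean_mutual_information_bits": self.mean_mutual_information,
            "mean_occupancy": self.mean_occupancy,
            "column_pairs_evaluated": self.column_pairs_evaluated,
        }


def column_occupancy(family: AlignedFamily) -> tuple[list[float], float]:
    """Per-column non-gap fraction and its mean over all columns."""
    rows = [family.rows[r] for r in family.row_ids]
    n = len(rows)
    per_col = [
        sum(1 for row in rows if row[c] != GAP) / n for c in range(family.width)
    ]
    return per_col, float(np.mean(per_col))


def _pair_mi(col_a: list[str], col_b: list[str], min_pair_rows: int) -> float | None:
    pairs = [
        (a, b) for a, b in zip(col_a, col_b) if a != GAP and b != GAP
    ]
    if len(pairs) < min_pair_rows:
        return None
    n = len(pairs)
    joint: dict[tuple[str, str], int] = {}
    pa: dict[str, int] = {}
    pb: dict[str, int] = {}
    for a, b in pairs:
        joint[(a, b)] = joint.get((a, b), 0) + 1
        pa[a] = pa.get(a, 0) + 1
        pb[b] = pb.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * np.log2(p_ab * n * n / (pa[a] * pb[b]))
    return float(mi)


def pairwise_column_mi(
    family: AlignedFamily, c1: int, c2: int, min_pair_rows: int = 2
) -> float | None:
    """MI in bits between two alignment columns (None if too few shared rows)."""
    rows = [family.rows[r] for r in family.row_ids]
    return _pair_mi([r[c1] for r in rows], [r[c2] for r in rows], min_pair_rows)


def mean_mutual_information(
    family: AlignedFamily,
    min_pair_rows: int = 2,
    max_column_pairs: int | None = None,
) -> tuple[float | None, int]:
    """Mean MI over unordered column pairs; (None, 0) when all pairs skip.

    Pairs iterate in ascending (c1, c2) order and truncate deterministically
    at ``max_column_pairs``.
    """
    if family.width < 2:
        raise ValueError("mutual information needs at least two columns")
    rows = [family.rows[r] for r in family.row_ids]
    columns = [[r[c] for r in rows] for c in range(family.width)]
    total, evaluated, seen = 0.0, 0, 0
    for c1, c2 in combinations(range(family.width), 2):
        if max_column_pairs is not None and seen >= max_column_pairs:
            break
        seen += 1
        mi = _pair_mi(columns[c1], columns[c2], min_pair_rows)
        if mi is None:
            continue
        total += mi
        evaluated += 1
    if evaluated == 0:
        return None, 0
    return total / evaluated, evaluated


def msa_quality(
    family: AlignedFamily,
    min_pair_rows: int = 2,
    max_column_pairs: int | None = None,
) -> MSAQualityReport:
    per_col, mean_occ = column_occupancy(family)
    mean_mi, n_pairs = mean_mutual_information(
        family, min_pair_rows=min_pair_rows, max_column_pairs=max_column_pairs
    )
    return MSAQualityReport(mean_mi, mean_occ, per_col, n_pairs)
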