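"""Conserved-column criteria shared by the detector and the simulator.

A multiple-sequence-alignment column counts as conserved when all three
hold:

(a) the fraction of unknown symbols — ``X`` and the gap ``-`` both count
    as unknown — is strictly below ``max_unknown_frac``;
(b) the number of distinct standard residue types among the non-unknown
    symbols is at most ``max_residue_types``;
(c) the most abundant standard residue covers at least
    ``min_majority_frac`` of the non-unknown symbols.
"""

from __future__ import annotations

from dataclasses import dataclass

from .vocab import STANDARD_RESIDUES, UNKNOWN_RESIDUE

GAP = "-"
_UNKNOWN = {UNKNOWN_RESIDUE, GAP}


@dataclass(frozen=True)
class ConservedColumnCriteria:
    max_unknown_frac: float = 0.05   # strict: fraction must be < this
    max_residue_types: int = 4       # inclusive
    min_majority_frac: float = 0.70  # inclusive

    def __post_init__(self):
        if not 0 < self.max_unknown_frac <= 1 or not 0 < self.min_majority_frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        if self.max_residue_types < 1:
            raise ValueError("max_residue_types must be at least 1")


def column_qualifies(column: list[str], criteria: ConservedColumnCriteria) -> bool:
    """Evaluate the three conservation criteria on one column of symbols."""
    n = len(column)
    unknown = sum(1 for ch in column if ch in _UNKNOWN)
    if unknown / n >= criteria.max_unknown_frac:
        return False
    residues = [ch for ch in column if ch in STANDARD_RESIDUES]
    if not residues:
        return False
    counts: dict[str, int] = {}
    for ch in residues:
        counts[ch] = counts.get(ch, 0) + 1
    if len(counts) > criteria.max_residue_types:
        return False
    return max(counts.values()) / len(residues) >= criteria.min_majority_frac
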