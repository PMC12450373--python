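"""Embedding-based pairwise soft alignment.

Two residue-embedding matrices induce an m x n cosine-similarity matrix.
Candidate matches are the mutual nearest neighbours of that matrix (row
i's best column is j and column j's best row is i, ties broken toward the
smallest index) whose similarity clears a threshold tau.  The soft
alignment is the longest chain of candidates strictly increasing in both
coordinates (a longest-increasing-subsequence dynamic program); its length
— the longest homologous residue path — is the embedding-quality metric.
Alignments are kept only when the path length exceeds ``min_path_length``
and both sequences are shorter than ``max_sequence_length``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SoftAlignConfig:
    similarity_threshold_tau: float = 0.0
    min_path_length: int = 18      # strict: keep paths with length > this
    max_sequence_length: int = 1024  # strict: keep sequences shorter than this


@dataclass(frozen=True)
class SoftAlignment:
    matches: tuple[tuple[int, int], ...]
    sequence_lengths: tuple[int, int]
    pair_ids: tuple[str, str] | None = None

    @property
    def path_length(self) -> int:
        return len(self.matches)

    def __post_init__(self):
        last = (-1, -1)
        for i, j in self.matches:
            if i <= last[0] or j <= last[1]:
                raise ValueError("matches must be strictly increasing in both coordinates")
            last = (i, j)


def residue_similarity_matrix(E1: np.ndarray, E2: np.ndarray) -> np.ndarray:
    """Entry (i, j) = cosine of row i of E1 and row j of E2."""
    E1 = np.asarray(E1, dtype=float)
    E2 = np.asarray(E2, dtype=float)
    if E1.ndim != 2 or E2.ndim != 2 or E1.shape[0] == 0 or E2.shape[0] == 0:
        raise ValueError("both embedding matrices must be nonempty 2-D arrays")
    n1 = np.linalg.norm(E1, axis=1)
    n2 = np.linalg.norm(E2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("zero embedding rows have no defined cosine")
    return (E1 / n1[:, None]) @ (E2 / n2[:, None]).T


def mutual_nearest_neighbors(
    similarity: np.ndarray, tau: float = 0.0
) -> list[tuple[int, int]]:
    """Candidate matches: mutual argmax pairs with similarity >= tau.

    ``np.argmax`` resolves ties toward the smallest index, matching the
    declared tie-break.
    """
    row_best = similarity.argmax(axis=1)
    col_best = similarity.argmax(axis=0)
    return [
        (i, int(j))
        for i, j in enumerate(row_best)
        if col_best[j] == i and similarity[i, j] >= tau
    ]


def longest_monotone_chain(
    candidates: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Maximum-cardinality subset strictly increasing in both coordinates;
    among equal-length chains, the lexicographically smallest match list."""
    cands = sorted(candidates)
    n = len(cands)
    if n == 0:
        return []
    length = [1] * n  # longest chain starting at k
    for k in range(n - 1, -1, -1):
        for l in range(k + 1, n):
            if cands[l][0] > cands[k][0] and cands[l][1] > cands[k][1]:
                length[k] = max(length[k], 1 + length[l])
    best = max(length)
    chain: list[tuple[int, int]] = []
    need, prev = best, (-1, -1)
    for k in range(n):
        if (
            length[k] == need
            and cands[k][0] > prev[0]
            and cands[k][1] > prev[1]
        ):
            chain.append(cands[k])
            prev = cands[k]
            need -= 1
            if need == 0:
                break
    return chain


def soft_align(
    E1: np.ndarray,
    E2: np.ndarray,
    config: SoftAlignConfig = SoftAlignConfig(),
    pair_ids: tuple[str, str] | None = None,
    match_rule=mutual_nearest_neighbors,
) -> SoftAlignment:
    """Soft-align two residue embedding matrices.

    ``match_rule`` is pluggable: any callable mapping (similarity matrix,
    tau) to candidate (i, j) pairs can replace the mutual-nearest-neighbour
    default.
    """
    sim = residue_similarity_matrix(E1, E2)
    candidates = match_rule(sim, config.similarity_threshold_tau)
    chain = longest_monotone_chain(candidates)
    return SoftAlignment(tuple(chain), (sim.shape[0], sim.shape[1]), pair_ids)


def filter_alignments(
    alignments: list[SoftAlignment], config: SoftAlignConfig = SoftAlignConfig()
) -> list[SoftAlignment]:
    """Keep alignments with path length > min and both sequences < max length."""
    return [
        a
        for a in alignments
        if a.path_length > config.min_path_length
        and a.sequence_lengths[0] < config.max_sequence_length
        and a.sequence_lengths[1] < config.max_sequence_length
    ]


def align_pairs(
    pairs: list[tuple[str, str]],
    residue_embeddings: dict[str, np.ndarray],
    config: SoftAlignConfig = SoftAlignConfig(),
) -> list[SoftAlignment]:
    """Soft-align each id pair, skipping over-length sequences upstream."""
    out = []
    for a, b in pairs:
        Ea, Eb = residue_embeddings[a], residue_embeddings[b]
        if (
            len(Ea) >= config.max_sequence_length
            or len(Eb) >= config.max_sequence_length
        ):
            continue
        out.append(soft_align(Ea, Eb, config, pair_ids=(a, b)))
    return out
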