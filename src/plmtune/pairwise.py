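"""Pairwise embedding-similarity benchmarks.

Three comparisons probe embedding quality:

1. pooled within-group similarity — cosine between the mean-pooled
   embeddings of every unordered pair of sequences inside each orthologous
   group;
2. conserved-site similarity — cosine between residue embeddings drawn
   from conserved alignment columns (a column is conserved when it has
   fewer than 5% unknown symbols, at most four residue types, and a
   majority residue covering at least 70% of the non-unknown symbols);
3. random-site similarity — cosine between residue embeddings at
   non-homologous, well-separated positions (|p_i - p_j| > 20 by default)
   outside conserved columns.

A well-calibrated encoder scores conserved sites above random sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .conservation import ConservedColumnCriteria, column_qualifies
from .data import AlignedFamily, OrthologGroupSet
from .embeddings import cosine

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RandomSiteConfig:
    min_separation: int = 20
    exclude_conserved: bool = True
    pairs_target: int = 10_000
    retry_cap: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.min_separation < 0:
            raise ValueError("min_separation must be nonnegative")


@dataclass
class PairwiseSimilarityReport:
    values: list[float]
    provenance: list[tuple] = field(default_factory=list)
    source_counts: dict[str, int] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.values)

    @property
    def median(self) -> float:
        if not self.values:
            raise ValueError("report holds no similarity values")
        return float(np.median(self.values))

    def summary(self) -> dict:
        return {
            "count": self.count,
            "median": self.median if self.values else None,
            "mean": float(np.mean(self.values)) if self.values else None,
            "source_counts": self.source_counts,
        }


def enumerate_within_group_pairs(data: OrthologGroupSet) -> list[tuple[str, str]]:
    """All unordered within-group pairs, each exactly once, in deterministic
    order (sorted group id, then sorted id pair); total = sum_g C(n_g, 2)."""
    pairs: list[tuple[str, str]] = []
    for gid in data.group_ids:
        pairs.extend(combinations(data.members(gid), 2))
    return pairs


def pooled_pairwise_similarity(
    pairs: list[tuple[str, str]], pooled: dict[str, np.ndarray]
) -> PairwiseSimilarityReport:
    values, prov = [], []
    for a, b in pairs:
        if a not in pooled or b not in pooled:
            missing = a if a not in pooled else b
            raise KeyError(f"no pooled embedding for sequence {missing!r}")
        values.append(cosine(pooled[a], pooled[b]))
        prov.append((a, b))
    return PairwiseSimilarityReport(values, prov, {"pooled": len(values)})


def detect_conserved_columns(
    family: AlignedFamily, criteria: ConservedColumnCriteria = ConservedColumnCriteria()
) -> list[int]:
    """0-based indices of alignment columns meeting all three criteria.

    Gaps count as unknown alongside 'X'; residue-type and majority counts
    are taken over the non-unknown symbols only.
    """
    rows = [family.rows[r] for r in family.row_ids]
    return [
        c
        for c in range(family.width)
        if column_qualifies([row[c] for row in rows], criteria)
    ]


def conserved_site_similarities(
    families: list[AlignedFamily],
    residue_embeddings: dict[str, np.ndarray],
    criteria: ConservedColumnCriteria = ConservedColumnCriteria(),
    max_comparisons: int = 1_000_000,
    conserved_columns: dict[str, list[int]] | None = None,
) -> PairwiseSimilarityReport:
    """Cosine similarities of residue embeddings within conserved columns.

    Iterates families (sorted by group id), conserved columns (ascending),
    and unordered row pairs (sorted ids); truncates deterministically at
    ``max_comparisons``.
    """
    values, prov = [], []
    source_counts: dict[str, int] = {}
    for family in sorted(families, key=lambda f: f.group_id):
        cols = (
            conserved_columns[family.group_id]
            if conserved_columns is not None
            else detect_conserved_columns(family, criteria)
        )
        maps = {rid: family.column_map(rid) for rid in family.row_ids}
        n_before = len(values)
        for c in cols:
            present = [rid for rid in family.row_ids if maps[rid][c] is not None]
            for a, b in combinations(present, 2):
                ia, ib = maps[a][c], maps[b][c]
                values.append(cosine(residue_embeddings[a][ia], residue_embeddings[b][ib]))
                prov.append((family.group_id, c, a, b))
                if len(values) >= max_comparisons:
                    source_counts[family.group_id] = len(values) - n_before
                    return PairwiseSimilarityReport(values, prov, source_counts)
        source_counts[family.group_id] = len(values) - n_before
    return PairwiseSimilarityReport(values, prov, source_counts)


def random_site_similarities(
    families: list[AlignedFamily],
    residue_embeddings: dict[str, np.ndarray],
    config: RandomSiteConfig = RandomSiteConfig(),
    conserved_columns: dict[str, list[int]] | None = None,
) -> PairwiseSimilarityReport:
    """Cosine similarities at separation-constrained random residue pairs.

    Sweeps families and unordered row pairs in deterministic order; per
    sweep each row pair contributes one accepted draw (rejection sampling
    with a per-draw retry cap).  Positions are 0-based ungapped residue
    indices; accepted draws satisfy p_i != p_j, |p_i - p_j| >
    ``min_separation`` and, when ``exclude_conserved``, fall outside the
    residue image of any conserved column for their row.
    """
    rng = np.random.default_rng(config.seed)
    values, prov = [], []
    source_counts: dict[str, int] = {}

    work = []
    for family in sorted(families, key=lambda f: f.group_id):
        lengths = {rid: len(family.sequence_of(rid)) for rid in family.row_ids}
        if max(lengths.values()) < config.min_separation + 2:
            logger.warning(
                "family %s skipped: no position pair can satisfy separation > %d",
                family.group_id,
                config.min_separation,
            )
            continue
        excluded: dict[str, set[int]] = {rid: set() for rid in family.row_ids}
        if config.exclude_conserved:
            cols = (
                conserved_columns[family.group_id]
                if conserved_columns is not None
                else detect_conserved_columns(family)
            )
            for rid in family.row_ids:
                cmap = family.column_map(rid)
                excluded[rid] = {cmap[c] for c in cols if cmap[c] is not None}
        pairs = list(combinations(family.row_ids, 2))
        work.append((family.group_id, lengths, excluded, pairs))

    if not work:
        return PairwiseSimilarityReport(values, prov, source_counts)

    progress = True
    while len(values) < config.pairs_target and progress:
        progress = False
        for gid, lengths, excluded, pairs in work:
            for a, b in pairs:
                if len(values) >= config.pairs_target:
                    return PairwiseSimilarityReport(values, prov, source_counts)
                for _ in range(config.retry_cap):
                    pi = int(rng.integers(lengths[a]))
                    pj = int(rng.integers(lengths[b]))
                    if pi == pj or abs(pi - pj) <= config.min_separation:
                        continue
                    if pi in excluded[a] or pj in excluded[b]:
                        continue
                    values.append(
                        cosine(residue_embeddings[a][pi], residue_embeddings[b][pj])
                    )
                    prov.append((gid, a, pi, b, pj))
                    source_counts[gid] = source_counts.get(gid, 0) + 1
                    progress = True
                    break
    return PairwiseSimilarityReport(values, prov, source_counts)
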