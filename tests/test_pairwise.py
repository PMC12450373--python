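"""Within-group pair enumeration, conserved-column detection, and the
conserved-site / random-site similarity benchmarks."""

from itertools import combinations

import numpy as np
import pytest

from plmtune import (
    AlignedFamily,
    ConservedColumnCriteria,
    OrthologGroupSet,
    ProteinRecord,
    RandomSiteConfig,
    conserved_site_similarities,
    detect_conserved_columns,
    enumerate_within_group_pairs,
    pooled_pairwise_similarity,
    random_site_similarities,
)


def _group_set(sizes: dict[str, int]) -> OrthologGroupSet:
    return OrthologGroupSet([
        ProteinRecord(f"{g}_{i:03d}", "ACDEFGHIKLMNPQRSTVWYA", g)
        for g, n in sizes.items()
        for i in range(n)
    ])


# -- pair enumeration -------------------------------------------------------

def test_673_groups_of_10_give_30285_pairs():
    data = _group_set({f"VOG{i:04d}": 10 for i in range(673)})
    pairs = enumerate_within_group_pairs(data)
    assert len(pairs) == 30285


def test_pair_enumeration_matches_brute_force():
    data = _group_set({"A": 3, "B": 5, "C": 7, "D": 2, "E": 1})
    pairs = enumerate_within_group_pairs(data)
    assert len(pairs) == 3 + 10 + 21 + 1 + 0
    brute = set()
    ids = [r.id for r in data.records]
    for i in ids:
        for j in ids:
            if i < j and data[i].group_id == data[j].group_id:
                brute.add((i, j))
    assert set(map(tuple, pairs)) == brute
    # deterministic order: sorted group, then sorted id pair
    assert pairs == sorted(pairs)


# -- pooled similarity ------------------------------------------------------

def test_pooled_similarity_identical_embeddings():
    data = _group_set({"A": 4})
    pooled = {r.id: np.array([1.0, 2.0, 3.0]) for r in data.records}
    report = pooled_pairwise_similarity(enumerate_within_group_pairs(data), pooled)
    assert report.count == 6
    assert report.median == pytest.approx(1.0)


def test_pooled_similarity_only_scores_within_group():
    data = _group_set({"A": 3, "B": 3})
    pooled = {}
    for r in data.records:  # orthogonal across groups, identical within
        pooled[r.id] = np.array([1.0, 0.0]) if r.group_id == "A" else np.array([0.0, 1.0])
    report = pooled_pairwise_similarity(enumerate_within_group_pairs(data), pooled)
    assert report.median == pytest.approx(1.0)


def test_pooled_similarity_median_matches_sort_oracle():
    rng = np.random.default_rng(2)
    data = _group_set({"A": 30})
    pooled = {r.id: rng.normal(size=8) for r in data.records}
    report = pooled_pairwise_similarity(enumerate_within_group_pairs(data), pooled)
    values = sorted(report.values)
    n = len(values)
    oracle = (values[n // 2] if n % 2 else (values[n // 2 - 1] + values[n // 2]) / 2)
    assert report.median == pytest.approx(oracle, abs=1e-12)


def test_missing_embedding_raises_keyed_error():
    data = _group_set({"A": 2})
    with pytest.raises(KeyError, match="A_001"):
        pooled_pairwise_similarity(
            enumerate_within_group_pairs(data), {"A_000": np.ones(3)}
        )


# -- conserved columns ------------------------------------------------------

def _family_from_columns(columns: list[str]) -> AlignedFamily:
    n_rows = len(columns[0])
    rows = {
        f"r{i:02d}": "".join(col[i] for col in columns) for i in range(n_rows)
    }
    return AlignedFamily("FAM", rows)


def test_conserved_column_hand_cases():
    qualifying = "A" * 16 + "G" * 2 + "V" * 2      # 3 types, 80% majority
    gapped = "A" * 19 + "-"                        # 5% unknown is not < 5%
    uniform = "W" * 20
    five_types = "A" * 16 + "GVLI"                 # 5 types
    weak_majority = "A" * 13 + "G" * 4 + "V" * 3   # 65% < 70%
    fam = _family_from_columns([qualifying, gapped, uniform, five_types, weak_majority])
    assert detect_conserved_columns(fam) == [0, 2]


def test_conserved_detection_row_order_invariant():
    fam = _family_from_columns(["A" * 16 + "G" * 2 + "V" * 2, "ACDEFGHIKLMNPQRSTVWY"])
    reordered = AlignedFamily("FAM", dict(reversed(list(fam.rows.items()))))
    assert detect_conserved_columns(fam) == detect_conserved_columns(reordered)


def test_all_gap_row_only_affects_unknown_fraction():
    # 39 A + 1 gap: 2.5% unknown < 5% -> still conserved
    fam = _family_from_columns(["A" * 39 + "-"])
    assert detect_conserved_columns(fam) == [0]
    # 19 A + 1 gap: 5% unknown -> fails
    fam2 = _family_from_columns(["A" * 19 + "-"])
    assert detect_conserved_columns(fam2) == []


def test_x_counts_as_unknown():
    fam = _family_from_columns(["A" * 19 + "X"])
    assert detect_conserved_columns(fam) == []


def test_custom_criteria():
    col = "A" * 12 + "G" * 8  # 60% majority
    fam = _family_from_columns([col])
    assert detect_conserved_columns(fam) == []
    relaxed = ConservedColumnCriteria(min_majority_frac=0.5)
    assert detect_conserved_columns(fam, relaxed) == [0]


# -- conserved-site similarities --------------------------------------------

@pytest.fixture()
def conserved_fixture():
    # 4 rows, 3 columns; column 1 conserved, column 0 has one gap
    fam = AlignedFamily("FAM", {
        "r0": "AWD", "r1": "CWE", "r2": "-WF", "r3": "GWH",
    })
    rng = np.random.default_rng(0)
    emb = {rid: rng.normal(size=(len(fam.sequence_of(rid)), 6)) for rid in fam.row_ids}
    return fam, emb


def test_conserved_site_pair_count(conserved_fixture):
    fam, emb = conserved_fixture
    report = conserved_site_similarities([fam], emb)
    assert detect_conserved_columns(fam) == [1]
    assert report.count == 6  # C(4,2) over the 4 non-gapped rows


def test_conserved_site_truncation_order(conserved_fixture):
    fam, emb = conserved_fixture
    full = conserved_site_similarities([fam], emb)
    cut = conserved_site_similarities([fam], emb, max_comparisons=5)
    assert cut.count == 5
    assert cut.values == full.values[:5]
    assert cut.provenance == full.provenance[:5]


def test_conserved_site_uses_column_maps(conserved_fixture):
    fam, emb = conserved_fixture
    report = conserved_site_similarities([fam], emb)
    # r2's row is "-WF" so its W is residue 0, everyone else's is residue 1
    from plmtune import cosine
    expected = cosine(emb["r0"][1], emb["r2"][0])
    pair_idx = report.provenance.index(("FAM", 1, "r0", "r2"))
    assert report.values[pair_idx] == pytest.approx(expected)


# -- random sites -----------------------------------------------------------

def _long_family(n_rows=4, length=60, seed=1):
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    rows = {
        f"r{i}": "".join(rng.choice(alphabet, size=length)) for i in range(n_rows)
    }
    fam = AlignedFamily("FAM", rows)
    emb = {rid: rng.normal(size=(length, 5)) for rid in rows}
    return fam, emb


def test_random_site_draws_satisfy_all_constraints():
    fam, emb = _long_family()
    conserved = {"FAM": [0, 1, 2]}
    cfg = RandomSiteConfig(min_separation=20, pairs_target=10_000, seed=3)
    report = random_site_similarities([fam], emb, cfg, conserved_columns=conserved)
    assert report.count == 10_000
    for gid, a, pi, b, pj in report.provenance:
        assert a != b
        assert pi != pj and abs(pi - pj) > 20
        assert pi not in (0, 1, 2) and pj not in (0, 1, 2)


def test_random_site_infeasible_family_skipped(caplog):
    fam, emb = _long_family(length=21)
    cfg = RandomSiteConfig(min_separation=20, pairs_target=10, seed=0)
    with caplog.at_level("WARNING"):
        report = random_site_similarities([fam], emb, cfg)
    assert report.count == 0
    assert any("skipped" in r.message for r in caplog.records)


def test_random_site_values_are_seeded():
    fam, emb = _long_family()
    cfg = RandomSiteConfig(pairs_target=500, seed=7)
    r1 = random_site_similarities([fam], emb, cfg)
    r2 = random_site_similarities([fam], emb, cfg)
    assert r1.values == r2.values
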