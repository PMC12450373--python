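"""Dataset I/O, the group-size filter, stratified splitting, and the
synthetic ortholog-family generator's ground-truth guarantees."""

import numpy as np
import pytest

from plmtune import (
    AlignedFamily,
    OrthologGroupSet,
    ProteinRecord,
    SyntheticFamilyConfig,
    detect_conserved_columns,
    filter_groups,
    generate_families,
    read_alignment,
    read_fasta,
    sample_triplets,
    stratified_split,
    write_alignment,
    write_fasta,
)
from plmtune.data import FastaParseError


def _make_set(sizes: dict[str, int]) -> OrthologGroupSet:
    records = [
        ProteinRecord(f"{g}_{i}", "ACDEFGHIKLMNPQRSTVWY", g)
        for g, n in sizes.items()
        for i in range(n)
    ]
    return OrthologGroupSet(records)


# -- FASTA ------------------------------------------------------------------

def test_fasta_round_trip_identity(tmp_path, small_families):
    data, _ = small_families
    path = tmp_path / "seqs.fasta"
    write_fasta(data.records, path)
    back = read_fasta(path)
    assert [(r.id, r.group_id, r.sequence) for r in back] == [
        (r.id, r.group_id, r.sequence) for r in data.records
    ]


def test_fasta_header_and_sidecar_parsing(tmp_path):
    path = tmp_path / "mixed.fasta"
    path.write_text(">s1|VOG1\nACDE\n>s2|VOG1\nWYWY\n>s3|VOG2\nMMMM\n")
    records = read_fasta(path)
    assert len(records) == 3
    assert {r.group_id for r in records} == {"VOG1", "VOG2"}

    bare = tmp_path / "bare.fasta"
    bare.write_text(">s1\nACDE\n")
    with pytest.raises(FastaParseError, match="s1"):
        read_fasta(bare)
    sidecar = tmp_path / "groups.tsv"
    sidecar.write_text("s1\tVOG9\n")
    assert read_fasta(bare, group_tsv=sidecar)[0].group_id == "VOG9"


def test_fasta_duplicate_id_rejected(tmp_path):
    path = tmp_path / "dup.fasta"
    path.write_text(">s1|G\nACDE\n>s1|G\nACDE\n")
    with pytest.raises(FastaParseError, match="duplicate"):
        read_fasta(path)


def test_alignment_round_trip(tmp_path, small_families):
    _, families = small_families
    fam = families[0]
    path = tmp_path / f"{fam.group_id}.afa"
    write_alignment(fam, path)
    back = read_alignment(path)
    assert back.rows == fam.rows


# -- filter -----------------------------------------------------------------

def test_filter_is_strictly_greater_than():
    data = _make_set({"G10": 10, "G11": 11, "G5": 5})
    kept = filter_groups(data, min_members_exclusive=10)
    assert kept.group_ids == ["G11"]
    assert len(kept) == 11


def test_filter_identity_when_all_large():
    data = _make_set({"A": 11, "B": 12})
    assert len(filter_groups(data)) == 23


def test_filter_kept_count_matches_recount():
    rng = np.random.default_rng(0)
    sizes = {f"G{i}": int(rng.integers(1, 30)) for i in range(40)}
    kept = filter_groups(_make_set(sizes), 10)
    assert len(kept) == sum(n for n in sizes.values() if n > 10)


# -- split ------------------------------------------------------------------

def test_split_counts_follow_max_one_round_rule():
    split20 = stratified_split(_make_set({"G": 20}), 0.1, seed=0)
    assert len(split20.test_ids) == 2 and len(split20.train_ids) == 18
    split10 = stratified_split(_make_set({"G": 10}), 0.1, seed=0)
    assert len(split10.test_ids) == 1 and len(split10.train_ids) == 9
    # max(1, .) kicks in below 1/(2*fraction)
    split3 = stratified_split(_make_set({"G": 3}), 0.1, seed=0)
    assert len(split3.test_ids) == 1


def test_split_is_disjoint_cover_with_per_group_counts():
    rng = np.random.default_rng(1)
    sizes = {f"G{i}": int(rng.integers(2, 40)) for i in range(50)}
    data = _make_set(sizes)
    split = stratified_split(data, 0.1, seed=3)
    all_ids = {r.id for r in data.records}
    assert split.train_ids | split.test_ids == all_ids
    assert not (split.train_ids & split.test_ids)
    for g, n in sizes.items():
        in_test = sum(1 for sid in split.test_ids if sid.startswith(f"{g}_"))
        assert in_test == max(1, int(np.floor(0.1 * n + 0.5)))  # half-up ties


def test_split_rejects_singleton_groups():
    with pytest.raises(ValueError):
        stratified_split(_make_set({"G": 1, "H": 5}), 0.1, seed=0)


def test_filter_plus_split_conserves_sequences(small_families):
    data, _ = small_families
    kept = filter_groups(data, min_members_exclusive=5)
    dropped = len(data) - len(kept)
    split = stratified_split(kept, 0.1, seed=0)
    assert dropped + len(split.train_ids) + len(split.test_ids) == len(data)


# -- generator --------------------------------------------------------------

def test_zero_rates_reproduce_ancestor_exactly():
    data, families = generate_families(SyntheticFamilyConfig(
        n_groups=2, members_per_group=5, ancestor_length=40,
        conserved_blocks=((5, 8),), substitution_rate=0.0, seed=4,
    ))
    for fam in families:
        seqs = {fam.sequence_of(r) for r in fam.row_ids}
        assert len(seqs) == 1  # all members identical to the ancestor


def test_generator_is_deterministic(small_families):
    data, families = small_families
    data2, families2 = generate_families(SyntheticFamilyConfig(
        n_groups=10, members_per_group=8, ancestor_length=60,
        conserved_blocks=((10, 10), (40, 8)), substitution_rate=0.3, seed=11,
    ))
    assert [r.sequence for r in data.records] == [r.sequence for r in data2.records]
    assert all(f1.rows == f2.rows for f1, f2 in zip(families, families2))


def test_detector_recovers_exactly_the_configured_blocks(small_families):
    _, families = small_families
    for fam in families:
        assert set(detect_conserved_columns(fam)) == set(fam.truth_conserved_columns)


@pytest.mark.parametrize("indel_rate", [0.0, 0.05])
def test_alignment_consistency_and_truth_with_indels(indel_rate):
    data, families = generate_families(SyntheticFamilyConfig(
        n_groups=3, members_per_group=10, ancestor_length=50,
        conserved_blocks=((5, 8), (30, 6)), substitution_rate=0.3,
        indel_rate=indel_rate, seed=6,
    ))
    for fam in families:
        widths = {len(row) for row in fam.rows.values()}
        assert len(widths) == 1
        for rid in fam.row_ids:
            assert fam.sequence_of(rid) == data[rid].sequence
            cmap = fam.column_map(rid)
            residues = [i for i in cmap if i is not None]
            assert residues == list(range(len(residues)))
        assert set(detect_conserved_columns(fam)) == set(fam.truth_conserved_columns)


def test_shared_motifs_are_identical_across_families():
    _, families = generate_families(SyntheticFamilyConfig(
        n_groups=4, members_per_group=3, ancestor_length=60,
        conserved_blocks=((10, 10),), shared_motif_seed=5, seed=0,
    ))
    block_strings = {
        fam.rows[fam.row_ids[0]][10:20] for fam in families
    }
    assert len(block_strings) == 1


# -- triplets ---------------------------------------------------------------

def test_triplets_satisfy_group_constraints(small_families):
    data, _ = small_families
    for a, p, n in sample_triplets(data, 1000, seed=0):
        assert a != p
        assert data[a].group_id == data[p].group_id
        assert data[n].group_id != data[a].group_id


def test_triplet_sampler_reaches_full_support():
    data = _make_set({"A": 2, "B": 2})
    seen = set(sample_triplets(data, 10_000, seed=1))
    # 4 anchors x 1 positive x 2 negatives
    assert len(seen) == 8


def test_triplets_are_seeded(small_families):
    data, _ = small_families
    assert sample_triplets(data, 50, seed=9) == sample_triplets(data, 50, seed=9)


def test_single_group_sampling_fails():
    with pytest.raises(ValueError):
        sample_triplets(_make_set({"A": 5}), 3, seed=0)
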