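"""Ortholog-group datasets: I/O, filtering, splitting, and synthesis.

Sequences are plain FASTA; group membership is carried either in the header
(``>seqid|groupid``) or in a sidecar TSV of ``(sequence id, group id)``
rows.  Multiple sequence alignments are aligned FASTA with ``-`` as the gap
character (``.`` is normalised to ``-`` on read).

The synthetic family generator emulates orthologous protein groups: each
group descends from a random ancestor, members keep conserved motif blocks
(optionally with a small flip rate) and diverge elsewhere by point
substitution and optional indels.  Because every member is simulated from
the ancestor, the true alignment and the true conserved columns are known
by construction, which is what the benchmark suite tests against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .vocab import STANDARD_RESIDUES, UNKNOWN_RESIDUE

GAP = "-"
_ALLOWED = set(STANDARD_RESIDUES + UNKNOWN_RESIDUE)


class FastaParseError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    group_id: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-residue symbols {sorted(bad)}"
            )


class OrthologGroupSet:
    """Sequences partitioned into labelled orthologous groups."""

    def __init__(self, records: list[ProteinRecord]):
        self.records = list(records)
        self._by_id: dict[str, ProteinRecord] = {}
        self.groups: dict[str, list[str]] = {}
        for rec in self.records:
            if rec.id in self._by_id:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            self._by_id[rec.id] = rec
            self.groups.setdefault(rec.group_id, []).append(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> ProteinRecord:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    @property
    def group_ids(self) -> list[str]:
        return sorted(self.groups)

    def members(self, group_id: str) -> list[str]:
        return sorted(self.groups[group_id])

    def subset(self, seq_ids) -> "OrthologGroupSet":
        wanted = set(seq_ids)
        return OrthologGroupSet([r for r in self.records if r.id in wanted])


@dataclass
class AlignedFamily:
    """Equal-width gapped rows for one group, with residue index maps."""

    group_id: str
    rows: dict[str, str]
    truth_conserved_columns: frozenset[int] | None = None

    def __post_init__(self):
        widths = {len(r) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValueError(
                f"family {self.group_id!r} has ragged rows of widths {sorted(widths)}"
            )
        self.rows = {k: v.replace(".", GAP) for k, v in self.rows.items()}

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def row_ids(self) -> list[str]:
        return sorted(self.rows)

    def sequence_of(self, row_id: str) -> str:
        return self.rows[row_id].replace(GAP, "")

    def column_map(self, row_id: str) -> list[int | None]:
        """Alignment column -> ungapped residue index (None at gaps)."""
        out: list[int | None] = []
        idx = 0
        for ch in self.rows[row_id]:
            if ch == GAP:
                out.append(None)
            else:
                out.append(idx)
                idx += 1
        return out


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _read_sidecar(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FastaParseError(f"{path}:{ln}: expected two tab-separated fields")
        mapping[parts[0]] = parts[1]
    return mapping


def read_fasta(
    path: str | Path, group_tsv: str | Path | None = None
) -> list[ProteinRecord]:
    """Read protein records; group ids from ``id|group`` headers or sidecar TSV."""
    sidecar = _read_sidecar(group_tsv) if group_tsv is not None else None
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        seq = str(rec.seq).upper()
        if "|" in name:
            seq_id, group_id = name.split("|", 1)
        elif sidecar is not None and name in sidecar:
            seq_id, group_id = name, sidecar[name]
        else:
            raise FastaParseError(
                f"{path}: record {name!r} has no 'id|group' header and no "
                "sidecar TSV entry"
            )
        if not seq:
            raise FastaParseError(f"{path}: record {name!r} has an empty sequence")
        if seq_id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        records.append(ProteinRecord(seq_id, seq, group_id))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    out = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}|{r.group_id}", description="")
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def read_alignment(path: str | Path, group_id: str | None = None) -> AlignedFamily:
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id = rec.id.split("|", 1)[0]
        if seq_id in rows:
            raise FastaParseError(f"{path}: duplicate row id {seq_id!r}")
        rows[seq_id] = str(rec.seq).upper()
    if not rows:
        raise FastaParseError(f"{path}: no alignment rows found")
    return AlignedFamily(group_id or Path(path).stem, rows)


def write_alignment(family: AlignedFamily, path: str | Path) -> None:
    out = [
        SeqRecord(Seq(family.rows[rid]), id=rid, description="")
        for rid in family.row_ids
    ]
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# Filtering and splitting
# ---------------------------------------------------------------------------

def filter_groups(
    data: OrthologGroupSet, min_members_exclusive: int = 10
) -> OrthologGroupSet:
    """Keep only groups with strictly more than ``min_members_exclusive`` members."""
    keep = {g for g, m in data.groups.items() if len(m) > min_members_exclusive}
    return OrthologGroupSet([r for r in data.records if r.group_id in keep])


@dataclass(frozen=True)
class SplitResult:
    train_ids: frozenset[str]
    test_ids: frozenset[str]
    ratio: float = 0.9


def stratified_split(
    data: OrthologGroupSet, test_fraction: float = 0.1, seed: int = 0
) -> SplitResult:
    """Group-stratified train/test split.

    Each group contributes ``max(1, round(test_fraction * n))`` members to
    the test set (ties round half-up), sampled uniformly without
    replacement, so every group is represented in both subsets.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    test: set[str] = set()
    for gid in data.group_ids:
        members = data.members(gid)
        n = len(members)
        if n < 2:
            raise ValueError(
                f"group {gid!r} has {n} member(s); at least 2 are needed to stratify"
            )
        n_test = max(1, int(np.floor(test_fraction * n + 0.5)))
        chosen = rng.choice(n, size=n_test, replace=False)
        chosen_set = {members[i] for i in chosen}
        test |= chosen_set
        train |= set(members) - chosen_set
    return SplitResult(frozenset(train), frozenset(test), ratio=1 - test_fraction)


# ---------------------------------------------------------------------------
# Synthetic families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticFamilyConfig:
    """Ground-truthed ortholog-family simulator settings.

    Defaults emulate a modest ortholog benchmark: 30 families of 12
    members, 120-residue ancestors with three 12-residue conserved motif
    blocks, 25% point substitution outside the blocks, no conserved-block
    noise, and no indels (so the true alignment is the trivial one).
    """

    n_groups: int = 30
    members_per_group: int | tuple[int, int] = 12
    ancestor_length: int | tuple[int, int] = 120
    conserved_blocks: tuple[tuple[int, int], ...] = ((10, 12), (55, 12), (95, 12))
    substitution_rate: float = 0.25
    conserved_noise_rate: float = 0.0
    indel_rate: float = 0.0
    residue_frequencies: tuple[float, ...] | None = None
    # when set, every family carries the same motif residues in its
    # conserved blocks (drawn once from this seed), so sequences from
    # different families are remote homologs sharing only the blocks
    shared_motif_seed: int | None = None
    seed: int = 0

    def __post_init__(self):
        for rate, name in (
            (self.substitution_rate, "substitution_rate"),
            (self.conserved_noise_rate, "conserved_noise_rate"),
            (self.indel_rate, "indel_rate"),
        ):
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.residue_frequencies is not None:
            freqs = np.asarray(self.residue_frequencies)
            if len(freqs) != 20 or not np.isclose(freqs.sum(), 1.0):
                raise ValueError("residue_frequencies must be a 20-vector summing to 1")
        spans = sorted(self.conserved_blocks)
        min_len = (
            self.ancestor_length
            if isinstance(self.ancestor_length, int)
            else self.ancestor_length[0]
        )
        prev_end = -1
        for start, length in spans:
            if start < 0 or length <= 0 or start + length > min_len:
                raise ValueError(f"conserved block {(start, length)} outside ancestor")
            if start <= prev_end:
                raise ValueError("conserved blocks must not overlap")
            prev_end = start + length - 1


def _draw(rng: np.random.Generator, value: int | tuple[int, int]) -> int:
    if isinstance(value, int):
        return value
    lo, hi = value
    return int(rng.integers(lo, hi + 1))


def _sample_divergent_column(
    rng: np.random.Generator,
    ancestral: str,
    deleted: np.ndarray,
    substitution_rate: float,
    alphabet: np.ndarray,
) -> list[str]:
    """Sample one non-conserved column (gaps where ``deleted``) that fails
    the conservation criteria, so ground-truth conserved columns are exact.

    Rejection sampling under the configured substitution rate; if a column
    keeps qualifying (possible for low rates or few members), the rate is
    escalated so termination is guaranteed in practice.
    """
    from .conservation import ConservedColumnCriteria, column_qualifies

    criteria = ConservedColumnCriteria()
    n = len(deleted)
    for attempt in range(600):
        rate = substitution_rate if attempt < 50 else max(substitution_rate, 0.6)
        column = []
        for j in range(n):
            if deleted[j]:
                column.append(GAP)
            elif rng.random() < rate:
                column.append(str(rng.choice(alphabet[alphabet != ancestral])))
            else:
                column.append(ancestral)
        if not column_qualifies(column, criteria):
            return column
    raise RuntimeError("could not sample a non-conserved column")  # pragma: no cover


def generate_families(
    config: SyntheticFamilyConfig,
) -> tuple[OrthologGroupSet, list[AlignedFamily]]:
    """Simulate ortholog families with known alignments and conserved columns.

    Members descend from a per-group random ancestor.  Conserved blocks are
    copied verbatim (each residue flipped with ``conserved_noise_rate``);
    every other ancestor position diverges by point substitution at
    ``substitution_rate``, re-sampled so the resulting column genuinely
    fails the conservation criteria (the simulator owns its ground truth).
    Indels fall only outside conserved blocks; insertions occupy
    member-private alignment columns, so the true alignment is maintained
    by construction.  With ``substitution_rate == 0`` the divergence
    machinery is disabled and members are identical to the ancestor.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(STANDARD_RESIDUES))
    freqs = (
        np.full(20, 0.05)
        if config.residue_frequencies is None
        else np.asarray(config.residue_frequencies)
    )
    records: list[ProteinRecord] = []
    families: list[AlignedFamily] = []

    shared_motif: dict[int, str] | None = None
    if config.shared_motif_seed is not None:
        motif_rng = np.random.default_rng(config.shared_motif_seed)
        shared_motif = {}
        for start, length in config.conserved_blocks:
            for k in range(start, start + length):
                shared_motif[k] = str(motif_rng.choice(alphabet))

    for g in range(config.n_groups):
        gid = f"FAM{g:04d}"
        La = _draw(rng, config.ancestor_length)
        ancestor = rng.choice(alphabet, size=La, p=freqs)
        conserved = np.zeros(La, dtype=bool)
        for start, length in config.conserved_blocks:
            conserved[start : start + length] = True
        if shared_motif is not None:
            for k, res in shared_motif.items():
                ancestor[k] = res

        n_members = _draw(rng, config.members_per_group)
        member_ids = [f"{gid}_m{j:02d}" for j in range(n_members)]

        # indel decisions per (member, non-conserved ancestor position)
        deletions = np.zeros((n_members, La), dtype=bool)
        inserts: dict[int, list[tuple[int, str]]] = {}
        if config.indel_rate:
            for j in range(n_members):
                for k in range(La):
                    if conserved[k]:
                        continue
                    u = rng.random()
                    if u < config.indel_rate / 2:
                        deletions[j, k] = True
                    elif u < config.indel_rate:
                        inserts.setdefault(k, []).append((j, str(rng.choice(alphabet))))

        columns: list[list[str]] = []
        ancestor_col: dict[int, int] = {}
        for k in range(La):
            ancestor_col[k] = len(columns)
            if conserved[k]:
                column = []
                for j in range(n_members):
                    res = ancestor[k]
                    if config.conserved_noise_rate and rng.random() < config.conserved_noise_rate:
                        res = rng.choice(alphabet[alphabet != res])
                    column.append(str(res))
            elif config.substitution_rate == 0:
                column = [
                    GAP if deletions[j, k] else str(ancestor[k])
                    for j in range(n_members)
                ]
            else:
                column = _sample_divergent_column(
                    rng, str(ancestor[k]), deletions[:, k],
                    config.substitution_rate, alphabet,
                )
            columns.append(column)
            for j, res in inserts.get(k, []):
                col = [GAP] * n_members
                col[j] = res
                columns.append(col)

        rows = {
            member_ids[j]: "".join(col[j] for col in columns)
            for j in range(n_members)
        }
        truth = frozenset(ancestor_col[k] for k in range(La) if conserved[k])
        families.append(AlignedFamily(gid, rows, truth_conserved_columns=truth))
        for j, mid in enumerate(member_ids):
            records.append(ProteinRecord(mid, rows[mid].replace(GAP, ""), gid))

    return OrthologGroupSet(records), families


def sample_triplets(
    data: OrthologGroupSet,
    n: int,
    seed: int = 0,
    anchor_ids=None,
) -> list[tuple[str, str, str]]:
    """Draw (anchor, positive, negative) id triplets.

    Anchor is uniform over sequences whose group has at least two members
    (optionally restricted to ``anchor_ids``, e.g. a held-out subset);
    positive is uniform over the anchor's group mates; negative is uniform
    over all sequences outside the anchor's group.
    """
    if len(data.groups) < 2:
        raise ValueError("triplet sampling requires at least two groups")
    rng = np.random.default_rng(seed)
    allowed = set(anchor_ids) if anchor_ids is not None else None
    eligible = [
        r.id
        for r in data.records
        if len(data.groups[r.group_id]) >= 2
        and (allowed is None or r.id in allowed)
    ]
    if not eligible:
        raise ValueError("no group has two or more members")
    eligible.sort()
    all_ids = sorted(r.id for r in data.records)
    triplets: list[tuple[str, str, str]] = []
    for _ in range(n):
        anchor = eligible[rng.integers(len(eligible))]
        group = data[anchor].group_id
        mates = [m for m in data.members(group) if m != anchor]
        positive = mates[rng.integers(len(mates))]
        others = [i for i in all_ids if data[i].group_id != group]
        negative = others[rng.integers(len(others))]
        triplets.append((anchor, positive, negative))
    return triplets
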