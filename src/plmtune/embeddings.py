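"""Residue-level and mean-pooled embedding extraction, plus cosine similarity.

Residue embeddings come from the encoder's last hidden layer; padding and
special tokens are stripped so the matrix has exactly one row per residue.
Pooled (sequence-level) embeddings are the arithmetic column mean of the
residue matrix.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def embed_residues(encoder, sequence: str) -> np.ndarray:
    """L x d matrix of last-hidden-layer vectors, one row per residue."""
    hidden, _, ids = encoder.encode(sequence)
    vocab = encoder.vocab
    keep = [i for i, t in enumerate(ids) if not vocab.is_special(t)]
    matrix = hidden.data[np.asarray(keep, dtype=np.intp)]
    assert matrix.shape[0] == len(sequence)
    return matrix


def pool(matrix: np.ndarray) -> np.ndarray:
    """Mean-pooled sequence embedding (exact column mean of the residue rows)."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("pooling requires a nonempty L x d matrix")
    return matrix.mean(axis=0)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(u @ v / (nu * nv))


def embed_dataset(
    encoder, data, pooled_only: bool = False
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Embed every record; returns (residue matrices by id, pooled vectors by id)."""
    residue: dict[str, np.ndarray] = {}
    pooled: dict[str, np.ndarray] = {}
    for rec in data.records:
        m = embed_residues(encoder, rec.sequence)
        if not pooled_only:
            residue[rec.id] = m
        pooled[rec.id] = pool(m)
    return residue, pooled


def save_embeddings(path: str | Path, residue: dict, pooled: dict) -> None:
    """Persist an embedding store (npz matrices plus an id manifest)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "pooled.npz", **pooled)
    if residue:
        np.savez(path / "residue.npz", **residue)
    (path / "ids.txt").write_text("\n".join(sorted(pooled)) + "\n")


def load_embeddings(path: str | Path) -> tuple[dict, dict]:
    path = Path(path)
    with np.load(path / "pooled.npz") as data:
        pooled = {k: data[k] for k in data.files}
    residue = {}
    if (path / "residue.npz").exists():
        with np.load(path / "residue.npz") as data:
            residue = {k: data[k] for k in data.files}
    return residue, pooled


def export_pooled_tsv(pooled: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(pooled):
            vec = "\t".join(f"{x:.10g}" for x in pooled[sid])
            fh.write(f"{sid}\t{vec}\n")
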