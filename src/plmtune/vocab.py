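"""Amino-acid token vocabulary for per-residue encoders.

The residue alphabet is the 20 standard amino acids plus ``X`` for unknown
residues (IUPAC).  Special tokens (pad, mask, optional begin/end) occupy the
low token ids and are disjoint from residue tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_RESIDUE = "X"

PAD = "<pad>"
MASK = "<mask>"
BOS = "<bos>"
EOS = "<eos>"


class SequenceTooLongError(ValueError):
    """Raised when a sequence exceeds the encoder's maximum length."""


@dataclass(frozen=True)
class AminoAcidVocabulary:
    """Token table mapping residues and special symbols to integer ids.

    Parameters
    ----------
    include_bos_eos:
        When true, :meth:`encode` brackets each sequence with begin/end
        tokens (which downstream embedding extraction strips again).
    """

    include_bos_eos: bool = False
    tokens: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        specials = [PAD, MASK] + ([BOS, EOS] if self.include_bos_eos else [])
        object.__setattr__(
            self,
            "tokens",
            tuple(specials) + tuple(STANDARD_RESIDUES) + (UNKNOWN_RESIDUE,),
        )

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def n_special(self) -> int:
        return 4 if self.include_bos_eos else 2

    @property
    def pad_id(self) -> int:
        return self.tokens.index(PAD)

    @property
    def mask_id(self) -> int:
        return self.tokens.index(MASK)

    @property
    def bos_id(self) -> int:
        return self.tokens.index(BOS)

    @property
    def eos_id(self) -> int:
        return self.tokens.index(EOS)

    def residue_id(self, residue: str) -> int:
        """Token id for a single residue character; unknowns map to X."""
        r = residue.upper()
        if r in STANDARD_RESIDUES or r == UNKNOWN_RESIDUE:
            return self.tokens.index(r)
        return self.tokens.index(UNKNOWN_RESIDUE)

    def is_special(self, token_id: int) -> bool:
        return token_id < self.n_special

    def encode(self, sequence: str) -> list[int]:
        if not sequence:
            raise ValueError("cannot tokenize an empty sequence")
        ids = [self.residue_id(c) for c in sequence]
        if self.include_bos_eos:
            ids = [self.bos_id] + ids + [self.eos_id]
        return ids

    def decode(self, token_ids: list[int]) -> str:
        """Recover the residue string, skipping special tokens."""
        return "".join(
            self.tokens[t] for t in token_ids if not self.is_special(t)
        )


def tokenize(
    sequence: str,
    vocab: AminoAcidVocabulary,
    max_sequence_length: int | None = None,
) -> list[int]:
    """Tokenize a residue string; refuses over-length input (no truncation)."""
    if max_sequence_length is not None:
        needed = len(sequence) + (2 if vocab.include_bos_eos else 0)
        if needed > max_sequence_length:
            raise SequenceTooLongError(
                f"sequence of length {len(sequence)} exceeds the encoder "
                f"maximum of {max_sequence_length} tokens"
            )
    return vocab.encode(sequence)
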