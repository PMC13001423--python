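"""Pluggable frozen token encoders.

The interaction module consumes token-level embeddings from frozen encoders
(in production settings these would be large pretrained protein/chemical
language models). The registry lets any callable mapping a token sequence to
an (len, h) array be plugged in by name; the built-in ``hash`` encoder is a
tiny deterministic stand-in that maps (token identity, position) through a
seeded hash into R^h. Encoders are frozen by construction here: they hold no
trainable parameters and are never touched by the optimizer.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .structures import LigandRecord, ProteinSequence

__all__ = ["EmbeddingBatch", "HashEncoder", "register_encoder", "get_encoder", "encode"]


@dataclass
class EmbeddingBatch:
    """Token embeddings for one protein-ligand pair: P is (n, h), D is (m, h)."""

    P: np.ndarray
    D: np.ndarray

    @property
    def h(self) -> int:
        return self.P.shape[1]

    def __post_init__(self) -> None:
        if self.P.ndim != 2 or self.D.ndim != 2 or self.P.shape[1] != self.D.shape[1]:
            raise ValueError("P and D must be 2-D with a common hidden dimension")
        if self.P.shape[0] < 1 or self.D.shape[0] < 1:
            raise ValueError("need at least one token per side")
        if not (np.isfinite(self.P).all() and np.isfinite(self.D).all()):
            raise ValueError("embeddings must be finite")


class HashEncoder:
    """Deterministic stand-in encoder: seeded hash of (token, position) -> R^h.

    Rows are unit-variance Gaussian draws from a generator keyed on the
    encoder seed, a CRC of the token string, and the 1-based position, so the
    same sequence always encodes to the same matrix.
    """

    def __init__(self, h: int = 64, seed: int = 0):
        if h < 1:
            raise ValueError("hidden dimension must be positive")
        self.h = h
        self.seed = seed

    def __call__(self, tokens: Sequence[str]) -> np.ndarray:
        if len(tokens) == 0:
            raise ValueError("cannot encode an empty token sequence")
        rows = []
        for pos, tok in enumerate(tokens, start=1):
            crc = zlib.crc32(str(tok).encode())
            rng = np.random.default_rng([self.seed, crc, pos])
            rows.append(rng.standard_normal(self.h) / np.sqrt(self.h))
        return np.stack(rows)


_REGISTRY: dict[str, Callable[..., Callable]] = {"hash": HashEncoder}


def register_encoder(name: str, factory: Callable[..., Callable]) -> None:
    _REGISTRY[name] = factory


def get_encoder(name: str, **kwargs) -> Callable:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown encoder {name!r}; registered: {sorted(_REGISTRY)}") from None
    return factory(**kwargs)


def encode(protein: ProteinSequence, ligand: LigandRecord, encoder) -> EmbeddingBatch:
    """Embed one pair with a frozen encoder (one row per residue / ligand token)."""
    if isinstance(encoder, str):
        encoder = get_encoder(encoder)
    P = encoder(list(protein.residues))
    D = encoder(list(ligand.atom_tokens))
    return EmbeddingBatch(P=np.asarray(P, float), D=np.asarray(D, float))
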