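"""Numeric feature encodings for RNA windows.

The primary encoding is one-hot: each position becomes a 5-dim indicator over
the channel order (A, U, G, C, N), so a 201-nt window maps to a 5 x 201
matrix. Alternates: NCP (3-bit ring / functional-group / hydrogen-bond code)
and an integer code consumed by a model-side learnable embedding layer.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

from .seqdata import SeqDataset

__all__ = [
    "FeatureMatrix",
    "ONE_HOT_ORDER",
    "one_hot_encode",
    "decode",
    "ncp_encode",
    "integer_encode",
    "encode_dataset",
    "encoder_channels",
    "stack_features",
]

# Channel order is frozen: A, U, G, C, N.
ONE_HOT_ORDER = "AUGCN"
_ONE_HOT_INDEX = {c: i for i, c in enumerate(ONE_HOT_ORDER)}

# NCP: (ring structure, functional group, hydrogen bonds); N is the null code.
_NCP = {
    "A": (1.0, 1.0, 1.0),
    "C": (0.0, 1.0, 0.0),
    "G": (1.0, 0.0, 0.0),
    "U": (0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0),
}

ENCODERS = ("onehot", "ncp", "embed")


@dataclasses.dataclass(frozen=True)
class FeatureMatrix:
    """channels x length numeric encoding of one sequence."""

    values: np.ndarray
    encoding_name: str

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"sequence contains non-normalised characters {sorted(bad)}")


def one_hot_encode(seq: str) -> FeatureMatrix:
    """Encode a normalised sequence as a 5 x L indicator matrix."""
    _check_alphabet(seq)
    idx = np.fromiter((_ONE_HOT_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    m = np.zeros((5, len(seq)), dtype=np.float32)
    m[idx, np.arange(len(seq))] = 1.0
    return FeatureMatrix(m, "onehot")


def decode(fm: FeatureMatrix) -> str:
    """Exact inverse of :func:`one_hot_encode`."""
    v = fm.values
    if v.shape[0] != 5:
        raise ValueError(f"one-hot matrix must have 5 channels, got {v.shape[0]}")
    is_one = v == 1.0
    if not (np.all((v == 0.0) | is_one) and np.all(is_one.sum(axis=0) == 1)):
        bad = int(np.argmin(is_one.sum(axis=0) == 1))
        raise ValueError(f"column {bad} violates the one-hot invariant")
    return "".join(ONE_HOT_ORDER[i] for i in np.argmax(v, axis=0))


def ncp_encode(seq: str) -> FeatureMatrix:
    """3 x L nucleotide chemical property encoding."""
    _check_alphabet(seq)
    m = np.array([_NCP[c] for c in seq], dtype=np.float32).T
    return FeatureMatrix(m.reshape(3, len(seq)), "ncp")


def integer_encode(seq: str) -> FeatureMatrix:
    """1 x L integer codes (A=0, U=1, G=2, C=3, N=4) for embedding layers."""
    _check_alphabet(seq)
    codes = np.fromiter((_ONE_HOT_INDEX[c] for c in seq), dtype=np.float32,
                        count=len(seq))
    return FeatureMatrix(codes.reshape(1, len(seq)), "embed")


_ENCODER_FN = {"onehot": one_hot_encode, "ncp": ncp_encode, "embed": integer_encode}


def encoder_channels(name: str) -> int:
    """Number of channels an encoder presents to the network input."""
    if name not in ENCODERS:
        raise ValueError(f"unknown encoder {name!r}; expected one of {ENCODERS}")
    # the embedding encoder emits integer codes; the model lifts them to 5 dims
    return {"onehot": 5, "ncp": 3, "embed": 5}[name]


def encode_dataset(ds: SeqDataset, encoder: str = "onehot"
                   ) -> list[tuple[FeatureMatrix, int]]:
    """Encode every record, preserving order; labels co-travel."""
    if encoder not in _ENCODER_FN:
        raise ValueError(f"unknown encoder {encoder!r}; expected one of {ENCODERS}")
    fn = _ENCODER_FN[encoder]
    return [(fn(r.sequence), r.label) for r in ds]


def stack_features(ds: SeqDataset, encoder: str = "onehot"
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(N, channels, L) feature array and (N,) label vector for batching."""
    pairs = encode_dataset(ds, encoder)
    X = np.stack([fm.values for fm, _ in pairs]).astype(np.float32)
    y = np.array([lab for _, lab in pairs], dtype=np.float32)
    return X, y
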