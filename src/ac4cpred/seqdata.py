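"""Labeled fixed-length RNA windows: records, file I/O, splitting, simulation.

The benchmark-style datum is a 201-nt window centred on a candidate cytosine,
labeled 1 (acetylated, ac4C) or 0. Sequences are normalised to the RNA
alphabet {A, C, G, U} plus N for anything ambiguous; DNA input is accepted
and T is mapped to U on read.

All user-facing coordinates are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SequenceRecord",
    "SeqDataset",
    "SynthSpec",
    "DataError",
    "normalize_sequence",
    "read_sequences",
    "write_sequences",
    "stratified_split",
    "kfold_indices",
    "generate_synthetic",
]

RNA_ALPHABET = "ACGUN"

# IUPAC degeneracy over the RNA alphabet; anything not listed maps to N.
IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "GC", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


class DataError(ValueError):
    """Raised for malformed or contract-violating input data."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, map T->U, and collapse non-ACGU characters to N."""
    seq = seq.upper().replace("T", "U")
    return "".join(c if c in "ACGU" else "N" for c in seq)


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """One labeled window: identifier, normalised sequence, binary label."""

    id: str
    sequence: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise DataError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")
        bad = set(self.sequence) - set(RNA_ALPHABET)
        if bad:
            raise DataError(f"record {self.id!r}: illegal characters {sorted(bad)}")


class SeqDataset:
    """An ordered collection of equal-length :class:`SequenceRecord`."""

    def __init__(self, records: Iterable[SequenceRecord], provenance: str = "",
                 window_length: int | None = None):
        self.records: list[SequenceRecord] = list(records)
        if not self.records:
            if window_length is None:
                raise DataError("an empty dataset needs an explicit window_length")
            self.window_length = int(window_length)
            self.provenance = provenance
            return
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            offenders = [r.id for r in self.records
                         if len(r.sequence) != len(self.records[0].sequence)]
            raise DataError(
                f"mixed sequence lengths {sorted(lengths)}; offending ids include "
                f"{offenders[:5]}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise DataError(f"duplicate record id {dup!r}")
        self.window_length: int = lengths.pop()
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset_by_ids(self, ids: Sequence[str], provenance: str = "") -> "SeqDataset":
        wanted = set(ids)
        recs = [r for r in self.records if r.id in wanted]
        if len(recs) != len(wanted):
            missing = wanted - {r.id for r in recs}
            raise DataError(f"unknown ids requested: {sorted(missing)[:5]}")
        return SeqDataset(recs, provenance or self.provenance)

    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        y = self.labels
        return int((y == 0).sum()), int((y == 1).sum())

    @property
    def center(self) -> int:
        """1-based centre position, (L+1)/2 for odd L."""
        return (self.window_length + 1) // 2


@dataclasses.dataclass
class SynthSpec:
    """Parameters of the synthetic benchmark emulator.

    Positives carry degenerate motifs implanted in a 5'-biased zone
    (defaults: GNNG/GGNGG/GNG at positions 20-60 of a 201-nt window, three
    implants per positive); negatives are background only. Both classes have
    a C at the centre position, mimicking candidate-cytosine windows.
    """

    n_positive: int = 500
    n_negative: int = 500
    window_length: int = 201
    motifs: tuple[str, ...] = ("GNNG", "GGNGG", "GNG")
    enrich_start: int = 20
    enrich_end: int = 60
    motifs_per_positive: int = 3
    background_gc: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.window_length < 1 or self.window_length % 2 == 0:
            raise DataError("window_length must be odd and positive")
        if not (1 <= self.enrich_start <= self.enrich_end <= self.window_length):
            raise DataError("need 1 <= enrich_start <= enrich_end <= window_length")
        zone = self.enrich_end - self.enrich_start + 1
        for m in self.motifs:
            if len(m) > zone:
                raise DataError(f"motif {m!r} does not fit inside the enrichment zone")
            for c in m.upper():
                if c not in IUPAC_RNA:
                    raise DataError(f"motif {m!r}: unknown IUPAC code {c!r}")
        if not (0.0 <= self.background_gc <= 1.0):
            raise DataError("background_gc must be in [0, 1]")
        if self.n_positive < 1 or self.n_negative < 1:
            raise DataError("need at least one record per class")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_fasta_label(description: str) -> tuple[str, int]:
    """Parse the ``id|label=L`` FASTA header dialect."""
    head = description.split()[0]
    if "|label=" not in head:
        raise DataError(f"FASTA header {description!r} lacks a '|label=' token")
    rid, _, tok = head.rpartition("|label=")
    try:
        label = int(tok)
    except ValueError:
        raise DataError(f"unparseable label {tok!r} in header {description!r}") from None
    return rid, label


def read_sequences(path: str | Path, format: str = "fasta") -> SeqDataset:
    """Read a labeled dataset from FASTA (``>id|label=L``) or a CSV/TSV table.

    Sequences are normalised (uppercase, T->U, non-ACGU -> N); all records
    must share one length.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    records: list[SequenceRecord] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            rid, label = _parse_fasta_label(rec.description)
            records.append(SequenceRecord(rid, normalize_sequence(str(rec.seq)), label))
    elif format == "table":
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, dtype={"id": str, "sequence": str})
        for col in ("id", "sequence", "label"):
            if col not in df.columns:
                raise DataError(f"table {path} lacks required column {col!r}")
        for _, row in df.iterrows():
            try:
                label = int(row["label"])
            except (TypeError, ValueError):
                raise DataError(f"unparseable label {row['label']!r} for id {row['id']!r}") from None
            records.append(SequenceRecord(str(row["id"]),
                                          normalize_sequence(str(row["sequence"])), label))
    else:
        raise DataError(f"unknown format {format!r} (expected 'fasta' or 'table')")
    return SeqDataset(records, provenance=str(path))


def write_sequences(ds: SeqDataset, path: str | Path, format: str = "fasta") -> None:
    """Write a dataset so that :func:`read_sequences` round-trips it exactly."""
    if len(ds) == 0:
        raise DataError("refusing to write an empty dataset")
    path = Path(path)
    if format == "fasta":
        bio = [_BioRecord(Seq(r.sequence), id=f"{r.id}|label={r.label}", description="")
               for r in ds]
        with open(path, "w") as fh:
            SeqIO.write(bio, fh, "fasta")
    elif format == "table":
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        pd.DataFrame({"id": ds.ids, "sequence": [r.sequence for r in ds],
                      "label": [r.label for r in ds]}).to_csv(path, sep=sep, index=False)
    else:
        raise DataError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def stratified_split(ds: SeqDataset, test_fraction: float, seed: int
                     ) -> tuple[SeqDataset, SeqDataset]:
    """Class-stratified train/test split; deterministic given ``seed``.

    Per-class test counts are ``round(n_class * test_fraction)``, matching the
    benchmark's 4:1 train:test convention at ``test_fraction=0.2``. Membership
    is keyed on record ids, not input order.
    """
    if not (0.0 < test_fraction < 1.0):
        raise DataError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls in (0, 1):
        cls_ids = sorted(r.id for r in ds if r.label == cls)
        if len(cls_ids) < 2:
            raise DataError(f"class {cls} has fewer than 2 records")
        n_test = int(round(len(cls_ids) * test_fraction))
        n_test = min(max(n_test, 1), len(cls_ids) - 1)
        perm = rng.permutation(len(cls_ids))
        test_ids.extend(cls_ids[i] for i in perm[:n_test])
        train_ids.extend(cls_ids[i] for i in perm[n_test:])
    return (ds.subset_by_ids(train_ids, provenance=f"{ds.provenance}[train]"),
            ds.subset_by_ids(test_ids, provenance=f"{ds.provenance}[test]"))


def kfold_indices(ds: SeqDataset, k: int, seed: int) -> list[tuple[list[str], list[str]]]:
    """Stratified k-fold partition as (train ids, held-out ids) pairs.

    Folds are pairwise disjoint, cover the dataset, and are keyed on sorted
    record ids so record order does not affect membership.
    """
    if k < 2:
        raise DataError("k must be >= 2")
    order = sorted(range(len(ds)), key=lambda i: ds.records[i].id)
    ids = [ds.records[i].id for i in order]
    y = np.array([ds.records[i].label for i in order])
    if min(int((y == 0).sum()), int((y == 1).sum())) < k:
        raise DataError(f"k={k} exceeds the size of the smaller class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 32))
    folds = []
    for train_idx, test_idx in skf.split(np.zeros(len(ids)), y):
        folds.append(([ids[i] for i in train_idx], [ids[i] for i in test_idx]))
    return folds


# ---------------------------------------------------------------------------
# synthetic benchmark
# ---------------------------------------------------------------------------

def _instantiate_motif(motif: str, rng: np.random.Generator) -> str:
    return "".join(c if c in "ACGU" else IUPAC_RNA[c][rng.integers(len(IUPAC_RNA[c]))]
                   for c in motif.upper())


def _place_nonoverlapping(rng: np.random.Generator, lengths: list[int],
                          zone_start: int, zone_end: int, max_tries: int = 200
                          ) -> list[int]:
    """Uniform non-overlapping 0-based starts inside [zone_start, zone_end]."""
    if sum(lengths) > zone_end - zone_start + 1:
        raise DataError("motifs cannot fit in the enrichment zone without overlap")
    for _ in range(max_tries):
        starts = []
        ok = True
        for ln in lengths:
            hi = zone_end - ln + 1
            if hi < zone_start:
                ok = False
                break
            s = int(rng.integers(zone_start, hi + 1))
            if any(s < t + tl and t < s + ln for t, tl in zip(starts, lengths)):
                ok = False
                break
            starts.append(s)
        if ok:
            return starts
    raise DataError("could not place motifs without overlap inside the enrichment zone")


def generate_synthetic(spec: SynthSpec) -> SeqDataset:
    """Generate a benchmark-style synthetic dataset.

    Every sequence is i.i.d. background with the requested GC content and a
    forced C at the centre; each positive additionally receives
    ``motifs_per_positive`` instantiated motifs at uniform non-overlapping
    starts whose full extent lies inside the 1-based enrichment zone.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    gc, at = spec.background_gc / 2.0, (1.0 - spec.background_gc) / 2.0
    probs = np.array([at, gc, gc, at])  # A, C, G, U
    bases = np.array(list("ACGU"))
    center0 = (spec.window_length - 1) // 2
    zone0_start, zone0_end = spec.enrich_start - 1, spec.enrich_end - 1

    def background() -> np.ndarray:
        return bases[rng.choice(4, size=spec.window_length, p=probs)]

    records: list[SequenceRecord] = []
    for i in range(spec.n_positive):
        arr = background()
        chosen = [spec.motifs[int(rng.integers(len(spec.motifs)))]
                  for _ in range(spec.motifs_per_positive)]
        starts = _place_nonoverlapping(rng, [len(m) for m in chosen],
                                       zone0_start, zone0_end)
        for m, s in zip(chosen, starts):
            inst = _instantiate_motif(m, rng)
            arr[s: s + len(inst)] = list(inst)
        arr[center0] = "C"
        records.append(SequenceRecord(f"pos_{i:05d}", "".join(arr), 1))
    for i in range(spec.n_negative):
        arr = background()
        arr[center0] = "C"
        records.append(SequenceRecord(f"neg_{i:05d}", "".join(arr), 0))
    prov = (f"synthetic(n_pos={spec.n_positive}, n_neg={spec.n_negative}, "
            f"L={spec.window_length}, zone={spec.enrich_start}-{spec.enrich_end}, "
            f"seed={spec.seed})")
    return SeqDataset(records, provenance=prov)
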