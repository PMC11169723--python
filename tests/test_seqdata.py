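"""Sequence records, I/O round trips, splitting partitions, and the
synthetic benchmark generator's statistical guarantees."""

import numpy as np
import pytest
from scipy.stats import norm

from ac4cpred.seqdata import (DataError, IUPAC_RNA, SeqDataset, SequenceRecord,
                              SynthSpec, generate_synthetic, kfold_indices,
                              normalize_sequence, read_sequences,
                              stratified_split, write_sequences)


def test_normalization_maps_dna_and_ambiguity_codes():
    assert normalize_sequence("acgt") == "ACGU"
    assert normalize_sequence("ARYX-") == "ANNNN"


def test_dataset_rejects_mixed_lengths_naming_offender():
    recs = [SequenceRecord("a", "ACGUA", 1), SequenceRecord("bad", "ACG", 0)]
    with pytest.raises(DataError, match="bad"):
        SeqDataset(recs)


def test_dataset_rejects_duplicate_ids():
    recs = [SequenceRecord("a", "ACG", 1), SequenceRecord("a", "GCA", 0)]
    with pytest.raises(DataError, match="duplicate"):
        SeqDataset(recs)


@pytest.mark.parametrize("fmt,suffix", [("fasta", ".fasta"), ("table", ".csv"),
                                        ("table", ".tsv")])
def test_io_round_trip(tmp_path, tiny_ds, fmt, suffix):
    path = tmp_path / f"ds{suffix}"
    write_sequences(tiny_ds, path, fmt)
    back = read_sequences(path, fmt)
    assert [(r.id, r.sequence, r.label) for r in back] == \
           [(r.id, r.sequence, r.label) for r in tiny_ds]


def test_fasta_reader_normalizes_t_to_u(tmp_path):
    path = tmp_path / "t.fasta"
    path.write_text(">x|label=1\nACGTACGTA\n>y|label=0\nTTTTTTTTT\n")
    ds = read_sequences(path, "fasta")
    assert ds[0].sequence == "ACGUACGUA"
    assert ds[1].sequence == "UUUUUUUUU"


def test_fasta_reader_rejects_unlabeled_headers(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">seq1\nACGU\n")
    with pytest.raises(DataError, match="label"):
        read_sequences(path, "fasta")


def test_write_empty_dataset_errors():
    empty = SeqDataset([], window_length=201)
    with pytest.raises(DataError):
        write_sequences(empty, "/tmp/never.fasta", "fasta")


def test_stratified_split_matches_four_to_one_convention():
    recs = [SequenceRecord(f"p{i}", "ACGUC", 1) for i in range(100)] + \
           [SequenceRecord(f"n{i}", "GGCCA", 0) for i in range(100)]
    ds = SeqDataset(recs)
    tr, te = stratified_split(ds, 0.2, seed=1)
    assert tr.class_counts() == (80, 80)
    assert te.class_counts() == (20, 20)


def test_stratified_split_deterministic_and_partition():
    recs = [SequenceRecord(f"p{i}", "ACGUC", 1) for i in range(5)] + \
           [SequenceRecord(f"n{i}", "GGCCA", 0) for i in range(5)]
    ds = SeqDataset(recs)
    first = stratified_split(ds, 0.2, seed=9)
    second = stratified_split(ds, 0.2, seed=9)
    assert first[0].ids == second[0].ids and first[1].ids == second[1].ids
    for seed in range(20):
        tr, te = stratified_split(ds, 0.2, seed=seed)
        assert sorted(tr.ids + te.ids) == sorted(ds.ids)
        assert not (set(tr.ids) & set(te.ids))


def test_kfold_sizes_match_benchmark_shape():
    recs = [SequenceRecord(f"p{i}", "AC", 1) for i in range(2206)] + \
           [SequenceRecord(f"n{i}", "GG", 0) for i in range(2206)]
    ds = SeqDataset(recs)
    folds = kfold_indices(ds, 10, seed=0)
    assert len(folds) == 10
    for _, held in folds:
        assert abs(len(held) - 441) <= 1
        labels = [1 if h.startswith("p") else 0 for h in held]
        assert abs(sum(labels) - len(labels) / 2) <= 1


def test_kfold_is_a_partition_for_random_datasets(rng):
    for trial in range(50):
        n_pos = int(rng.integers(4, 15))
        n_neg = int(rng.integers(4, 15))
        recs = [SequenceRecord(f"p{i}", "ACG", 1) for i in range(n_pos)] + \
               [SequenceRecord(f"n{i}", "GUA", 0) for i in range(n_neg)]
        ds = SeqDataset(recs)
        k = int(rng.integers(2, min(n_pos, n_neg) + 1))
        folds = kfold_indices(ds, k, seed=trial)
        held_all = [h for _, hs in folds for h in hs]
        assert sorted(held_all) == sorted(ds.ids)  # cover, no duplication
        for train_ids, held_ids in folds:
            assert sorted(train_ids + held_ids) == sorted(ds.ids)


def test_kfold_rejects_k_larger_than_class():
    recs = [SequenceRecord(f"p{i}", "AC", 1) for i in range(3)] + \
           [SequenceRecord(f"n{i}", "GG", 0) for i in range(8)]
    with pytest.raises(DataError):
        kfold_indices(SeqDataset(recs), 4, seed=0)


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

def motif_match_positions(seq: str, motif: str) -> list[int]:
    """0-based starts where the IUPAC motif matches exactly (oracle)."""
    hits = []
    for s in range(len(seq) - len(motif) + 1):
        if all(seq[s + i] in IUPAC_RNA[m] for i, m in enumerate(motif.upper())):
            hits.append(s)
    return hits


def test_generator_structure(tiny_ds):
    assert len(tiny_ds) == 60
    assert tiny_ds.window_length == 201
    center = tiny_ds.center - 1
    assert all(r.sequence[center] == "C" for r in tiny_ds)
    assert tiny_ds.class_counts() == (30, 30)


def test_generator_deterministic():
    spec = SynthSpec(n_positive=20, n_negative=20, seed=5)
    a = generate_synthetic(spec)
    b = generate_synthetic(spec)
    assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]


def test_generator_motif_enrichment_in_zone():
    """Motif-matching density inside positions 20-60 must be significantly
    higher in positives (one-sided two-proportion test, p < 0.01)."""
    spec = SynthSpec(n_positive=500, n_negative=500, seed=3)
    ds = generate_synthetic(spec)
    zone = slice(spec.enrich_start - 1, spec.enrich_end)
    counts = {0: 0, 1: 0}
    trials = {0: 0, 1: 0}
    for r in ds:
        window = r.sequence[zone]
        for motif in spec.motifs:
            n_starts = len(window) - len(motif) + 1
            counts[r.label] += len(motif_match_positions(window, motif))
            trials[r.label] += n_starts
    p1, p0 = counts[1] / trials[1], counts[0] / trials[0]
    pooled = (counts[1] + counts[0]) / (trials[1] + trials[0])
    se = np.sqrt(pooled * (1 - pooled) * (1 / trials[1] + 1 / trials[0]))
    p_value = float(norm.sf((p1 - p0) / se))
    assert p1 > p0
    assert p_value < 0.01


def test_generator_classes_exchangeable_outside_zone():
    """Base composition beyond the enrichment zone differs by < 3 points."""
    spec = SynthSpec(n_positive=500, n_negative=500, seed=13)
    ds = generate_synthetic(spec)
    tail = slice(spec.enrich_end, spec.window_length)  # 0-based positions 60..
    comp = {}
    for label in (0, 1):
        seqs = "".join(r.sequence[tail] for r in ds if r.label == label)
        # exclude the forced centre C from the comparison symmetrically: it is
        # present in both classes, so it cannot bias the difference
        comp[label] = {b: seqs.count(b) / len(seqs) for b in "ACGU"}
    for b in "ACGU":
        assert abs(comp[1][b] - comp[0][b]) < 0.03


def test_generator_rejects_impossible_motif_packing():
    with pytest.raises(DataError):
        SynthSpec(n_positive=2, n_negative=2, window_length=201,
                  motifs=("GGGGGGGG",), enrich_start=20, enrich_end=25)


def test_generator_rejects_bad_zone():
    with pytest.raises(DataError):
        SynthSpec(enrich_start=0, enrich_end=60)
    with pytest.raises(DataError):
        SynthSpec(window_length=200)
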