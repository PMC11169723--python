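"""Sequence-region impact analyses.

Two retraining experiments locate where the predictive signal lives:

* the truncation ladder — centred slices of decreasing length (default
  21, 41, ..., 201 nt, i.e. removing 10 nt from each end per step), each
  cross-validated from scratch;
* the window scan — a fixed 41-nt window slid along the sequence in 10-nt
  steps, one cross-validation per window, conditions labeled by the window's
  1-based centre position.

Both hold model hyperparameters fixed across conditions and reuse identical
fold membership (same fold seed), so differences across conditions are not
fold-resampling noise. A positional k-mer enrichment table (two-proportion
one-sided z-test, positives vs negatives per start position) provides a
descriptive summary of motif placement.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import norm

from .metrics import METRIC_NAMES, MetricsReport
from .network import ModelConfig
from .seqdata import DataError, SeqDataset, SequenceRecord
from .training import CVReport, TrainConfig, run_cv

__all__ = [
    "RegionResult", "results_table", "truncate_centered", "slice_window",
    "default_ladder_lengths", "window_conditions",
    "length_ladder", "window_scan", "positional_kmer_enrichment",
]


@dataclasses.dataclass
class RegionResult:
    """One experimental condition (a length or a window centre) and its CV."""

    condition: int
    cv: CVReport

    def mean_auc(self) -> float:
        return self.cv.mean_sd()["AUC"][0]


def results_table(results: list["RegionResult"], condition_name: str) -> pd.DataFrame:
    """Tidy (condition, fold, Sn, Sp, Acc, MCC, AUC) table of a region scan."""
    rows = []
    for res in results:
        for fold, rep in enumerate(res.cv.fold_reports):
            rows.append({condition_name: res.condition, "fold": fold,
                         **rep.as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# slicing
# ---------------------------------------------------------------------------

def truncate_centered(ds: SeqDataset, target_length: int) -> SeqDataset:
    """Centred slice of every record; the centre symbol is preserved.

    Both the source and the target length must be odd; for L=201 and target
    21 the retained 1-based positions are 91..111.
    """
    if target_length % 2 == 0 or target_length < 1:
        raise DataError("target_length must be odd and positive")
    if target_length > ds.window_length:
        raise DataError(f"target_length {target_length} exceeds window length "
                        f"{ds.window_length}")
    half = (target_length - 1) // 2
    c0 = (ds.window_length - 1) // 2  # 0-based centre
    recs = [SequenceRecord(r.id, r.sequence[c0 - half: c0 + half + 1], r.label)
            for r in ds]
    return SeqDataset(recs, provenance=f"{ds.provenance}[center {target_length}nt]")


def slice_window(ds: SeqDataset, start: int, window: int) -> SeqDataset:
    """Per-record slice of ``window`` nt starting at 1-based ``start``."""
    if start < 1 or start + window - 1 > ds.window_length:
        raise DataError("window does not fit inside the sequence")
    recs = [SequenceRecord(r.id, r.sequence[start - 1: start - 1 + window], r.label)
            for r in ds]
    return SeqDataset(recs, provenance=f"{ds.provenance}[{start}..{start + window - 1}]")


def default_ladder_lengths(window_length: int = 201, step: int = 20,
                           shortest: int = 21) -> tuple[int, ...]:
    """Truncation-ladder lengths: shortest, shortest+step, ..., window_length.

    The default removes 10 nt from each end per rung: 21, 41, ..., 201.
    """
    return tuple(range(shortest, window_length + 1, step))


def window_conditions(window_length: int, window: int = 41, step: int = 10
                      ) -> list[tuple[int, int]]:
    """(start, centre) pairs of the sliding windows, 1-based inclusive.

    Starts are 1, 1+step, ... while start+window-1 <= window_length; the
    centre is start + (window-1)/2. For L=201, window 41, step 10 this yields
    17 windows with centres 21, 31, ..., 181.
    """
    if window > window_length:
        raise DataError("window exceeds the sequence length")
    if step < 1:
        raise DataError("step must be >= 1")
    out = []
    start = 1
    while start + window - 1 <= window_length:
        out.append((start, start + (window - 1) // 2))
        start += step
    return out


# ---------------------------------------------------------------------------
# retraining experiments
# ---------------------------------------------------------------------------

def length_ladder(ds: SeqDataset, model_cfg: ModelConfig, train_cfg: TrainConfig,
                  lengths: tuple[int, ...] | None = None, k: int = 10
                  ) -> list[RegionResult]:
    """Cross-validate the model on centred truncations of each length."""
    if lengths is None:
        lengths = default_ladder_lengths(ds.window_length)
    if max(lengths) > ds.window_length:
        raise DataError("ladder length exceeds the window length")
    results = []
    for length in sorted(lengths):
        sub = truncate_centered(ds, length)
        results.append(RegionResult(length, run_cv(sub, model_cfg, train_cfg, k=k)))
    return results


def window_scan(ds: SeqDataset, model_cfg: ModelConfig, train_cfg: TrainConfig,
                window: int = 41, step: int = 10, k: int = 10
                ) -> list[RegionResult]:
    """Cross-validate the model on each sliding window; condition = centre."""
    results = []
    for start, center in window_conditions(ds.window_length, window, step):
        sub = slice_window(ds, start, window)
        results.append(RegionResult(center, run_cv(sub, model_cfg, train_cfg, k=k)))
    return results


# ---------------------------------------------------------------------------
# positional k-mer enrichment (descriptive)
# ---------------------------------------------------------------------------

def positional_kmer_enrichment(ds: SeqDataset, k_values: tuple[int, ...] = (3, 4, 5)
                               ) -> pd.DataFrame:
    """Most class-skewed exact k-mer per start position, with a one-sided p.

    For every 1-based start position and every k, counts the sequences of
    each class carrying each exact k-mer at that position, picks the k-mer
    with the largest positive-vs-negative proportion gap, and reports the
    one-sided two-proportion z-test p-value (positives enriched). Output is
    descriptive: no multiple-testing correction is applied.
    """
    y = ds.labels
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise DataError("both classes need at least two records")
    seqs = np.array([list(r.sequence) for r in ds])
    rows = []
    for k in k_values:
        if k >= ds.window_length:
            raise DataError(f"k={k} must be smaller than the window length")
        for start0 in range(ds.window_length - k + 1):
            sub = ["".join(s) for s in seqs[:, start0: start0 + k]]
            sub = np.array(sub)
            best = None
            for kmer in np.unique(sub):
                c_pos = int(((sub == kmer) & (y == 1)).sum())
                c_neg = int(((sub == kmer) & (y == 0)).sum())
                gap = c_pos / n_pos - c_neg / n_neg
                if best is None or gap > best[0]:
                    best = (gap, kmer, c_pos, c_neg)
            gap, kmer, c_pos, c_neg = best
            p = _one_sided_proportion_p(c_pos, n_pos, c_neg, n_neg)
            rows.append({"position": start0 + 1, "k": k, "kmer": kmer,
                         "count_pos": c_pos, "count_neg": c_neg,
                         "prop_gap": gap, "p_value": p})
    return pd.DataFrame(rows)


def _one_sided_proportion_p(x1: int, n1: int, x2: int, n2: int) -> float:
    """P(pos proportion > neg proportion) under H0 of equal proportions."""
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0.0:
        return 1.0 if p1 <= p2 else 0.5
    z = (p1 - p2) / se
    return float(norm.sf(z))
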