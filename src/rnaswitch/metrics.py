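"""Prediction-accuracy metrics and landscape export.

Base-pair level accuracy is pooled over a dataset: total sensitivity
(total-SEN) and total positive predictive value (total-PPV) are computed
from summed true/false positive/negative pair counts, with base-pair match
defined as exact index identity (no slippage tolerance). The combined F
score is the harmonic mean of the two proportions, labeled F1. Riboswitch
classification is scored by rank-based ROC/AUC (Mann–Whitney formulation,
ties counted half). The Alternative-Structure-Referenced (ASR) landscape
is an energy-versus-distance table of sampled structures, referenced to an
arbitrary structure (conventionally the alternative rather than the MFE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .sc import Clustering, SampleSet
from .structures import Structure, hamming_distance

__all__ = [
    "PairConfusion",
    "LandscapeRow",
    "pair_confusion",
    "total_metrics",
    "roc_auc",
    "asr_landscape",
    "write_landscape_tsv",
]


@dataclass(frozen=True)
class PairConfusion:
    """Base-pair counts of one predicted-vs-actual structure comparison."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def pair_confusion(pred: Structure, actual: Structure) -> PairConfusion:
    """Exact-index base-pair confusion: TP = shared pairs, FP = predicted
    only, FN = actual only."""
    if pred.length != actual.length:
        raise ValueError(f"length mismatch: {pred.length} vs {actual.length}")
    tp = len(pred.pairs & actual.pairs)
    return PairConfusion(tp, len(pred.pairs) - tp, len(actual.pairs) - tp)


def total_metrics(confusions: list[PairConfusion]) -> dict:
    """Pooled total-SEN (%), total-PPV (%), and F1 over a dataset.

    A metric whose pooled denominator is zero is reported as None.
    """
    if not confusions:
        raise ValueError("need at least one confusion")
    tp = sum(c.tp for c in confusions)
    fp = sum(c.fp for c in confusions)
    fn = sum(c.fn for c in confusions)
    sen = 100.0 * tp / (tp + fn) if tp + fn else None
    ppv = 100.0 * tp / (tp + fp) if tp + fp else None
    if sen is None or ppv is None or sen + ppv == 0.0:
        f1 = None
    else:
        p, q = sen / 100.0, ppv / 100.0
        f1 = 2.0 * p * q / (p + q)
    return {"total_sen": sen, "total_ppv": ppv, "f1": f1}


def roc_auc(scores, labels) -> float:
    """Rank-based AUC (Mann–Whitney; ties counted half)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class LandscapeRow:
    """One point of an energy-versus-distance landscape."""

    distance: int
    energy: float
    cluster: int | None = None


def asr_landscape(
    samples: SampleSet,
    reference: Structure,
    cl: Clustering | None = None,
    *,
    reference_energy: float = float("nan"),
) -> list[LandscapeRow]:
    """Energy landscape referenced to an arbitrary structure.

    One row per sample (base-pair Hamming distance to the reference, its
    energy, and its cluster label if a clustering is given), preceded by
    the reference itself at distance 0. With the MFE structure as the
    reference this is the standard landscape; with the actual alternative
    structure it is the ASR landscape.
    """
    if reference.length != len(samples.sequence):
        raise ValueError(
            f"reference length {reference.length} != sequence "
            f"{len(samples.sequence)}"
        )
    rows = [LandscapeRow(0, reference_energy, None)]
    for k, (s, e, _) in enumerate(samples.samples):
        label = int(cl.labels[k]) if cl is not None else None
        rows.append(LandscapeRow(hamming_distance(s, reference), e, label))
    return rows


def write_landscape_tsv(path, rows: list[LandscapeRow]) -> None:
    with open(path, "w") as fh:
        fh.write("distance\tenergy\tcluster\n")
        for r in rows:
            cluster = "" if r.cluster is None else str(r.cluster)
            fh.write(f"{r.distance}\t{r.energy:.6g}\t{cluster}\n")
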