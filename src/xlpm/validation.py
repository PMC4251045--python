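"""Decoy-based FDR control and the relaxed-specificity ROC analysis.

FDR follows the separate-search target/decoy design: the reversed-sequence
database is searched on its own, and at a score threshold t the estimated
FDR is  #{decoys >= t} / max(1, #{targets >= t}).  Because cross-link
searches yield few true matches, a handful of decoy hits moves this estimate
a lot; thresholds should be read with that caveat in mind.

The relaxed-specificity ROC validates *site* assignment rather than pair
identification: a residue-specific cross-linker (amine-to-amine) is searched
as if one end were non-specific, localizations landing on a known-reactive
residue count as positives, any other residue as false positives, and the
curve sweeps the score threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from xlpm.chem import N_TERMINUS, Site
from xlpm.search import MatchResult


@dataclass(frozen=True)
class ScoredIdentification:
    """A scored result labeled for validation."""

    score: float
    decoy: bool = False
    site_within_specificity: bool | None = None


@dataclass(frozen=True)
class RocCurve:
    """A receiver-operating-characteristic curve with its trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def fdr_threshold(
    targets: Sequence[float], decoys: Sequence[float], alpha: float = 0.05
) -> float:
    """Smallest score threshold controlling the decoy-estimated FDR at alpha.

    Scans every candidate threshold (the union of observed scores); returns
    ``math.inf`` with a warning when no threshold achieves alpha.  With no
    decoy hits at all, every threshold has FDR 0 and the minimum target
    score is returned.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    targets = np.asarray(sorted(targets, reverse=True), dtype=float)
    decoys = np.asarray(sorted(decoys, reverse=True), dtype=float)
    if targets.size == 0:
        warnings.warn("no target identifications; FDR threshold undefined",
                      stacklevel=2)
        return math.inf
    candidates = np.unique(np.concatenate([targets, decoys]))
    best = math.inf
    for t in candidates:  # ascending: the last qualifying t is the smallest kept
        n_t = int(np.sum(targets >= t))
        n_d = int(np.sum(decoys >= t))
        if n_d / max(1, n_t) <= alpha:
            best = min(best, float(t))
    if math.isinf(best):
        warnings.warn(f"no score threshold achieves FDR <= {alpha}", stacklevel=2)
    return best


def q_values(targets: Sequence[float], decoys: Sequence[float]) -> np.ndarray:
    """q-value per target score (input order): the minimum decoy-estimated
    FDR over all thresholds at or below that score, hence monotone
    non-increasing in score."""
    targets = np.asarray(targets, dtype=float)
    decoys = np.asarray(sorted(decoys), dtype=float)
    order = np.argsort(-targets, kind="stable")
    n = targets.size
    fdr = np.empty(n)
    for rank, idx in enumerate(order, start=1):
        t = targets[idx]
        n_d = decoys.size - np.searchsorted(decoys, t, side="left")
        fdr[rank - 1] = n_d / rank
    # q(s) = min FDR over thresholds <= s: cumulative min from the lowest
    # score upward in the descending ranking
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n)
    q[order] = q_sorted
    return q


def relaxed_specificity_roc(
    identifications: Sequence[ScoredIdentification],
) -> RocCurve:
    """ROC over the score threshold with within-specificity sites as the
    positive class.

    Every identification must carry the site-within-specificity flag (set by
    :func:`site_within_specificity` on search output).  Tied scores
    contribute diagonal segments, so the trapezoidal AUC equals the
    Mann-Whitney probability with half-credit for ties.
    """
    labels, scores = [], []
    for ident in identifications:
        if ident.site_within_specificity is None:
            raise ValueError("identification lacks the site-specificity flag")
        labels.append(ident.site_within_specificity)
        scores.append(ident.score)
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("ROC is undefined when all identifications share one class")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(
        fpr=fpr, tpr=tpr, thresholds=thresholds,
        auc=float(_trapezoid_auc(fpr, tpr)),
    )


def site_within_specificity(
    result: MatchResult, residues: frozenset[str] = frozenset("K"),
    allow_nterm: bool = True,
) -> bool:
    """Whether a localized cross-link lies entirely on known-reactive sites.

    Used by the relaxed-specificity analysis: the search runs with one end
    treated as non-specific, then each localization is judged against the
    linker's true chemistry (lysine side chains and, for amine-reactive
    reagents, the protein N-terminus).
    """

    def ok(site: Site, sequence: str) -> bool:
        if site == N_TERMINUS:
            return allow_nterm
        return sequence[int(site) - 1] in residues

    return ok(result.site_a, result.pair.peptide_a.sequence) and ok(
        result.site_b, result.pair.peptide_b.sequence
    )
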