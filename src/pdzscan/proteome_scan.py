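"""Proteome scanning: classify every unique C-terminal tail of a proteome
against a trained model to nominate candidate binders, and validate the
predictions against known-interaction lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, PEPTIDE_LENGTH
from .data_io import ContactMapDef, Domain
from .encoding import encode_pairs
from .evaluation import Metrics, compute_metrics, fisher_overlap_test
from .svm import SVMModel, decide_batch

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """Per-domain scan output.

    ``predictions`` has one row per scanned unique tail: tail, decision
    score, predicted label (+1/-1) and the comma-joined protein ids
    carrying that tail.  Rows are sorted by descending score.
    """

    domain_id: str
    predictions: pd.DataFrame
    n_scanned: int
    n_skipped: int

    @property
    def positive_tails(self) -> list[str]:
        return self.predictions.loc[self.predictions["label"] == 1, "tail"].tolist()

    @property
    def n_positive(self) -> int:
        return int((self.predictions["label"] == 1).sum())


def _encodable(tail: str) -> bool:
    return len(tail) == PEPTIDE_LENGTH and all(ch in AA_INDEX for ch in tail)


def scan(
    model: SVMModel,
    domain: Domain,
    tails: dict[str, list[str]],
    encoding: str = "contact_map",
    cmap: ContactMapDef | None = None,
    table=None,
) -> ScanResult:
    """Classify every unique tail against one domain.

    Tails containing non-standard residues (X, U, B, ...) cannot be
    encoded and are skipped with a warning.  Output is deterministic
    given the model: sorted by descending score, ties broken by tail.
    """
    if not tails:
        raise ValueError("no tails to scan")
    usable = sorted(t for t in tails if _encodable(t))
    skipped = len(tails) - len(usable)
    if skipped:
        logger.warning("domain %s: %d tails with non-standard residues skipped",
                       domain.id, skipped)
    X = encode_pairs([(domain, t) for t in usable], encoding, cmap, table)
    labels, scores = decide_batch(model, X)
    frame = pd.DataFrame({
        "tail": usable,
        "score": scores,
        "label": labels,
        "protein_ids": [",".join(tails[t]) for t in usable],
    }).sort_values(["score", "tail"], ascending=[False, True], ignore_index=True)
    return ScanResult(domain.id, frame, n_scanned=len(usable), n_skipped=skipped)


def validate_scan(
    result: ScanResult,
    known_positives: list[str],
    known_negatives: list[str] | None = None,
) -> dict:
    """Validate a scan against known interactor (and optional non-interactor) tails.

    Returns recall over the known positives, FPR (None unless known
    negatives are supplied), confusion-matrix metrics restricted to the
    known tails, and the Fisher overlap p-value of the positive
    predictions against the scanned universe.
    """
    if not known_positives:
        raise ValueError("known_positives must be non-empty")
    scanned = set(result.predictions["tail"])
    pos = [t for t in set(known_positives) if t in scanned]
    dropped = len(set(known_positives)) - len(pos)
    if dropped:
        logger.warning("%d known positives not in the scanned universe; ignored", dropped)
    neg = []
    if known_negatives:
        neg = [t for t in set(known_negatives) if t in scanned]
        if len(neg) < len(set(known_negatives)):
            logger.warning("%d known negatives not in the scanned universe; ignored",
                           len(set(known_negatives)) - len(neg))

    predicted_pos = set(result.positive_tails)
    known = pos + neg
    truth = np.array([1] * len(pos) + [-1] * len(neg))
    predicted = np.array([1 if t in predicted_pos else -1 for t in known])
    metrics: Metrics | None = None
    recall = float((predicted[: len(pos)] == 1).mean())
    fpr = None
    if neg:
        metrics = compute_metrics(truth, predicted)
        fpr = metrics.fpr
    hits = int((predicted[: len(pos)] == 1).sum())
    p = fisher_overlap_test(hits, len(predicted_pos), len(pos), result.n_scanned)
    return {
        "recall": recall,
        "fpr": fpr,
        "metrics": metrics,
        "fisher_p": p,
        "n_known_positives": len(pos),
        "n_predicted_positive": len(predicted_pos),
    }
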