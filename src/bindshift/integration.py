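"""Combine per-potential variant scores into one TF ranking.

A variant's delta_dbA values form a matrix over motifs x chemical
potentials. Motifs that never pass the direct-binding filter are dropped,
the remaining entries are compressed with the odd log transform

    Sig(x) = log(|x| + 1) * sign(x)

giving the matrix D with D[i, j] = Sig(delta_dbA(motif_i, mu_j)). The
delta_dbA profiles of all motifs lie roughly along a line in mu-space, so
the motif most affected by the variant is the one most extreme along the
first principal axis: with eps the unit eigenvector of the Gram matrix
D'D for its largest eigenvalue (no column centering), the projections
D @ eps are the integrated scores. The projection is defined up to a
global sign, which is recovered per motif from the sign of its mean raw
delta_dbA across the grid. Motifs with positive final score (binding
reduced in the mutant: site destruction) and negative score (binding
gained: site creation) are ranked separately by decreasing magnitude.

Alternative integrations (median rank, median delta, a single mu column)
are provided for comparison, along with the top-20 mean |delta_dbA|
functional-mutation score and cumulative-accuracy evaluation of ranked
predictions against known TFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .affinity import DeltaTable

__all__ = [
    "IntegrationMatrix",
    "RankedPrediction",
    "sig_transform",
    "build_integration_matrix",
    "pca_integrate",
    "alternative_integrations",
    "mutation_score",
    "cumulative_accuracy",
]

log = logging.getLogger(__name__)


def sig_transform(x):
    """Odd log compression Sig(x) = log(|x| + 1) * sign(x) (natural log)."""
    arr = np.asarray(x, dtype=float)
    out = np.log1p(np.abs(arr)) * np.sign(arr)
    return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class IntegrationMatrix:
    """Sig-transformed delta_dbA matrix for the motifs that pass the direct filter."""

    D: np.ndarray  # (n_motifs, n_mu)
    motif_ids: tuple
    tf_names: dict
    mu_grid: tuple
    mean_deltas: pd.Series  # per retained motif, mean raw delta across the grid

    @property
    def n_motifs(self) -> int:
        return self.D.shape[0]


@dataclass(frozen=True)
class RankedPrediction:
    """Signed integrated scores and the two ranking lists for one variant.

    A positive score means binding is higher on the reference allele (the
    variant destroys a site); negative means the variant creates one. The
    positive and negative lists are sorted by decreasing |score|, rank 1
    first; ties are broken lexicographically by motif id. TF-level lists
    collapse motifs to their best rank, case-insensitively by TF name.
    """

    variant_id: str
    scores: pd.Series  # signed, indexed by motif_id
    tf_names: dict
    mean_deltas: pd.Series
    positive: tuple  # motif ids, rank order
    negative: tuple
    tf_positive: tuple  # TF names, rank order
    tf_negative: tuple

    def tf_rank(self, tf_name: str, direction: Optional[str] = None) -> Optional[int]:
        """1-based best rank of a TF, in one list or the better of both.

        ``direction`` is "positive", "negative" or None (either list).
        Returns None when the TF does not appear.
        """
        needle = tf_name.lower()
        ranks = []
        lists = {"positive": self.tf_positive, "negative": self.tf_negative}
        for name, lst in lists.items():
            if direction is not None and name != direction:
                continue
            for i, tf in enumerate(lst):
                if tf.lower() == needle:
                    ranks.append(i + 1)
                    break
        return min(ranks) if ranks else None

    def to_frame(self) -> pd.DataFrame:
        """Long-form ranking table: direction, rank, tf_name, motif_id, score, mean_delta."""
        rows = []
        for direction, lst in (("+", self.positive), ("-", self.negative)):
            for i, mid in enumerate(lst):
                rows.append(
                    {
                        "direction": direction,
                        "rank": i + 1,
                        "tf_name": self.tf_names.get(mid, mid),
                        "motif_id": mid,
                        "integrated_score": self.scores[mid],
                        "mean_delta": self.mean_deltas.get(mid, np.nan),
                    }
                )
        return pd.DataFrame(
            rows, columns=["direction", "rank", "tf_name", "motif_id", "integrated_score", "mean_delta"]
        )


def build_integration_matrix(table: DeltaTable, min_direct: int = 1) -> IntegrationMatrix:
    """Pivot a DeltaTable into the Sig-transformed motif x mu matrix.

    Motifs flagged direct in fewer than ``min_direct`` grid columns are
    dropped. An empty result (no direct TF) is returned as a 0-row matrix,
    not raised.
    """
    frame = table.frame
    tf_names = table.tf_names()
    if frame.empty:
        return IntegrationMatrix(
            D=np.zeros((0, len(table.mu_grid))),
            motif_ids=(),
            tf_names=tf_names,
            mu_grid=table.mu_grid,
            mean_deltas=pd.Series(dtype=float),
        )
    deltas = frame.pivot(index="motif_id", columns="mu", values="delta")
    deltas = deltas.reindex(columns=list(table.mu_grid)).sort_index()
    direct = frame.pivot(index="motif_id", columns="mu", values="direct").reindex(deltas.index)
    keep = direct.sum(axis=1) >= min_direct
    retained = deltas.loc[keep]
    if retained.isna().any().any():
        raise ValueError("delta table does not cover a full motif x mu grid")
    return IntegrationMatrix(
        D=sig_transform(retained.to_numpy()),
        motif_ids=tuple(retained.index),
        tf_names=tf_names,
        mu_grid=table.mu_grid,
        mean_deltas=retained.mean(axis=1),
    )


def _make_prediction(
    scores: pd.Series, tf_names: dict, mean_deltas: pd.Series, variant_id: str = ""
) -> RankedPrediction:
    def ordered(ids: Iterable[str]) -> tuple:
        return tuple(sorted(ids, key=lambda mid: (-abs(scores[mid]), mid)))

    positive = ordered(scores.index[scores > 0])
    negative = ordered(scores.index[scores < 0])

    def collapse(lst: tuple) -> tuple:
        seen, out = set(), []
        for mid in lst:
            tf = tf_names.get(mid, mid)
            if tf.lower() not in seen:
                seen.add(tf.lower())
                out.append(tf)
        return tuple(out)

    return RankedPrediction(
        variant_id=variant_id,
        scores=scores,
        tf_names=tf_names,
        mean_deltas=mean_deltas,
        positive=positive,
        negative=negative,
        tf_positive=collapse(positive),
        tf_negative=collapse(negative),
    )


def _empty_prediction(tf_names: dict, variant_id: str) -> RankedPrediction:
    empty = pd.Series(dtype=float)
    return _make_prediction(empty, tf_names, empty, variant_id)


def pca_integrate(
    M: IntegrationMatrix,
    mean_deltas: Optional[pd.Series] = None,
    variant_id: str = "",
) -> RankedPrediction:
    """Project the Sig matrix on its first principal axis and recover signs.

    eps is the unit eigenvector of D'D with the largest eigenvalue (computed
    via the SVD of D; no column centering). Its global sign is fixed by a
    non-negative dot product with the column-sum vector. The final score of
    motif i is sign(mean_delta_i) * |(D eps)_i|; motifs with zero mean delta
    score 0 and appear in neither list.
    """
    md = M.mean_deltas if mean_deltas is None else mean_deltas.reindex(list(M.motif_ids))
    if M.n_motifs == 0:
        return _empty_prediction(M.tf_names, variant_id)
    D = M.D
    if not np.any(D):
        scores = pd.Series(0.0, index=list(M.motif_ids))
        return _make_prediction(scores, M.tf_names, md, variant_id)
    _, _, vt = np.linalg.svd(D, full_matrices=False)
    eps = vt[0]
    if eps @ D.sum(axis=0) < 0:
        eps = -eps
    proj = D @ eps
    signed = np.sign(md.to_numpy()) * np.abs(proj)
    scores = pd.Series(signed, index=list(M.motif_ids))
    return _make_prediction(scores, M.tf_names, md, variant_id)


def alternative_integrations(
    table: DeltaTable,
    method: str,
    min_direct: int = 1,
    mu: float = 0.0,
    variant_id: str = "",
) -> RankedPrediction:
    """Baseline score integrations: median_rank, median_delta or single_mu.

    ``median_rank`` ranks motifs within each mu column by decreasing |delta|
    and scores by the (negated) median of those ranks; ``median_delta``
    scores by the signed median delta across the grid; ``single_mu`` uses
    the delta at one stated grid value. Filtering matches
    :func:`build_integration_matrix`.
    """
    M = build_integration_matrix(table, min_direct=min_direct)
    if M.n_motifs == 0:
        return _empty_prediction(M.tf_names, variant_id)
    deltas = (
        table.frame[table.frame["motif_id"].isin(M.motif_ids)]
        .pivot(index="motif_id", columns="mu", values="delta")
        .reindex(index=list(M.motif_ids), columns=list(M.mu_grid))
    )
    md = M.mean_deltas
    if method == "median_delta":
        med = deltas.median(axis=1)
        scores = med
    elif method == "median_rank":
        ranks = deltas.abs().rank(axis=0, ascending=False, method="average")
        mr = ranks.median(axis=1)
        magnitude = len(deltas) + 1 - mr  # larger = better median rank
        scores = np.sign(md) * magnitude
    elif method == "single_mu":
        if mu not in deltas.columns:
            raise ValueError(f"mu = {mu} is not a grid column; available: {list(deltas.columns)}")
        scores = deltas[mu]
    else:
        raise ValueError(f"unknown integration method {method!r}")
    return _make_prediction(pd.Series(scores, index=deltas.index), M.tf_names, md, variant_id)


def mutation_score(prediction: RankedPrediction, table: DeltaTable, k: int = 20) -> float:
    """Functional-mutation score: mean |delta_dbA| of the top-k TFs per direction.

    |delta_dbA| is first averaged over the mu grid per motif; the score is
    the mean over the union of the top-k positive and top-k negative motifs
    (all of them when fewer than k are available; 0 for an empty prediction).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ids = list(prediction.positive[:k]) + list(prediction.negative[:k])
    if not ids:
        return 0.0
    mad = table.mean_abs_delta()
    return float(mad.loc[ids].mean())


def cumulative_accuracy(
    cases: Sequence[tuple],
    max_rank: Optional[int] = None,
) -> np.ndarray:
    """Fraction of cases whose true TF is recovered at or below each rank.

    ``cases`` holds (RankedPrediction, true TF name[, direction]) tuples;
    with no direction the better rank over both lists counts. The returned
    curve[r - 1] is the fraction recovered at rank <= r; it is
    non-decreasing and <= 1. True TFs absent from a prediction count as
    never recovered (warned).
    """
    ranks = []
    longest = 1
    for case in cases:
        pred, true_tf = case[0], case[1]
        direction = case[2] if len(case) > 2 else None
        r = pred.tf_rank(true_tf, direction)
        if r is None:
            log.warning("true TF %r not recovered for variant %r", true_tf, pred.variant_id)
        ranks.append(r)
        longest = max(longest, len(pred.tf_positive), len(pred.tf_negative))
    if max_rank is None:
        max_rank = longest
    curve = np.zeros(max_rank)
    n = len(cases)
    for r in range(1, max_rank + 1):
        curve[r - 1] = sum(1 for x in ranks if x is not None and x <= r) / n if n else 0.0
    return curve
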