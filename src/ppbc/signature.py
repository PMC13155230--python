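"""Weighted gene-signature scoring and score-marker correlation.

The immune-exhaustion score of a sample is a weighted mean of log2
expression over the signature genes, with signs of the weights encoding
direction:

    score_i = sum_g w_g x_{g,i} / sum_g |w_g|

Genes absent from the matrix are dropped and their weight removed from the
denominator (the mapping audit records which). Published exhaustion gene
lists/weights are supplied by the user as a two-column (gene, weight) file; a
toy signature ships with the test suite. Expression is assumed
log2-normalized; a loud warning is emitted if the input looks like raw
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SignatureDefinition", "ScoreTable", "sig_score",
           "correlate_with_score", "bh_adjust"]

logger = logging.getLogger(__name__)


@dataclass
class SignatureDefinition:
    genes: list[str]
    weights: list[float]

    def __post_init__(self):
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        if not any(w != 0 for w in self.weights):
            raise ValueError("signature needs at least one nonzero weight")

    @classmethod
    def from_tsv(cls, path) -> "SignatureDefinition":
        t = pd.read_csv(path, sep="\t")
        return cls(genes=t.iloc[:, 0].astype(str).tolist(),
                   weights=t.iloc[:, 1].astype(float).tolist())


@dataclass
class ScoreTable:
    scores: pd.Series  # sample_id -> score
    genes_used: list[str]
    genes_missing: list[str] = field(default_factory=list)
    correlations: pd.DataFrame | None = None  # marker, r, p, q_bh


def _warn_if_counts(expr: pd.DataFrame) -> None:
    vals = expr.to_numpy()
    if vals.size and np.allclose(vals, np.round(vals)) and vals.max() > 50:
        logger.warning(
            "expression matrix looks like raw counts (integer-valued, max "
            "%.0f); scores expect log2-normalized input", vals.max()
        )


def sig_score(expr: pd.DataFrame, sig: SignatureDefinition,
              missing_policy: str = "drop") -> ScoreTable:
    """Per-sample weighted-mean signature score on a sample x gene matrix.

    ``missing_policy='drop'`` removes absent genes and their weights from the
    denominator; ``'error'`` refuses if any signature gene is absent. Scores
    are invariant to gene ordering and to uniform rescaling of all weights.
    """
    if missing_policy not in ("drop", "error"):
        raise ValueError("missing_policy must be 'drop' or 'error'")
    _warn_if_counts(expr)
    present = [g for g in sig.genes if g in expr.columns]
    absent = [g for g in sig.genes if g not in expr.columns]
    if absent and missing_policy == "error":
        raise KeyError(f"signature genes absent from matrix: {absent}")
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    w = np.array([w for g, w in zip(sig.genes, sig.weights) if g in expr.columns])
    denom = np.abs(w).sum()
    if denom == 0:
        raise ValueError("all present signature genes have zero weight")
    scores = expr[present].to_numpy() @ w / denom
    return ScoreTable(
        scores=pd.Series(scores, index=expr.index, name="score"),
        genes_used=present, genes_missing=absent,
    )


def correlate_with_score(expr_subset: pd.DataFrame, scores: ScoreTable,
                         groups: pd.Series | None = None) -> pd.DataFrame:
    """Pearson correlation of each marker column with the signature score.

    Returns a frame with columns ``marker, r, p_value, q_bh, n`` (plus
    ``group`` when a per-sample stratification is given, q-values computed
    within stratum). Zero-variance markers get NaN correlations (logged).
    Sample identifiers must align with the score index.
    """
    s = scores.scores
    expr_subset = expr_subset.loc[s.index]
    strata = ([(None, expr_subset, s)] if groups is None else
              [(g, expr_subset[groups.loc[s.index] == g],
                s[groups.loc[s.index] == g])
               for g in pd.unique(groups.loc[s.index].dropna())])
    frames = []
    for label, mat, sc in strata:
        if len(mat) < 3:
            raise ValueError("need at least 3 samples per stratum")
        rows = []
        for m in mat.columns:
            x = mat[m].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(sc.to_numpy()) == 0:
                logger.warning("zero variance for marker %s; r absent", m)
                rows.append({"marker": m, "r": np.nan, "p_value": np.nan,
                             "n": len(mat)})
                continue
            r, p = stats.pearsonr(x, sc.to_numpy())
            rows.append({"marker": m, "r": float(r), "p_value": float(p),
                         "n": len(mat)})
        frame = pd.DataFrame(rows)
        ok = frame["p_value"].notna()
        frame["q_bh"] = np.nan
        if ok.any():
            frame.loc[ok, "q_bh"] = bh_adjust(frame.loc[ok, "p_value"].to_numpy())
        if label is not None:
            frame.insert(0, "group", label)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be a vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
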