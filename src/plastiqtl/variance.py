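"""Per-transcript ANOVA variance partitioning and profile clustering.

Each transcript's abundance is decomposed with the fixed-effect linear model

    abundance ~ replicate + genotype + treatment + genotype:treatment

under sum-to-zero factor contrasts, reporting type III sums of squares: the
increase in residual SS when a term's columns are dropped from the otherwise
full design. Replicate is fit as a fixed blocking factor; for a two-level
replicate this captures the replicate-shift structure an experimental-
replicate random effect would model, while keeping the SS decomposition well
defined. Proportions are taken against the total corrected SS, so in a
balanced complete design the five proportions (replicate, genotype,
treatment, GxT, residual) sum to one.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_io import ExpressionDataset

logger = logging.getLogger(__name__)

TERMS = ("replicate", "genotype", "treatment", "GxT")
PROP_COLS = ["prop_replicate", "prop_genotype", "prop_treatment",
             "prop_GxT", "prop_residual"]


@dataclass
class VarianceDecomposition:
    """Type III SS per term per transcript, with proportions of total SS.

    ``table`` is indexed by transcript with columns ``SS_<term>``,
    ``SS_residual``, ``SS_total``, ``prop_<term>``, ``prop_residual`` and a
    boolean ``degenerate`` flag for zero-variance transcripts (their
    proportions are reported as 0).
    """

    table: pd.DataFrame

    def profiles(self, include_degenerate: bool = False) -> pd.DataFrame:
        t = self.table if include_degenerate else self.table[~self.table["degenerate"]]
        return t[PROP_COLS]


def _sum_contrast(levels: pd.Series) -> np.ndarray:
    """Sum-to-zero (effects) coding: k levels -> n x (k-1) matrix."""
    cats = sorted(pd.unique(levels))
    k = len(cats)
    if k < 2:
        return np.empty((len(levels), 0))
    cols = np.zeros((len(levels), k - 1))
    arr = np.asarray(levels)
    for j, lev in enumerate(cats[:-1]):
        cols[arr == lev, j] = 1.0
    cols[arr == cats[-1], :] = -1.0
    return cols


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual SS of Y's columns after projection on span(X), via QR."""
    Q, R = np.linalg.qr(X)
    # discard dependent directions so rank deficiency cannot inflate the fit
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Qy = Q[:, keep].T @ Y
    return np.sum(Y * Y, axis=0) - np.sum(Qy * Qy, axis=0)


def decompose_variance(dataset: ExpressionDataset) -> VarianceDecomposition:
    """Fit the replicate+genotype+treatment+GxT model to every transcript.

    Requires >= 2 genotypes, both treatments and >= 2 replicates; a factor
    that collapses to one level contributes SS = 0 with a warning. A design
    whose full model matrix is rank deficient beyond single-level collapse
    (e.g. an empty genotype x treatment cell) raises ``ValueError``.
    """
    meta = dataset.metadata
    Y = dataset.values.to_numpy(float)
    n = Y.shape[0]

    blocks = {"intercept": np.ones((n, 1))}
    rep = _sum_contrast(meta["replicate"])
    gen = _sum_contrast(meta["genotype"])
    trt = _sum_contrast(meta["treatment"])
    for name, block in (("replicate", rep), ("genotype", gen), ("treatment", trt)):
        if block.shape[1] == 0:
            logger.warning("factor %s has a single level; its SS is 0", name)
    blocks["replicate"] = rep
    blocks["genotype"] = gen
    blocks["treatment"] = trt
    if gen.shape[1] and trt.shape[1]:
        gxt = np.einsum("ij,ik->ijk", gen, trt).reshape(n, -1)
    else:
        gxt = np.empty((n, 0))
    blocks["GxT"] = gxt

    X_full = np.hstack([blocks[k] for k in ("intercept",) + TERMS])
    expected_rank = X_full.shape[1]
    if np.linalg.matrix_rank(X_full) < expected_rank:
        raise ValueError(
            "singular design: genotype/treatment/replicate structure leaves "
            "the full model rank deficient (empty cell or confounded factor)"
        )

    rss_full = _rss(X_full, Y)
    total = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    degenerate = total <= 1e-12 * max(1.0, float(np.abs(Y).max()) ** 2)

    out = pd.DataFrame(index=dataset.values.columns)
    for term in TERMS:
        if blocks[term].shape[1] == 0:
            ss = np.zeros(Y.shape[1])
        else:
            X_reduced = np.hstack(
                [blocks[k] for k in ("intercept",) + TERMS if k != term]
            )
            ss = _rss(X_reduced, Y) - rss_full
        out[f"SS_{term}"] = np.maximum(ss, 0.0)
    out["SS_residual"] = np.maximum(rss_full, 0.0)
    out["SS_total"] = total
    safe_total = np.where(degenerate, 1.0, total)
    for term in list(TERMS) + ["residual"]:
        prop = out[f"SS_{term}"] / safe_total
        out[f"prop_{term}"] = np.where(degenerate, 0.0, np.clip(prop, 0.0, 1.0))
    out["degenerate"] = degenerate
    if degenerate.any():
        logger.warning("%d zero-variance transcript(s) flagged degenerate",
                       int(degenerate.sum()))
    return VarianceDecomposition(out)


def cluster_variance_profiles(decomposition: VarianceDecomposition, k: int,
                              seed: int, n_restarts: int = 10):
    """k-means over the five-component variance-proportion vectors.

    Degenerate transcripts are excluded. Returns ``(labels, centroids)``:
    labels as a Series indexed by transcript, centroids as a k x 5 DataFrame.
    """
    profiles = decomposition.profiles()
    if len(profiles) < k:
        raise ValueError(f"k={k} exceeds {len(profiles)} usable transcripts")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy())
    return (pd.Series(labels, index=profiles.index, name="cluster"),
            pd.DataFrame(km.cluster_centers_, columns=PROP_COLS))


def summarize_variance(decomposition: VarianceDecomposition) -> pd.Series:
    """Mean proportion of variance per model term across usable transcripts."""
    profiles = decomposition.profiles()
    if profiles.empty:
        raise ValueError("all transcripts are degenerate; nothing to summarize")
    return profiles.mean(axis=0)
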