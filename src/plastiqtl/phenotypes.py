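"""Expression phenotypes: treatment means, delta plasticity, PCA, transgression.

Three phenotypes are built per transcript per genotype: the mean abundance
under control, the mean under SA, and delta — the treatment difference
scaled by the treatment mean,

    delta = (SA - control) / ((SA + control) / 2),

a symmetric, scale-invariant plasticity index bounded by [-2, 2] for
non-negative abundances. Transgressive segregation is quantified as the
fraction of RIL phenotype values falling strictly outside the range set by
the two parents.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_io import ExpressionDataset, PHENOTYPES

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeSet:
    """Genotype x transcript tables for the control, SA and delta phenotypes."""

    control: pd.DataFrame
    SA: pd.DataFrame
    delta: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.control.index.equals(self.SA.index)
                and self.control.columns.equals(self.SA.columns)):
            raise ValueError("control and SA tables are not aligned")

    def __getitem__(self, name: str) -> pd.DataFrame:
        if name not in PHENOTYPES:
            raise KeyError(name)
        return getattr(self, name)

    def items(self):
        return [(p, self[p]) for p in PHENOTYPES]


def genotype_means(dataset: ExpressionDataset) -> dict:
    """Mean abundance over replicates per (genotype, treatment) cell.

    Returns ``{"control": table, "SA": table}`` with genotypes as rows. A
    genotype missing all samples for a treatment yields missing values with
    a warning.
    """
    meta = dataset.metadata
    out = {}
    genotypes = dataset.genotypes
    for treatment in ("control", "SA"):
        mask = (meta["treatment"] == treatment).to_numpy()
        sub = dataset.values.loc[mask]
        grouped = sub.groupby(meta.loc[mask, "genotype"].to_numpy()).mean()
        grouped = grouped.reindex(genotypes)
        absent = grouped.index[grouped.isna().all(axis=1)]
        if len(absent):
            logger.warning("no %s samples for genotype(s) %s",
                           treatment, list(absent[:5]))
        out[treatment] = grouped
    return out


def compute_delta(control: pd.DataFrame, sa: pd.DataFrame,
                  floor: float = 1e-8) -> pd.DataFrame:
    """Plasticity index (SA - control) / ((SA + control)/2) per cell.

    Cells whose cross-treatment mean falls below ``floor`` in absolute value
    are set missing (the ratio is numerically unstable there); the count is
    logged.
    """
    if control.shape != sa.shape or not control.index.equals(sa.index) \
            or not control.columns.equals(sa.columns):
        raise ValueError("control and SA tables are not aligned")
    mean = (sa + control) / 2.0
    unstable = mean.abs() < floor
    n_unstable = int(unstable.to_numpy().sum())
    if n_unstable:
        logger.info("delta: %d cell(s) below denominator floor set missing",
                    n_unstable)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (sa - control) / mean
    return delta.mask(unstable)


def build_phenotypes(dataset: ExpressionDataset, floor: float = 1e-8) -> PhenotypeSet:
    """Construct the three expression phenotypes from raw samples."""
    means = genotype_means(dataset)
    delta = compute_delta(means["control"], means["SA"], floor=floor)
    return PhenotypeSet(means["control"], means["SA"], delta)


def pca_transcriptomes(table: pd.DataFrame, n_components: int = 2,
                       exclude_transcripts=None):
    """Column-centered PCA of a genotype x transcript table.

    ``exclude_transcripts`` removes a transcript set before fitting — used to
    re-run the ordination without cis-eQTL-bearing genes and ask whether the
    RIL-vs-parent spread survives. Returns ``(scores, loadings,
    explained_variance_ratio)``.
    """
    if exclude_transcripts is not None:
        keep = [c for c in table.columns if c not in set(exclude_transcripts)]
        if not keep:
            raise ValueError("exclusion set removes every transcript")
        table = table[keep]
    X = table.dropna(axis=1, how="any").to_numpy(float)
    if X.shape[1] == 0:
        raise ValueError("no complete transcripts to decompose")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant matrix has no principal components")
    n_components = min(n_components, min(X.shape) - 1 if min(X.shape) > 1 else 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    score_df = pd.DataFrame(scores, index=table.index,
                            columns=[f"PC{i + 1}" for i in range(n_components)])
    load_df = pd.DataFrame(pca.components_.T,
                           index=table.dropna(axis=1, how="any").columns,
                           columns=score_df.columns)
    return score_df, load_df, pca.explained_variance_ratio_


def transgression_summary(phenotypes: PhenotypeSet, parent_ids) -> pd.DataFrame:
    """Fraction of RILs strictly outside the parental range, per phenotype.

    Ties with a parental value count as inside (conservative). Returns one
    row per transcript with columns ``<phenotype>_lo``, ``<phenotype>_hi``
    (the parental range) and ``<phenotype>_frac_outside``.
    """
    pa, pb = parent_ids
    out = {}
    for name, table in phenotypes.items():
        if pa not in table.index or pb not in table.index:
            raise ValueError(f"parent(s) {parent_ids} absent from {name} table")
        parents = table.loc[[pa, pb]]
        lo, hi = parents.min(axis=0), parents.max(axis=0)
        rils = table.drop(index=[pa, pb])
        outside = rils.lt(lo, axis=1) | rils.gt(hi, axis=1)
        frac = outside.sum(axis=0) / rils.notna().sum(axis=0)
        out[f"{name}_lo"] = lo
        out[f"{name}_hi"] = hi
        out[f"{name}_frac_outside"] = frac
    return pd.DataFrame(out)
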