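"""Single-QTL Haley-Knott genome scans with LOD peak calling.

Each transcript x phenotype pair is regressed, marker by marker, on the
expected dosage of the parent-2 allele; the LOD score is the regression
likelihood ratio

    LOD = (n/2) * log10(RSS0 / RSS1),

with RSS0 the intercept-only residual sum of squares. Missing genotype
calls are imputed as conditional expectations under the selfed-RIL Markov
chain (transition R = 2r/(1+2r) per marker interval), so complete data pass
through as exact 0/1 dosages. Scans run at observed markers only — at the
marker densities this analysis assumes, a pseudomarker grid adds nothing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneticMap, GenotypeMatrix, PHENOTYPES
from .phenotypes import PhenotypeSet
from .simulate import ril_R

logger = logging.getLogger(__name__)


@dataclass
class EQTLRecord:
    """A detected LOD peak for one transcript and one expression phenotype."""

    transcript: str
    phenotype: str  # control | SA | delta
    chromosome: str
    position_cM: float
    lod: float
    slope_sign: int  # direction of the parent-2 (B) allele effect
    r2: float = np.nan  # filled by the classify stage

    def to_dict(self) -> dict:
        return {"transcript": self.transcript, "phenotype": self.phenotype,
                "chromosome": self.chromosome, "position_cM": self.position_cM,
                "lod": self.lod, "slope_sign": self.slope_sign, "r2": self.r2}


@dataclass
class LODCurve:
    """Per-marker LOD scores for one (transcript, phenotype) pair."""

    lod: np.ndarray        # aligned to map marker order
    slope: np.ndarray
    n: int
    degenerate: bool = False  # zero phenotypic variance


def genotype_probabilities(genotypes: GenotypeMatrix,
                           gmap: GeneticMap | None = None) -> pd.DataFrame:
    """Expected parent-2 allele dosage per line per marker.

    Observed calls give exact 0/1. A missing call between two flanking
    observations at distances dL and dR is the Markov conditional

        g = T(dL)[L,B] * T(dR)[B,R] / sum_s T(dL)[L,s] * T(dR)[s,R]

    with the two-state transition T(d) having off-diagonal ``ril_R(d)``.
    A terminal gap conditions on the single available flank; a chromosome
    with no calls at all gives 0.5 everywhere.
    """
    gmap = gmap or genotypes.map
    dosage = genotypes.dosage_observed()
    if not np.isnan(dosage).any():
        return pd.DataFrame(dosage, index=genotypes.lines, columns=gmap.markers)

    pos_all = gmap.table["position_cM"].to_numpy(float)
    out = dosage.copy()
    for chrom in gmap.chromosomes:
        idx = gmap.chrom_slice(chrom)
        pos = pos_all[idx]
        sub = dosage[:, idx]
        for i in range(sub.shape[0]):
            row = sub[i]
            miss = np.isnan(row)
            if not miss.any():
                continue
            obs = np.flatnonzero(~miss)
            if obs.size == 0:
                out[i, idx] = 0.5
                continue
            for j in np.flatnonzero(miss):
                left = obs[obs < j]
                right = obs[obs > j]
                if left.size and right.size:
                    l, r = left[-1], right[0]
                    RL, RR = ril_R(pos[j] - pos[l]), ril_R(pos[r] - pos[j])
                    # P(state at j | flanks) over the two-state chain
                    pL = np.array([1 - RL, RL]) if row[l] == 0 else np.array([RL, 1 - RL])
                    pR = np.array([1 - RR, RR]) if row[r] == 0 else np.array([RR, 1 - RR])
                    w = pL * pR
                    out[i, idx[j]] = w[1] / w.sum()
                elif left.size:
                    l = left[-1]
                    R = ril_R(pos[j] - pos[l])
                    out[i, idx[j]] = R if row[l] == 0 else 1 - R
                else:
                    r = right[0]
                    R = ril_R(pos[r] - pos[j])
                    out[i, idx[j]] = R if row[r] == 0 else 1 - R
    return pd.DataFrame(out, index=genotypes.lines, columns=gmap.markers)


def scan1_hk(probabilities: pd.DataFrame, phenotype: pd.Series,
             lod_cap: float = 50.0) -> LODCurve:
    """Haley-Knott regression of one phenotype on dosage at every marker.

    Genotypes with a missing phenotype are dropped. A perfect fit (RSS1
    underflow) yields the configured LOD cap rather than infinity; a
    zero-variance phenotype yields an all-zero, flagged curve.
    """
    common = probabilities.index.intersection(phenotype.dropna().index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} genotypes with phenotype; need >= 3")
    G = probabilities.loc[common].to_numpy(float)
    y = phenotype.loc[common].to_numpy(float)
    n = len(y)

    yc = y - y.mean()
    rss0 = float(yc @ yc)
    n_markers = G.shape[1]
    if rss0 <= 1e-300:
        return LODCurve(np.zeros(n_markers), np.zeros(n_markers), n, degenerate=True)

    Gc = G - G.mean(axis=0)
    sxx = np.sum(Gc * Gc, axis=0)
    sxy = Gc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    rss1 = rss0 - slope * sxy  # = RSS0 - Sxy^2/Sxx
    rss1 = np.maximum(rss1, 0.0)
    with np.errstate(divide="ignore"):
        lod = (n / 2.0) * np.log10(rss0 / np.where(rss1 > 0, rss1, 1.0))
    # only the perfect-fit (RSS1 underflow) case is capped; large finite LODs
    # are real and must keep their ordering so the peak lands at the locus
    lod = np.where(rss1 > 0, np.maximum(lod, 0.0), max(lod_cap, 0.0))
    return LODCurve(lod, slope, n)


def find_peaks(curve: LODCurve, gmap: GeneticMap, lod_threshold: float,
               min_peak_separation_cM: float, transcript: str,
               phenotype_name: str, peak_drop: float = 1.5) -> list:
    """Call LOD peaks per chromosome with greedy proximity suppression.

    Local maxima at or above the threshold are accepted in order of
    descending LOD (ties broken by smaller cM), suppressing any candidate
    within ``min_peak_separation_cM`` of an already-accepted peak. A
    candidate must additionally be separated from every accepted peak by a
    valley dropping at least ``peak_drop`` LOD below the candidate —
    otherwise it is a shoulder of the same QTL, not a second locus.
    """
    if curve.degenerate:
        return []
    records = []
    pos_all = gmap.table["position_cM"].to_numpy(float)
    for chrom in gmap.chromosomes:
        idx = gmap.chrom_slice(chrom)
        lod = curve.lod[idx]
        pos = pos_all[idx]
        # local maxima incl. chromosome ends; plateaus keep their first index
        above = lod >= lod_threshold
        left_ok = np.r_[True, lod[1:] > lod[:-1]]
        right_ok = np.r_[lod[:-1] >= lod[1:], True]
        cand = [int(j) for j in np.flatnonzero(above & left_ok & right_ok)]
        if not cand and above.any():  # flat-topped curve starting at index 0
            cand = [int(np.flatnonzero(above)[0])]
        cand.sort(key=lambda j: (-lod[j], pos[j]))
        accepted = []
        for j in cand:
            ok = True
            for k in accepted:
                if abs(pos[j] - pos[k]) <= min_peak_separation_cM:
                    ok = False
                    break
                lo, hi = min(j, k), max(j, k)
                if lod[lo:hi + 1].min() > lod[j] - peak_drop:
                    ok = False  # no valley: shoulder of an accepted peak
                    break
            if ok:
                accepted.append(j)
        for j in sorted(accepted, key=lambda j: pos[j]):
            records.append(EQTLRecord(
                transcript=transcript, phenotype=phenotype_name,
                chromosome=chrom, position_cM=float(pos[j]),
                lod=float(lod[j]),
                slope_sign=int(np.sign(curve.slope[idx[j]])) or 1,
            ))
    return records


def scan_all(probabilities: pd.DataFrame, phenotypes: PhenotypeSet,
             gmap: GeneticMap, lod_threshold: float = 2.0,
             min_peak_separation_cM: float = 11.0,
             lod_cap: float = 50.0, peak_drop: float = 1.5) -> pd.DataFrame:
    """Scan every transcript x {control, SA, delta} and collect peak records.

    Returns a DataFrame with one row per detected eQTL (columns transcript,
    phenotype, chromosome, position_cM, lod, slope_sign, r2).
    """
    records = []
    counts = dict.fromkeys(PHENOTYPES, 0)
    for name, table in phenotypes.items():
        common = probabilities.index.intersection(table.index)
        if len(common) == 0:
            raise ValueError(f"no genotypes shared between dosages and {name} table")
        probs = probabilities.loc[common]
        for transcript in table.columns:
            y = table.loc[common, transcript]
            if y.dropna().shape[0] < 3:
                continue
            curve = scan1_hk(probs, y, lod_cap=lod_cap)
            recs = find_peaks(curve, gmap, lod_threshold,
                              min_peak_separation_cM, transcript, name,
                              peak_drop=peak_drop)
            counts[name] += len(recs)
            records.extend(recs)
    logger.info("eQTLs detected: %s",
                ", ".join(f"{k}={v}" for k, v in counts.items()))
    if not records:
        return pd.DataFrame(columns=["transcript", "phenotype", "chromosome",
                                     "position_cM", "lod", "slope_sign", "r2"])
    return pd.DataFrame([r.to_dict() for r in records])
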