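"""cis/trans labelling, cross-phenotype eQTL merging, effect sizes, annotation.

An eQTL is cis when it lies on the transcript's own chromosome within a
fixed genetic window (default 10 cM, boundary inclusive) of the transcript's
interpolated map position; otherwise trans. eQTLs detected for the same
transcript in different expression phenotypes (control, SA, delta) that map
within the merge window (default 5.5 cM, single linkage) are collapsed into
one locus whose consensus position is the mean of the member positions.
Effect size is the R^2 of the phenotype regressed on dosage at the marker
nearest the consensus; merged records carry per-phenotype R^2 and their
mean. Trans loci are optionally annotated with paralog proximity and
named-hotspot membership.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GeneticMap, PHENOTYPES
from .phenotypes import PhenotypeSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene positions
# ---------------------------------------------------------------------------

def interpolate_gene_positions(genes: pd.DataFrame,
                               anchors: pd.DataFrame) -> pd.DataFrame:
    """Piecewise-linear bp -> cM interpolation of gene positions.

    ``genes`` needs columns transcript, chromosome, bp; ``anchors`` needs
    marker, chromosome, bp, cM with >= 2 anchors per chromosome, strictly
    increasing bp and non-decreasing cM. Genes beyond the anchored span are
    clamped to the terminal anchor's cM (logged).
    """
    out_rows = []
    anchor_by_chrom = {}
    for chrom, sub in anchors.groupby("chromosome", sort=False):
        sub = sub.sort_values("bp")
        bp = sub["bp"].to_numpy(float)
        cm = sub["cM"].to_numpy(float)
        if len(bp) < 2:
            raise ValueError(f"chromosome {chrom!r} has < 2 anchors")
        if not (np.diff(bp) > 0).all():
            raise ValueError(f"anchor bp not strictly increasing on {chrom!r}")
        if (np.diff(cm) < 0).any():
            raise ValueError(f"anchor cM decreasing on chromosome {chrom!r}")
        anchor_by_chrom[chrom] = (bp, cm)

    n_clamped = 0
    for _, g in genes.iterrows():
        chrom = g["chromosome"]
        if chrom not in anchor_by_chrom:
            raise ValueError(
                f"gene {g['transcript']!r} lies on chromosome {chrom!r} "
                "which has no anchors"
            )
        bp, cm = anchor_by_chrom[chrom]
        x = float(g["bp"])
        if x < bp[0] or x > bp[-1]:
            n_clamped += 1
        pos = float(np.interp(x, bp, cm))  # np.interp clamps outside the span
        out_rows.append({"transcript": g["transcript"], "chromosome": chrom,
                         "bp": x, "cM": pos})
    if n_clamped:
        logger.warning("%d gene(s) outside anchor span clamped to terminal cM",
                       n_clamped)
    return pd.DataFrame(out_rows)


def classify_cis_trans(chromosome, position_cM: float, gene_chromosome,
                       gene_cM: float | None, window: float = 10.0) -> str:
    """Label one eQTL cis/trans relative to its transcript's map position.

    cis iff same chromosome and |peak - gene| <= window (inclusive);
    "unplaced" when the gene has no known position.
    """
    if gene_cM is None or (isinstance(gene_cM, float) and np.isnan(gene_cM)):
        return "unplaced"
    if chromosome != gene_chromosome:
        return "trans"
    return "cis" if abs(position_cM - gene_cM) <= window else "trans"


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

@dataclass
class MergedEQTL:
    """A cross-phenotype merged eQTL for one transcript."""

    transcript: str
    chromosome: str
    consensus_cM: float
    membership: frozenset  # subset of {control, SA, delta}
    members: list          # row dicts of the contributing records
    cis_trans: str = "unplaced"
    r2: dict = field(default_factory=dict)   # phenotype -> R^2
    r2_mean: float = np.nan
    lod_max: float = np.nan
    paralog_flag: bool = False
    paralog_counts: dict = field(default_factory=dict)
    hotspot_flag: bool = False


def _single_linkage_clusters(positions: np.ndarray, window: float) -> list:
    """Indices grouped by single-linkage with gap <= window (1-D, sorted scan)."""
    order = np.argsort(positions, kind="stable")
    clusters, current = [], [order[0]]
    for a, b in itertools.pairwise(order):
        if positions[b] - positions[a] <= window:
            current.append(b)
        else:
            clusters.append(current)
            current = [b]
    clusters.append(current)
    return clusters


def merge_across_phenotypes(records: pd.DataFrame,
                            window: float = 5.5) -> list:
    """Collapse one transcript's eQTL records across expression phenotypes.

    Single-linkage clustering of same-chromosome records with linkage
    distance <= window; chaining is allowed (records 0/5/10 cM form one
    cluster at a 5.5 cM window). If one phenotype contributes two records to
    a cluster the higher-LOD record stays and the other is re-clustered among
    the remaining spares. Deterministic and order-invariant: records are
    canonically sorted before clustering.
    """
    if records.empty:
        return []
    transcripts = records["transcript"].unique()
    if len(transcripts) != 1:
        raise ValueError("merge_across_phenotypes expects a single transcript")
    transcript = transcripts[0]

    merged: list[MergedEQTL] = []
    rec = records.sort_values(
        ["chromosome", "position_cM", "phenotype", "lod"]).reset_index(drop=True)
    for chrom, sub in rec.groupby("chromosome", sort=False):
        pool = sub.to_dict("records")
        while pool:
            pos = np.array([r["position_cM"] for r in pool])
            clusters = _single_linkage_clusters(pos, window)
            spares = []
            for cluster in clusters:
                members = [pool[i] for i in cluster]
                # at most one member per phenotype: keep the highest LOD
                by_phen: dict = {}
                for r in members:
                    cur = by_phen.get(r["phenotype"])
                    if cur is None or (r["lod"], -r["position_cM"]) > (cur["lod"], -cur["position_cM"]):
                        if cur is not None:
                            spares.append(cur)
                        by_phen[r["phenotype"]] = r
                    else:
                        spares.append(r)
                kept = sorted(by_phen.values(), key=lambda r: r["position_cM"])
                merged.append(MergedEQTL(
                    transcript=transcript, chromosome=chrom,
                    consensus_cM=float(np.mean([r["position_cM"] for r in kept])),
                    membership=frozenset(r["phenotype"] for r in kept),
                    members=kept,
                    lod_max=float(max(r["lod"] for r in kept)),
                ))
            pool = sorted(spares, key=lambda r: (r["position_cM"], r["phenotype"]))
    return merged


def merge_all(records: pd.DataFrame, window: float = 5.5) -> list:
    """Merge every transcript's records; returns a flat MergedEQTL list."""
    out = []
    if records.empty:
        return out
    for _, sub in records.groupby("transcript", sort=True):
        out.extend(merge_across_phenotypes(sub, window))
    return out


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------

def effect_size(dosage: pd.Series, phenotype: pd.Series) -> float:
    """R^2 of the simple regression of a phenotype on marker dosage.

    Zero phenotype (or dosage) variance gives R^2 = 0.
    """
    common = dosage.index.intersection(phenotype.dropna().index)
    x = dosage.loc[common].to_numpy(float)
    y = phenotype.loc[common].to_numpy(float)
    xc, yc = x - x.mean(), y - y.mean()
    sxx, syy = float(xc @ xc), float(yc @ yc)
    if sxx <= 0 or syy <= 0:
        return 0.0
    sxy = float(xc @ yc)
    return sxy * sxy / (sxx * syy)


def attach_effect_sizes(merged: list, probabilities: pd.DataFrame,
                        phenotypes: PhenotypeSet, gmap: GeneticMap) -> None:
    """Fill per-phenotype R^2 (and the mean) at each consensus locus in place.

    One locus, one genotype vector: R^2 is computed at the marker nearest the
    consensus position for every member phenotype.
    """
    for m in merged:
        marker_idx = gmap.nearest_marker_index(m.chromosome, m.consensus_cM)
        marker = gmap.markers[marker_idx]
        dosage = probabilities[marker]
        r2 = {}
        for phen in sorted(m.membership):
            table = phenotypes[phen]
            r2[phen] = effect_size(dosage, table[m.transcript])
        m.r2 = r2
        m.r2_mean = float(np.mean(list(r2.values())))


# ---------------------------------------------------------------------------
# annotation & summaries
# ---------------------------------------------------------------------------

def attach_cis_trans(merged: list, gene_positions: pd.DataFrame,
                     window: float = 10.0) -> None:
    """Label each merged eQTL from its consensus position, in place."""
    lookup = gene_positions.set_index("transcript")[["chromosome", "cM"]]
    for m in merged:
        if m.transcript in lookup.index:
            row = lookup.loc[m.transcript]
            m.cis_trans = classify_cis_trans(m.chromosome, m.consensus_cM,
                                             row["chromosome"], float(row["cM"]),
                                             window)
        else:
            m.cis_trans = "unplaced"


def _region_distance(pos: float, start: float, end: float) -> float:
    if start <= pos <= end:
        return 0.0
    return min(abs(pos - start), abs(pos - end))


def annotate_paralogs(merged: list, paralogs: pd.DataFrame | None,
                      hotspot_regions=None, paralog_window: float = 10.0,
                      membership_window: float = 5.0) -> list:
    """Flag trans eQTLs with nearby paralogs and hotspot-region membership.

    The paralog flag is set when any paralog of the transcript (any
    accession) lies within ``paralog_window`` cM of the consensus on the same
    chromosome; the hotspot flag when the consensus is within
    ``membership_window`` cM of a provided (chromosome, start, end) region.
    """
    by_tx = ({} if paralogs is None or paralogs.empty
             else dict(tuple(paralogs.groupby("transcript", sort=False))))
    hotspot_regions = hotspot_regions or []
    for m in merged:
        sub = by_tx.get(m.transcript)
        if sub is not None:
            m.paralog_counts = sub["accession"].value_counts().to_dict()
            if m.cis_trans == "trans":
                same = sub[sub["paralog_chromosome"] == m.chromosome]
                m.paralog_flag = bool(
                    (np.abs(same["paralog_cM"].to_numpy(float) - m.consensus_cM)
                     <= paralog_window).any()
                )
        for chrom, start, end in hotspot_regions:
            if chrom == m.chromosome and \
                    _region_distance(m.consensus_cM, start, end) <= membership_window:
                m.hotspot_flag = True
                break
    return merged


def merged_to_frame(merged: list) -> pd.DataFrame:
    """Flatten merged eQTLs to the output table schema."""
    rows = []
    for m in merged:
        rows.append({
            "transcript": m.transcript, "chromosome": m.chromosome,
            "consensus_cM": m.consensus_cM,
            "membership": "+".join(p for p in PHENOTYPES if p in m.membership),
            "cis_trans": m.cis_trans, "lod_max": m.lod_max,
            "r2_control": m.r2.get("control", np.nan),
            "r2_sa": m.r2.get("SA", np.nan),
            "r2_delta": m.r2.get("delta", np.nan),
            "r2_mean": m.r2_mean,
            "paralog_flag": m.paralog_flag,
            "paralog_counts": ";".join(f"{k}={v}" for k, v in
                                       sorted(m.paralog_counts.items())),
            "hotspot_flag": m.hotspot_flag,
        })
    return pd.DataFrame(rows)


def summarize_cis_trans(merged: list) -> dict:
    """Counts and cis/trans proportions per phenotype and per membership set.

    Unplaced eQTLs are excluded from proportions but kept in raw counts.
    Also reports mean cis- and trans-eQTL per transcript.
    """
    if not merged:
        raise ValueError("no merged eQTLs to summarize")
    placed = [m for m in merged if m.cis_trans in ("cis", "trans")]

    per_phen = {}
    for phen in PHENOTYPES:
        sub = [m for m in placed if phen in m.membership]
        n_cis = sum(m.cis_trans == "cis" for m in sub)
        per_phen[phen] = {
            "n_cis": n_cis, "n_trans": len(sub) - n_cis,
            "trans_proportion": (len(sub) - n_cis) / len(sub) if sub else np.nan,
        }

    per_membership = {}
    for m in placed:
        key = "+".join(p for p in PHENOTYPES if p in m.membership)
        d = per_membership.setdefault(
            key, {"n_cis": 0, "n_trans": 0, "r2_values": []})
        d["n_cis" if m.cis_trans == "cis" else "n_trans"] += 1
        if np.isfinite(m.r2_mean):
            d["r2_values"].append(m.r2_mean)
    for d in per_membership.values():
        vals = d.pop("r2_values")
        d["mean_r2"] = float(np.mean(vals)) if vals else np.nan

    transcripts = {m.transcript for m in placed}
    n_tx = max(len(transcripts), 1)
    overall = {
        "n_cis": sum(m.cis_trans == "cis" for m in placed),
        "n_trans": sum(m.cis_trans == "trans" for m in placed),
        "n_unplaced": len(merged) - len(placed),
        "cis_per_transcript": sum(m.cis_trans == "cis" for m in placed) / n_tx,
        "trans_per_transcript": sum(m.cis_trans == "trans" for m in placed) / n_tx,
    }
    total_placed = overall["n_cis"] + overall["n_trans"]
    overall["trans_proportion"] = (overall["n_trans"] / total_placed
                                   if total_placed else np.nan)
    return {"per_phenotype": per_phen, "per_membership": per_membership,
            "overall": overall}
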