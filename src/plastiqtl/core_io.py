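"""Domain types and tabular readers/writers shared by all pipeline stages.

Genetic coordinates are centimorgans (cM), continuous and 0-based at each
chromosome start; chromosomes are independent linkage groups. Genotype codes
are the two parental alleles (A = Bay-0-like parent 1, B = Sha-like parent 2)
plus missing. Expression values are treated as already-normalised abundance
estimates on the scale provided.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("control", "SA")
PHENOTYPES = ("control", "SA", "delta")

FLOAT_FMT = "%.6g"  # all floating-point output at 6 significant digits


class FormatError(ValueError):
    """A file does not have the expected columns or dialect."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Markers with cM positions on independent linkage groups.

    ``table`` has columns ``marker``, ``chromosome``, ``position_cM`` sorted
    by chromosome (first-appearance order) then position. ``chrom_ends`` maps
    chromosome id to its terminal cM position (>= last marker).
    """

    table: pd.DataFrame
    chrom_ends: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chromosome", "position_cM"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"genetic map missing columns: {sorted(missing)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValidationError(f"duplicate marker name: {dup!r}")
        for chrom, sub in t.groupby("chromosome", sort=False):
            pos = sub["position_cM"].to_numpy()
            if len(pos) < 2:
                raise ValidationError(
                    f"chromosome {chrom!r} has {len(pos)} marker(s); need >= 2"
                )
            bad = np.where(np.diff(pos) < 0)[0]
            if bad.size:
                m = sub["marker"].iloc[bad[0] + 1]
                raise ValidationError(
                    f"positions on chromosome {chrom!r} not sorted at marker {m!r}"
                )
            if (pos < 0).any():
                raise ValidationError(f"negative cM position on chromosome {chrom!r}")
            end = self.chrom_ends.setdefault(chrom, float(pos[-1]))
            if end < pos[-1]:
                raise ValidationError(
                    f"terminal position {end} of chromosome {chrom!r} precedes "
                    f"last marker at {pos[-1]}"
                )

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chromosome"]))

    @property
    def markers(self) -> list:
        return list(self.table["marker"])

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def positions(self, chromosome) -> np.ndarray:
        sub = self.table[self.table["chromosome"] == chromosome]
        return sub["position_cM"].to_numpy(float)

    def chrom_slice(self, chromosome) -> np.ndarray:
        """Integer indices (into marker order) of one chromosome's markers."""
        return np.flatnonzero((self.table["chromosome"] == chromosome).to_numpy())

    def total_length(self) -> float:
        return float(sum(self.chrom_ends.values()))

    def nearest_marker_index(self, chromosome, pos_cM: float) -> int:
        idx = self.chrom_slice(chromosome)
        if idx.size == 0:
            raise ValidationError(f"unknown chromosome {chromosome!r}")
        pos = self.table["position_cM"].to_numpy(float)[idx]
        return int(idx[np.argmin(np.abs(pos - pos_cM))])


def read_genetic_map(path, chrom_ends: dict | None = None) -> GeneticMap:
    """Read a genetic map CSV with columns marker, chromosome, position_cM."""
    df = pd.read_csv(path, dtype={"marker": str, "chromosome": str})
    required = {"marker", "chromosome", "position_cM"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    try:
        df["position_cM"] = df["position_cM"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric position_cM ({exc})") from exc
    return GeneticMap(df.reset_index(drop=True), dict(chrom_ends or {}))


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """RIL genotype calls, lines x markers, aligned to a :class:`GeneticMap`.

    ``calls`` holds "A", "B" or NaN; its columns equal the map's marker order.
    """

    calls: pd.DataFrame
    map: GeneticMap

    def __post_init__(self) -> None:
        if list(self.calls.columns) != self.map.markers:
            raise ValidationError("genotype columns do not match map marker order")
        arr = self.calls.to_numpy(object)
        valid = (arr == "A") | (arr == "B") | pd.isna(arr)
        if not valid.all():
            r, c = np.argwhere(~valid)[0]
            raise ValidationError(
                f"invalid genotype code {arr[r, c]!r} at line "
                f"{self.calls.index[r]!r}, marker {self.calls.columns[c]!r}"
            )
        for chrom in self.map.chromosomes:
            idx = self.map.chrom_slice(chrom)
            sub = arr[:, idx]
            all_missing = pd.isna(sub).all(axis=1)
            if all_missing.any():
                line = self.calls.index[np.flatnonzero(all_missing)[0]]
                logger.warning(
                    "line %s has no genotype call on chromosome %s", line, chrom
                )

    @property
    def lines(self) -> list:
        return list(self.calls.index)

    @property
    def n_lines(self) -> int:
        return len(self.calls)

    def dosage_observed(self) -> np.ndarray:
        """0/1 dosage of the B allele with NaN at missing calls."""
        arr = self.calls.to_numpy(object)
        out = np.full(arr.shape, np.nan)
        out[arr == "A"] = 0.0
        out[arr == "B"] = 1.0
        return out


def read_genotypes(path, gmap: GeneticMap, codes: dict | None = None) -> GenotypeMatrix:
    """Read a genotype CSV (rows = lines, columns = markers).

    ``codes`` maps canonical {"A","B","NA"} to accepted aliases, so qtl2-style
    dialects ("BB"/"SS") load without preprocessing.
    """
    codes = codes or {"A": ["A"], "B": ["B"], "NA": ["NA", ""]}
    alias = {}
    for canon, aliases in codes.items():
        for a in aliases:
            alias[a] = canon
        alias[canon] = canon
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    missing_markers = set(gmap.markers) - set(df.columns)
    if missing_markers:
        raise ValidationError(
            f"{path}: markers absent from genotype file: {sorted(missing_markers)[:5]}"
        )
    df = df[gmap.markers]  # reorder to map order

    def recode(cell, line, marker):
        canon = alias.get(cell)
        if canon is None:
            raise FormatError(
                f"{path}: unknown genotype code {cell!r} at line {line!r}, marker {marker!r}"
            )
        return np.nan if canon == "NA" else canon

    out = pd.DataFrame(
        {
            m: [recode(v, li, m) for li, v in zip(df.index, df[m])]
            for m in df.columns
        },
        index=df.index,
    )
    frac_missing = float(out.isna().to_numpy().mean())
    logger.info("read %d lines x %d markers, %.2f%% missing",
                len(out), out.shape[1], 100 * frac_missing)
    return GenotypeMatrix(out, gmap)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    geno.calls.fillna("NA").to_csv(path)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Expression values (samples x transcripts) with sample metadata.

    ``metadata`` is indexed by sample id with columns genotype, treatment,
    replicate; treatments are restricted to {"control", "SA"}.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"genotype", "treatment", "replicate"}
        missing = required - set(self.metadata.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        if self.metadata.index.duplicated().any():
            dup = self.metadata.index[self.metadata.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate transcript id: {dup!r}")
        bad = set(self.metadata["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValidationError(
                f"treatment(s) {sorted(bad)} not in {TREATMENTS}"
            )
        orphans = set(self.values.index) - set(self.metadata.index)
        if orphans:
            raise ValidationError(
                f"samples without metadata: {sorted(map(str, orphans))[:5]}"
            )
        # align metadata to sample order of the value matrix
        self.metadata = self.metadata.loc[self.values.index]

    @property
    def samples(self) -> list:
        return list(self.values.index)

    @property
    def transcripts(self) -> list:
        return list(self.values.columns)

    @property
    def genotypes(self) -> list:
        return list(dict.fromkeys(self.metadata["genotype"]))

    def subset_genotypes(self, genotype_ids) -> "ExpressionDataset":
        keep = self.metadata["genotype"].isin(set(genotype_ids))
        return ExpressionDataset(self.values.loc[keep.to_numpy()],
                                 self.metadata.loc[keep.to_numpy()].copy())


def read_expression(matrix_path, metadata_path) -> ExpressionDataset:
    """Read a transcripts-x-samples TSV matrix plus a sample metadata TSV."""
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample", "genotype", "treatment", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{metadata_path}: missing columns {sorted(missing)}")
    meta = meta.set_index("sample")
    values = mat.T  # samples x transcripts
    values.index = values.index.astype(str)
    absent = set(values.index) - set(meta.index)
    if absent:
        raise ValidationError(
            f"{metadata_path}: no metadata for sample(s) {sorted(absent)[:5]}"
        )
    return ExpressionDataset(values, meta)


def write_expression(ds: ExpressionDataset, matrix_path, metadata_path) -> None:
    ds.values.T.to_csv(matrix_path, sep="\t", float_format=FLOAT_FMT,
                       index_label="transcript")
    ds.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# derived tables
# ---------------------------------------------------------------------------

def read_table(path) -> pd.DataFrame:
    """Read a genotypes-x-transcripts TSV table (mean expression or delta)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(table: pd.DataFrame, path, index_label: str = "genotype") -> None:
    table.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


def read_gene_positions(path) -> pd.DataFrame:
    """Gene position TSV: transcript, chromosome, bp (and optionally cM)."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript": str, "chromosome": str})
    required = {"transcript", "chromosome", "bp"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_paralogs(path) -> pd.DataFrame:
    """Paralog TSV: transcript, accession, paralog_chromosome, paralog_cM."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"transcript": str, "accession": str,
                            "paralog_chromosome": str})
    required = {"transcript", "accession", "paralog_chromosome", "paralog_cM"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
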