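"""Synthetic F8 RIL populations with planted eQTL architecture.

Emulates a Bay-0 x Sha-like recombinant inbred population: five independent
linkage groups, lines generated as two-state Markov chains along each
chromosome using the Haldane-Waddington selfed-RIL recombination fraction
R = 2r/(1+2r) with Haldane r = (1 - exp(-2d/100))/2 for an interval of
d cM. Expression is generated from planted additive effects (cis or trans),
optional treatment-interaction (plasticity) effects, pleiotropic trans
hotspots, and opposing-sign effect pairs whose parental contributions cancel
-- the mechanism behind transgressive segregation of the SA response.

The stationary F-infinity formula is used directly instead of simulating
seven selfing generations; it is exact in the limit and a close approximation
for F8. Residual heterozygosity (~0.8% at F8) is ignored: genotypes are
strictly biallelic homozygous, matching how the mapping model treats lines.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionDataset, GeneticMap, GenotypeMatrix

PARENT_A_ID = "Bay"
PARENT_B_ID = "Sha"


def haldane_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: cM distance -> meiotic recombination fraction."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM) / 100.0))


def ril_R(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Observed recombination fraction between selfed-RIL genotypes.

    Haldane-Waddington: R = 2r / (1 + 2r) with Haldane r at distance d.
    """
    r = haldane_r(d_cM)
    return 2.0 * r / (1.0 + 2.0 * r)


def make_map(chromosome_lengths, marker_spacing: float,
             chromosome_names=None) -> GeneticMap:
    """Regular marker grid: 0, s, 2s, ... plus a terminal marker at each end.

    Marker names are deterministic: ``c{chrom}m{idx}``.
    """
    if marker_spacing <= 0:
        raise ValueError("marker_spacing must be > 0")
    rows = []
    ends = {}
    names = chromosome_names or [str(i + 1) for i in range(len(chromosome_lengths))]
    for chrom, length in zip(names, chromosome_lengths):
        if length <= 0:
            raise ValueError(f"chromosome length must be > 0, got {length}")
        if marker_spacing > length:
            raise ValueError(
                f"marker spacing {marker_spacing} exceeds chromosome length {length}"
            )
        n_steps = int(np.floor(length / marker_spacing + 1e-9))
        positions = [i * marker_spacing for i in range(n_steps + 1)]
        if length - positions[-1] > 1e-9:
            positions.append(float(length))
        for i, pos in enumerate(positions):
            rows.append({"marker": f"c{chrom}m{i}", "chromosome": chrom,
                         "position_cM": float(pos)})
        ends[chrom] = float(length)
    return GeneticMap(pd.DataFrame(rows), ends)


def simulate_ril_genotypes(gmap: GeneticMap, n_lines: int, seed: int) -> GenotypeMatrix:
    """Draw selfed-RIL genotypes as independent Markov chains per chromosome.

    The first marker of each chromosome is A or B with probability 1/2; the
    allele switches between adjacent markers at distance d with probability
    ``ril_R(d)``. Chromosomes segregate independently.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    n_markers = gmap.n_markers
    calls = np.empty((n_lines, n_markers), dtype="U1")
    for chrom in gmap.chromosomes:
        idx = gmap.chrom_slice(chrom)
        pos = gmap.table["position_cM"].to_numpy(float)[idx]
        R = ril_R(np.diff(pos))
        state = rng.random(n_lines) < 0.5  # True = B allele
        col = np.where(state, "B", "A")
        calls[:, idx[0]] = col
        for j, Rj in enumerate(R):
            flip = rng.random(n_lines) < Rj
            state = state ^ flip
            calls[:, idx[j + 1]] = np.where(state, "B", "A")
    df = pd.DataFrame(calls, columns=gmap.markers,
                      index=[f"RIL{i + 1:03d}" for i in range(n_lines)])
    return GenotypeMatrix(df, gmap)


@dataclass
class PlantedEffect:
    """One additive eQTL effect acting on one transcript.

    ``baseline_effect`` is the parental mean difference (B minus A) in both
    treatments; ``interaction_effect`` is the additional shift applied only
    under SA, so a nonzero value makes this a plasticity effect.
    """

    transcript: str
    chromosome: str
    position_cM: float
    kind: str  # "cis" | "trans"
    baseline_effect: float
    interaction_effect: float

    @property
    def sign(self) -> int:
        ref = self.baseline_effect if self.baseline_effect != 0 else self.interaction_effect
        return int(np.sign(ref))

    @property
    def is_plasticity(self) -> bool:
        return self.interaction_effect != 0.0


@dataclass
class PlantedArchitecture:
    """Ground truth of a simulated transcriptome: effects, hotspots, noise."""

    effects: list
    hotspots: list  # (chromosome, position_cM, n_targets)
    transcript_positions: pd.DataFrame  # transcript, chromosome, position_cM
    baseline_mean: float = 8.0
    noise_sd: float = 0.25
    replicate_sd: float = 0.1

    @property
    def transcripts(self) -> list:
        return list(self.transcript_positions["transcript"])

    def effects_for(self, transcript: str) -> list:
        return [e for e in self.effects if e.transcript == transcript]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"transcript": e.transcript, "chromosome": e.chromosome,
              "position_cM": e.position_cM, "type": e.kind,
              "baseline_effect": e.baseline_effect,
              "interaction_effect": e.interaction_effect,
              "sign": e.sign}
             for e in self.effects]
        )


@dataclass
class ArchitectureConfig:
    """Counts and effect-size choices for :func:`plant_architecture`.

    Defaults emulate the study population's regulatory structure at desk
    scale: a minority of cis effects, pleiotropic trans hotspots carrying
    treatment-interaction (plasticity) effects, and opposing-sign pairs that
    cancel in the parents.
    """

    n_cis: int = 30
    n_trans: int = 30
    hotspots: list = field(default_factory=lambda: [("2", 48.0, 60)])
    effect_sd: float = 1.0
    min_effect: float = 0.4
    interaction_fraction: float = 0.5
    opposing_fraction: float = 0.2
    cis_window_cM: float = 10.0
    baseline_mean: float = 8.0
    noise_sd: float = 0.25
    replicate_sd: float = 0.1


def plant_architecture(gmap: GeneticMap, n_transcripts: int,
                       config: ArchitectureConfig, seed: int) -> PlantedArchitecture:
    """Assign transcripts random genomic positions and plant eQTL effects.

    Effect magnitudes are half-normal with a floor (``min_effect``) so every
    planted locus is detectable in principle; a fraction carry a
    treatment-interaction term, and a fraction of trans-affected transcripts
    receive an opposing second effect of equal magnitude and opposite sign at
    an unlinked locus, cancelling in the parental sums.
    """
    rng = np.random.default_rng(seed)
    chroms = gmap.chromosomes
    lengths = np.array([gmap.chrom_ends[c] for c in chroms])
    probs = lengths / lengths.sum()

    def random_locus():
        c = chroms[rng.choice(len(chroms), p=probs)]
        return c, float(rng.uniform(0, gmap.chrom_ends[c]))

    tx_rows = []
    for i in range(n_transcripts):
        c, p = random_locus()
        tx_rows.append({"transcript": f"T{i + 1:04d}", "chromosome": c,
                        "position_cM": p})
    tx = pd.DataFrame(tx_rows)

    def draw_effect():
        mag = abs(rng.normal(0, config.effect_sd)) + config.min_effect
        return mag * (1 if rng.random() < 0.5 else -1)

    def split_effect(total):
        """Allocate a total effect to baseline vs SA-interaction channels."""
        if rng.random() < config.interaction_fraction:
            return 0.0, total  # pure plasticity effect
        return total, 0.0

    effects: list[PlantedEffect] = []
    order = rng.permutation(n_transcripts)
    cursor = 0

    # cis effects: locus at (near) the transcript's own position
    n_cis = min(config.n_cis, n_transcripts)
    for i in order[cursor:cursor + n_cis]:
        row = tx.iloc[i]
        base, inter = split_effect(draw_effect())
        effects.append(PlantedEffect(row["transcript"], row["chromosome"],
                                     float(row["position_cM"]), "cis", base, inter))
    cursor += n_cis

    # dispersed trans effects at loci unlinked to the transcript
    n_trans = min(config.n_trans, n_transcripts - cursor)
    trans_transcripts = []
    for i in order[cursor:cursor + n_trans]:
        row = tx.iloc[i]
        while True:
            c, p = random_locus()
            if c != row["chromosome"] or abs(p - row["position_cM"]) > config.cis_window_cM:
                break
        base, inter = split_effect(draw_effect())
        effects.append(PlantedEffect(row["transcript"], c, p, "trans", base, inter))
        trans_transcripts.append((len(effects) - 1, row))
    cursor += n_trans

    # opposing pairs: second unlinked locus cancelling the first in parents
    n_opposing = int(round(config.opposing_fraction * len(trans_transcripts)))
    for k in range(n_opposing):
        eff_idx, row = trans_transcripts[k]
        first = effects[eff_idx]
        while True:
            c, p = random_locus()
            far_from_gene = (c != row["chromosome"]
                             or abs(p - row["position_cM"]) > config.cis_window_cM)
            far_from_first = (c != first.chromosome
                              or abs(p - first.position_cM) > config.cis_window_cM)
            if far_from_gene and far_from_first:
                break
        effects.append(PlantedEffect(row["transcript"], c, p, "trans",
                                     -first.baseline_effect,
                                     -first.interaction_effect))

    # pleiotropic hotspots: many transcripts loaded on one trans locus
    hot_list = []
    for chrom, pos, n_targets in config.hotspots:
        eligible = [
            i for i in range(n_transcripts)
            if tx.iloc[i]["chromosome"] != chrom
            or abs(tx.iloc[i]["position_cM"] - pos) > config.cis_window_cM
        ]
        chosen = rng.choice(eligible, size=min(n_targets, len(eligible)),
                            replace=False)
        for i in chosen:
            row = tx.iloc[i]
            base, inter = split_effect(draw_effect())
            effects.append(PlantedEffect(row["transcript"], chrom, float(pos),
                                         "trans", base, inter))
        hot_list.append((chrom, float(pos), int(len(chosen))))

    return PlantedArchitecture(effects, hot_list, tx,
                               baseline_mean=config.baseline_mean,
                               noise_sd=config.noise_sd,
                               replicate_sd=config.replicate_sd)


def simulate_expression(genotypes: GenotypeMatrix, arch: PlantedArchitecture,
                        n_replicates: int, seed: int,
                        include_parents: bool = True) -> ExpressionDataset:
    """Generate abundance = baseline + allele-coded effects + replicate + noise.

    Alleles are coded -1/2 (A) and +1/2 (B) so a baseline effect equals the
    parental mean difference. Under SA the interaction effect is added to the
    allelic effect. The replicate term is one shared shift per (replicate,
    transcript), mirroring an experimental-replicate random effect. Parental
    lines (all-A, all-B) are appended when ``include_parents``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    gmap = genotypes.map
    transcripts = arch.transcripts
    n_tx = len(transcripts)

    dosage = genotypes.dosage_observed()
    line_ids = list(genotypes.lines)
    if include_parents:
        dosage = np.vstack([dosage,
                            np.zeros((1, dosage.shape[1])),
                            np.ones((1, dosage.shape[1]))])
        line_ids = line_ids + [PARENT_A_ID, PARENT_B_ID]
    coded = np.nan_to_num(dosage, nan=0.5) - 0.5  # -1/2 A, +1/2 B
    n_geno = len(line_ids)

    # per-transcript genetic signal, control and SA channels
    base_signal = np.zeros((n_geno, n_tx))
    sa_signal = np.zeros((n_geno, n_tx))
    tx_index = {t: j for j, t in enumerate(transcripts)}
    for eff in arch.effects:
        m = gmap.nearest_marker_index(eff.chromosome, eff.position_cM)
        g = coded[:, m]
        j = tx_index[eff.transcript]
        base_signal[:, j] += g * eff.baseline_effect
        sa_signal[:, j] += g * (eff.baseline_effect + eff.interaction_effect)

    rep_shift = (rng.normal(0, arch.replicate_sd, size=(n_replicates, n_tx))
                 if arch.replicate_sd > 0 else np.zeros((n_replicates, n_tx)))

    rows, meta = [], []
    for treatment, signal in (("control", base_signal), ("SA", sa_signal)):
        for rep in range(n_replicates):
            noise = (rng.normal(0, arch.noise_sd, size=(n_geno, n_tx))
                     if arch.noise_sd > 0 else 0.0)
            block = arch.baseline_mean + signal + rep_shift[rep] + noise
            rows.append(block)
            for line in line_ids:
                meta.append({"sample": f"{line}_{treatment}_r{rep + 1}",
                             "genotype": line, "treatment": treatment,
                             "replicate": f"r{rep + 1}"})
    values = pd.DataFrame(np.vstack(rows), columns=transcripts,
                          index=[m["sample"] for m in meta])
    metadata = pd.DataFrame(meta).set_index("sample")
    return ExpressionDataset(values, metadata)
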