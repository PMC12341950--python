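"""Pipeline configuration.

Every numeric constant of the analysis lives here so that no magic numbers
are buried in stage code: the 2-LOD significance threshold, the 10 cM cis
window, the 5.5 cM cross-phenotype merge window, the 10 cM / 1 cM sliding
window used for hotspot profiles, the 95th-percentile permutation threshold,
and the k = 10 variance-profile clustering.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    """Raised when a configuration file is malformed."""


@dataclass
class PipelineConfig:
    """Numeric constants and switches shared by all pipeline stages.

    Attributes
    ----------
    lod_threshold:
        Minimum LOD score for an eQTL peak to be reported (genome-wide,
        per transcript x phenotype scan).
    cis_window_cM:
        An eQTL within this distance of its transcript's genomic position
        (same chromosome, inclusive) is labelled cis.
    merge_window_cM:
        eQTLs for the same transcript across expression phenotypes within
        this distance are collapsed into one merged locus.
    hotspot_window_cM, hotspot_step_cM:
        Sliding-window width and step for trans-eQTL density profiles.
    n_permutations, permutation_percentile:
        Uniform-position permutations used to calibrate the global hotspot
        count threshold, and the percentile of the pooled null counts taken
        as that threshold.
    kmeans_k:
        Number of k-means clusters for variance profiles.
    paralog_window_cM:
        A trans-eQTL with a paralog of its transcript within this distance
        is flagged as paralog-associated.
    hotspot_membership_window_cM:
        Distance to a named hotspot region within which a merged eQTL is
        flagged as a hotspot member.
    lod_cap:
        Ceiling applied to LOD when the residual sum of squares underflows
        (perfect fit).
    delta_floor:
        Denominator floor for the plasticity ratio; cells whose mean
        abundance across treatments falls below it become missing.
    log_transform:
        If true, expression values are log2(x+1)-transformed on load.
    genotype_codes:
        Aliases accepted for the two parental alleles and missing calls.
    """

    lod_threshold: float = 2.0
    cis_window_cM: float = 10.0
    merge_window_cM: float = 5.5
    hotspot_window_cM: float = 10.0
    hotspot_step_cM: float = 1.0
    n_permutations: int = 1000
    permutation_percentile: float = 95.0
    kmeans_k: int = 10
    paralog_window_cM: float = 10.0
    hotspot_membership_window_cM: float = 5.0
    lod_cap: float = 50.0
    delta_floor: float = 1e-8
    min_peak_separation_cM: float = 11.0
    peak_drop_lod: float = 1.5
    kmeans_restarts: int = 10
    log_transform: bool = False
    permutation_marker_weighted: bool = False
    seed: int = 0
    genotype_codes: dict = field(
        default_factory=lambda: {
            "A": ["A", "AA", "BB"],  # parent-1 (Bay-0); "BB" is the qtl2 dialect
            "B": ["B", "SS"],        # parent-2 (Sha)
            "NA": ["NA", "", "-", "N"],
        }
    )

    def __post_init__(self) -> None:
        for name in (
            "cis_window_cM",
            "merge_window_cM",
            "hotspot_window_cM",
            "hotspot_step_cM",
            "paralog_window_cM",
            "hotspot_membership_window_cM",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.permutation_percentile < 100:
            raise ConfigError(
                f"permutation_percentile must lie in (0, 100), got {self.permutation_percentile}"
            )
        if self.lod_threshold <= 0:
            raise ConfigError("lod_threshold must be > 0")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")

    def stage_seed(self, stage: str) -> int:
        """Derive a stable per-stage seed below 2**31 from the global seed.

        Hashing the stage name together with the seed lets each stage be
        re-run in isolation without perturbing the randomness of the others.
        """
        digest = hashlib.sha256(f"{stage}:{self.seed}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}


def validate_config(path: str) -> PipelineConfig:
    """Load a YAML config file, applying defaults and rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    coerced = {}
    for key, value in raw.items():
        coerced[key] = _coerce(key, value)
    return PipelineConfig(**coerced)


def _coerce(key: str, value):
    typ = _FIELD_TYPES[key]
    if typ in ("float", float):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"config key '{key}' expects a number, got {value!r}")
        return float(value)
    if typ in ("int", int):
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"config key '{key}' expects an integer, got {value!r}")
        return int(value)
    if typ in ("bool", bool):
        if not isinstance(value, bool):
            raise ConfigError(f"config key '{key}' expects a boolean, got {value!r}")
        return value
    if typ in ("dict", dict):
        if not isinstance(value, dict):
            raise ConfigError(f"config key '{key}' expects a mapping, got {value!r}")
        return value
    return value
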