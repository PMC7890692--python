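"""Configuration objects for the simulation, preprocessing and classification
pipeline.

All tunables live in small frozen-ish dataclasses with explicit validation so
that a malformed configuration fails loudly, naming the offending field, before
any computation starts.  Configurations can be loaded from a flat YAML mapping
whose keys mirror the dataclass field names (see :func:`load_run_config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "ConfigError",
    "GroupParams",
    "CohortConfig",
    "PreprocessConfig",
    "ClassifierConfig",
    "RunConfig",
    "DEFAULT_SEGMENT_LABELS",
    "load_run_config",
]


class ConfigError(ValueError):
    """A configuration field failed validation; the message names the field."""


#: Ten suture phases in temporal order.  Only ``needle_pick``, ``edge_touch``,
#: ``knot_1``..``knot_3`` and ``cutting`` are event names used in microsurgical
#: suturing protocols; the remaining four are placeholder phase names and can
#: be replaced freely via :attr:`CohortConfig.segment_labels`.
DEFAULT_SEGMENT_LABELS: tuple[str, ...] = (
    "needle_pick",
    "edge_touch",
    "pierce",
    "pull_through",
    "regrasp",
    "loop",
    "knot_1",
    "knot_2",
    "knot_3",
    "cutting",
)


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{name}: {msg}")


@dataclass
class GroupParams:
    """Per-group (novice/expert) generative parameters.

    duration_mean_s / duration_sd_s
        Moments of the (truncated) normal suture-duration model, seconds.
    blink_rate_per_min
        Expected blink events per minute of on-microscope time.
    pcps_offset
        Tonic task-evoked pupil dilation above the resting baseline,
        expressed as a fraction of the baseline (dimensionless).
    """

    duration_mean_s: float
    duration_sd_s: float
    blink_rate_per_min: float
    pcps_offset: float

    def validate(self, name: str = "group") -> None:
        _require(self.duration_mean_s > 0, f"{name}.duration_mean_s", "must be > 0")
        _require(self.duration_sd_s >= 0, f"{name}.duration_sd_s", "must be >= 0")
        _require(self.blink_rate_per_min >= 0, f"{name}.blink_rate_per_min", "must be >= 0")


@dataclass
class CohortConfig:
    """Study-design and generative parameters for a synthetic cohort.

    Defaults reproduce the recorded study conditions: 5 novices and 5 experts,
    a task board of 6 slots receiving 2 sutures each, 10 segments per suture,
    expert suture durations ~N(70.6, 14.9) s versus novice ~N(168.8, 68.7) s
    (floored at 10 s), blink rates of ~4.7/min, an 11/120 unsuccessful-suture
    rate and a 5/1090 missing-segment rate.
    """

    n_novices: int = 5
    n_experts: int = 5
    slots: int = 6
    sutures_per_slot: int = 2
    segment_labels: tuple[str, ...] = DEFAULT_SEGMENT_LABELS
    expert: GroupParams = field(
        default_factory=lambda: GroupParams(70.6, 14.9, 4.69, 0.03)
    )
    novice: GroupParams = field(
        default_factory=lambda: GroupParams(168.8, 68.7, 4.68, 0.10)
    )
    duration_floor_s: float = 10.0
    pupil_baseline_range: tuple[float, float] = (400.0, 600.0)
    #: per-segment phasic dilation (fraction of baseline), added on top of the
    #: group tonic offset while that segment is underway
    segment_phasic_amplitudes: tuple[float, ...] = (
        0.02, 0.04, 0.06, 0.03, 0.02, 0.03, 0.05, 0.05, 0.04, 0.00,
    )
    noise_sd: float = 5.0  # pupil units
    #: per-suture tonic arousal fluctuation (PCPS units, iid across sutures);
    #: dominates within-group feature variability, as in real pupillometry
    tonic_jitter_sd: float = 0.03
    high_freq_noise_hz: float = 6.0  # sinusoidal measurement-noise component
    p_failed_suture: float = 11.0 / 120.0
    p_missing_segment: float = 5.0 / 1090.0
    away_gap_s: float = 3.0  # scissors pick at the end of each suture
    blink_min_s: float = 0.1
    blink_max_s: float = 0.4
    rest_s: float = 8.0  # pre-slot rest; must cover the baseline window
    sampling_rate_hz: float = 30.0
    segment_concentration: float = 4.0  # Dirichlet concentration per segment
    seed: int = 0

    def validate(self) -> None:
        for nm in ("n_novices", "n_experts", "slots", "sutures_per_slot"):
            _require(int(getattr(self, nm)) >= 1, nm, "must be >= 1")
        _require(len(self.segment_labels) == 10, "segment_labels", "needs exactly 10 entries")
        _require(
            len(set(self.segment_labels)) == 10, "segment_labels", "entries must be unique"
        )
        self.expert.validate("expert")
        self.novice.validate("novice")
        _require(self.duration_floor_s > 0, "duration_floor_s", "must be > 0")
        lo, hi = self.pupil_baseline_range
        _require(0 < lo <= hi, "pupil_baseline_range", "must satisfy 0 < lo <= hi")
        _require(
            len(self.segment_phasic_amplitudes) == 10,
            "segment_phasic_amplitudes",
            "needs exactly 10 entries",
        )
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.tonic_jitter_sd >= 0, "tonic_jitter_sd", "must be >= 0")
        _require(self.high_freq_noise_hz > 2.0, "high_freq_noise_hz", "must be > 2 Hz")
        for nm in ("p_failed_suture", "p_missing_segment"):
            _require(0.0 <= getattr(self, nm) <= 1.0, nm, "must be in [0, 1]")
        _require(self.away_gap_s >= 0, "away_gap_s", "must be >= 0")
        _require(
            0 < self.blink_min_s <= self.blink_max_s, "blink_min_s", "need 0 < min <= max"
        )
        _require(self.rest_s > 0, "rest_s", "must be > 0")
        # downstream low-pass cutoff is 4 Hz; the Nyquist condition must hold
        _require(self.sampling_rate_hz > 8.0, "sampling_rate_hz", "must exceed 2x the 4 Hz cutoff")
        _require(self.segment_concentration > 0, "segment_concentration", "must be > 0")

    def group(self, name: str) -> GroupParams:
        if name == "expert":
            return self.expert
        if name == "novice":
            return self.novice
        raise ConfigError(f"group: unknown group {name!r}")


@dataclass
class PreprocessConfig:
    """Resampling/filtering/blink-classification parameters."""

    rate_hz: float = 30.0
    cutoff_hz: float = 4.0
    filter_order: int = 2  # applied forward and backward (zero phase)
    min_filter_run_s: float = 1.0
    blink_max_s: float = 0.5  # not-found runs shorter than this are blinks
    away_min_s: float = 2.0  # not-found runs at least this long are away

    def validate(self) -> None:
        _require(self.rate_hz > 2 * self.cutoff_hz, "rate_hz", "must exceed 2x cutoff_hz")
        _require(self.cutoff_hz > 0, "cutoff_hz", "must be > 0")
        _require(self.filter_order >= 1, "filter_order", "must be >= 1")
        _require(self.min_filter_run_s > 0, "min_filter_run_s", "must be > 0")
        _require(0 < self.blink_max_s <= self.away_min_s, "blink_max_s", "need 0 < blink_max_s <= away_min_s")


def _default_c_grid() -> tuple[float, ...]:
    return tuple(2.0 ** k for k in range(-3, 18))


@dataclass
class ClassifierConfig:
    """SVM and cross-validation parameters.

    The penalty default C = 0.25 is the value the grid search settles on for
    this task family; ``c_grid`` spans 2^-3 .. 2^17 in factor-of-two steps.
    """

    C: float = 0.25
    c_grid: tuple[float, ...] = field(default_factory=_default_c_grid)
    kernel: str = "rbf"  # "rbf" (bandwidth 1/(n_features * var)) or "linear"
    pca_components_per_block: int = 4
    scaling_mode: str = "independent"  # or "train_fitted"
    k_folds: int = 10
    repeats: int = 10
    seed: int = 0

    def validate(self) -> None:
        _require(self.C > 0, "C", "must be > 0")
        grid = tuple(self.c_grid)
        _require(len(grid) >= 1, "c_grid", "must be nonempty")
        _require(all(c > 0 for c in grid), "c_grid", "values must be > 0")
        _require(
            all(a < b for a, b in zip(grid, grid[1:])), "c_grid", "must be strictly increasing"
        )
        _require(self.kernel in ("rbf", "linear"), "kernel", "must be 'rbf' or 'linear'")
        _require(
            1 <= self.pca_components_per_block <= 10,
            "pca_components_per_block",
            "must be in 1..10",
        )
        _require(
            self.scaling_mode in ("independent", "train_fitted"),
            "scaling_mode",
            "must be 'independent' or 'train_fitted'",
        )
        _require(self.k_folds >= 2, "k_folds", "must be >= 2")
        _require(self.repeats >= 1, "repeats", "must be >= 1")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (paths + nested stage configs)."""

    out_dir: Path = Path("results/run")
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0
    log_level: str = "INFO"
    schemes: tuple[str, ...] = ("suture", "suture_pca", "suture_pupil_only", "segment")
    include_lopo: bool = True

    def validate(self) -> None:
        self.cohort.validate()
        self.preprocess.validate()
        self.classifier.validate()

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self,
            seed=seed,
            cohort=replace(self.cohort, seed=seed),
            classifier=replace(self.classifier, seed=seed),
        )


def _build(cls, mapping: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"{name}: unknown keys {sorted(unknown)}")
    return cls(**mapping)


def _coerce_group(val) -> GroupParams:
    if isinstance(val, GroupParams):
        return val
    if isinstance(val, dict):
        return _build(GroupParams, val, "group")
    if isinstance(val, Sequence) and len(val) == 4:
        return GroupParams(*val)
    raise ConfigError("group: expected mapping or 4-sequence")


def cohort_config_from_mapping(mapping: dict) -> CohortConfig:
    mapping = dict(mapping)
    for key in ("expert", "novice"):
        if key in mapping:
            mapping[key] = _coerce_group(mapping[key])
    for key in ("segment_labels", "segment_phasic_amplitudes", "pupil_baseline_range"):
        if key in mapping:
            mapping[key] = tuple(mapping[key])
    cfg = _build(CohortConfig, mapping, "cohort")
    cfg.validate()
    return cfg


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file with nested sections
    ``cohort``, ``preprocess``, ``classifier`` plus top-level scalars."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path}: expected a mapping at top level")
    kw: dict = {}
    if "cohort" in raw:
        kw["cohort"] = cohort_config_from_mapping(raw.pop("cohort"))
    if "preprocess" in raw:
        kw["preprocess"] = _build(PreprocessConfig, raw.pop("preprocess"), "preprocess")
        kw["preprocess"].validate()
    if "classifier" in raw:
        sec = dict(raw.pop("classifier"))
        if "c_grid" in sec:
            sec["c_grid"] = tuple(sec["c_grid"])
        kw["classifier"] = _build(ClassifierConfig, sec, "classifier")
        kw["classifier"].validate()
    if "out_dir" in raw:
        kw["out_dir"] = Path(raw.pop("out_dir"))
    if "schemes" in raw:
        kw["schemes"] = tuple(raw.pop("schemes"))
    for key in ("seed", "log_level", "include_lopo"):
        if key in raw:
            kw[key] = raw.pop(key)
    if raw:
        raise ConfigError(f"config file {path}: unknown keys {sorted(raw)}")
    cfg = _build(RunConfig, kw, "run")
    cfg.validate()
    return cfg
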