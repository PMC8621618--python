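"""Synthetic cohorts emulating stochastic multicolor reporter integration.

The generative model mirrors UbC-(GFAP-PB)-StarTrack labeling of embryonic
radial glial progenitors: each progenitor independently integrates each of
12 piggyBac reporters (6 XFPs x cytoplasm/nucleus) with probability
``p_integration``; integrated reporters carry a small random copy number
that scales fluorescence linearly.  Every progenitor expands into a glial
clone of 4-49 sibling cells sharing its integration profile, spanning 1-7
consecutive 50-um coronal sections, with a mono- or bipotent fate class
drawn from configurable proportions and per-cell placement across upper
cortical layers (I-IV), lower layers (V-VI) and corpus callosum.

Ground truth (progenitor partition, fate classes, integration profiles) is
returned alongside the cell table so clone calling and clonal statistics
can be scored against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._schema import FATE_CLASSES, FATE_CLASS_TYPES, INTENSITY_COLUMNS, REGIONS

N_REPORTERS = 12

#: Fate-class proportions over (Ast, NG2, OL, NG2+OL, Ast+NG2, Ast+OL).
DEFAULT_FATE_CLASS_PROBS: tuple[float, ...] = (0.26, 0.34, 0.17, 0.11, 0.06, 0.06)

#: Per-class mean clone size (cells/clone) used by the truncated
#: negative-binomial size law.
DEFAULT_CLONE_SIZE_MEANS: dict[str, float] = {
    "Ast": 11.58,
    "NG2": 16.58,
    "OL": 11.88,
    "NG2+OL": 14.40,
    "Ast+NG2": 32.0,
    "Ast+OL": 12.67,
}

#: Per-class placement probabilities over (UL, LL, CC).  Qualitative:
#: clones are anchored in lower layers; astrocytes reach upper layers,
#: oligodendrocytes the corpus callosum, mixed clones both.
DEFAULT_REGION_PROBS: dict[str, tuple[float, float, float]] = {
    "Ast": (0.25, 0.75, 0.0),
    "NG2": (0.08, 0.87, 0.05),
    "OL": (0.0, 0.75, 0.25),
    "NG2+OL": (0.15, 0.65, 0.20),
    "Ast+NG2": (0.30, 0.50, 0.20),
    "Ast+OL": (0.0, 0.65, 0.35),
}

MIN_CLONE_SIZE = 4
MAX_CLONE_SIZE = 49
MAX_SPAN = 7

_LAYERS_BY_REGION = {"UL": ("I", "II", "III", "IV"), "LL": ("V", "VI"), "CC": ("CC",)}


@dataclass
class SimulationConfig:
    """All generative parameters for a synthetic cohort.

    Intensities are on an arbitrary 0-255-like scale in which one
    integrated copy contributes ``gain`` units, chosen so the 80-point
    sibling-consistency rule and the 40-unit presence threshold are
    meaningful.
    """

    n_progenitors: int = 200
    p_integration: float = 0.5
    copy_number_law: str = "one_plus_poisson"
    copy_number_params: dict = field(default_factory=lambda: {"lam": 1.0})
    gain: float = 100.0
    noise_sd: float = 8.0
    background_level: float = 5.0
    presence_threshold: float = 40.0
    fate_class_probs: tuple[float, ...] = DEFAULT_FATE_CLASS_PROBS
    clone_size_law: str = "truncated_negbin"
    clone_size_means: dict = field(default_factory=lambda: dict(DEFAULT_CLONE_SIZE_MEANS))
    clone_size_shape: float = 6.0
    span_law: str = "one_plus_binomial"
    span_p: float = 0.27
    region_probs: dict = field(default_factory=lambda: dict(DEFAULT_REGION_PROBS))
    mixed_split_ratio: dict = field(
        default_factory=lambda: {"NG2+OL": 0.5, "Ast+NG2": 0.5, "Ast+OL": 0.5}
    )
    section_thickness: float = 50.0
    n_sections: int = 30
    animal_id: str = "sim1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_progenitors < 0:
            raise ValueError("n_progenitors must be non-negative")
        if not 0.0 <= self.p_integration <= 1.0:
            raise ValueError("p_integration must lie in [0, 1]")
        probs = np.asarray(self.fate_class_probs, dtype=float)
        if probs.shape != (len(FATE_CLASSES),):
            raise ValueError(f"fate_class_probs needs {len(FATE_CLASSES)} entries")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("fate_class_probs must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("fate_class_probs must sum to 1 within 1e-9")
        if self.n_sections < 1 or self.section_thickness <= 0:
            raise ValueError("need n_sections >= 1 and positive section_thickness")
        for cls, rp in self.region_probs.items():
            rp = np.asarray(rp, dtype=float)
            if rp.shape != (3,) or np.any(rp < 0) or abs(rp.sum() - 1.0) > 1e-9:
                raise ValueError(f"region_probs[{cls!r}] must be 3 probabilities summing to 1")


@dataclass(frozen=True)
class IntegrationProfile:
    """Copy counts of the 12 reporters for one progenitor.

    Indexed in cell-table column order (cytoplasm block digits 1-6, then
    nucleus block).  A labeled progenitor has at least one positive entry;
    every sibling cell of a clone shares the profile.
    """

    copies: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.copies) != N_REPORTERS:
            raise ValueError("IntegrationProfile requires 12 copy counts")
        if any(c < 0 for c in self.copies):
            raise ValueError("copy counts must be non-negative")

    @property
    def presence(self) -> tuple[bool, ...]:
        return tuple(c > 0 for c in self.copies)


@dataclass
class GroundTruth:
    """Known clonal structure of a generated cohort.

    ``assignments`` maps every cell_id to its progenitor_id and fate class;
    ``profiles`` holds each progenitor's integration profile.
    """

    assignments: pd.DataFrame
    profiles: dict[int, IntegrationProfile]
    fate_classes: dict[int, str]


def _draw_copies(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.copy_number_law == "one_plus_poisson":
        return 1 + int(rng.poisson(config.copy_number_params.get("lam", 1.0)))
    if config.copy_number_law == "constant":
        return int(config.copy_number_params.get("value", 1))
    raise ValueError(f"unknown copy_number_law {config.copy_number_law!r}")


def sample_integration_profile(config: SimulationConfig, rng: np.random.Generator) -> IntegrationProfile:
    """Draw one progenitor's reporter copy counts.

    Each of the 12 reporters integrates independently with
    ``p_integration``; present reporters draw copies from the copy-number
    law (support >= 1).  All-zero draws are rejected and resampled, since an
    unlabeled progenitor is invisible to the analysis.
    """
    config.validate()
    if config.p_integration == 0.0:
        raise ValueError("cannot generate labeled progenitor with p_integration = 0")
    while True:
        present = rng.random(N_REPORTERS) < config.p_integration
        if present.any():
            break
    copies = tuple(_draw_copies(config, rng) if p else 0 for p in present)
    return IntegrationProfile(copies=copies)


def _draw_clone_size(fate_class: str, config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.clone_size_law == "constant":
        size = int(config.clone_size_means[fate_class])
        if not MIN_CLONE_SIZE <= size <= MAX_CLONE_SIZE:
            raise ValueError("constant clone size outside [4, 49]")
        return size
    if config.clone_size_law != "truncated_negbin":
        raise ValueError(f"unknown clone_size_law {config.clone_size_law!r}")
    mean = config.clone_size_means[fate_class]
    r = config.clone_size_shape
    p = r / (r + mean)
    # rejection-sample into the observed clone-size range
    while True:
        size = int(rng.negative_binomial(r, p))
        if MIN_CLONE_SIZE <= size <= MAX_CLONE_SIZE:
            return size


def _draw_span(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.span_law == "constant":
        span = int(config.span_p)
    elif config.span_law == "one_plus_binomial":
        span = 1 + int(rng.binomial(MAX_SPAN - 1, config.span_p))
    else:
        raise ValueError(f"unknown span_law {config.span_law!r}")
    if not 1 <= span <= MAX_SPAN:
        raise ValueError("span outside [1, 7]")
    return min(span, config.n_sections)


def _assign_types(fate_class: str, size: int, config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    try:
        constituents = FATE_CLASS_TYPES[fate_class]
    except KeyError:
        raise ValueError(f"unknown fate_class {fate_class!r}") from None
    if len(constituents) == 1:
        return [constituents[0]] * size
    ratio = config.mixed_split_ratio.get(fate_class, 0.5)
    n_first = int(round(ratio * size))
    n_first = min(max(n_first, 1), size - 1)  # both types always represented
    types = [constituents[0]] * n_first + [constituents[1]] * (size - n_first)
    rng.shuffle(types)
    return types


def sample_clone(
    profile: IntegrationProfile,
    fate_class: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    progenitor_id: int = 0,
) -> pd.DataFrame:
    """Expand one labeled progenitor into a clone of sibling cells.

    Returns a cell-table DataFrame.  All siblings share the integration
    profile; measured intensity of a present reporter is
    ``copies * gain + N(0, noise_sd)`` floored at 0, absent reporters read
    ``background_level + N(0, noise_sd)``.  Cells occupy a run of
    consecutive sections whose length equals the drawn span (both run
    endpoints are always occupied, so the ground-truth rostro-caudal
    dispersion equals span x section thickness).
    """
    config.validate()
    if fate_class not in FATE_CLASS_TYPES:
        raise ValueError(f"unknown fate_class {fate_class!r}")
    size = _draw_clone_size(fate_class, config, rng)
    span = _draw_span(config, rng)
    start = int(rng.integers(0, config.n_sections - span + 1))
    sections = np.empty(size, dtype=int)
    sections[0] = start
    sections[1] = start + span - 1
    sections[2:] = rng.integers(start, start + span, size=size - 2)
    rng.shuffle(sections)

    types = _assign_types(fate_class, size, config, rng)
    region_p = np.asarray(config.region_probs[fate_class], dtype=float)
    regions = rng.choice(np.array(REGIONS), size=size, p=region_p)
    layers = [
        _LAYERS_BY_REGION[r][int(rng.integers(len(_LAYERS_BY_REGION[r])))] for r in regions
    ]

    copies = np.asarray(profile.copies, dtype=float)
    mean = np.where(copies > 0, copies * config.gain, config.background_level)
    intensities = mean[None, :] + rng.normal(0.0, config.noise_sd, size=(size, N_REPORTERS))
    np.maximum(intensities, 0.0, out=intensities)

    table = pd.DataFrame(
        {
            "cell_id": [f"{config.animal_id}_p{progenitor_id:04d}_c{i:03d}" for i in range(size)],
            "animal_id": config.animal_id,
            "section_index": sections,
            "region": regions,
            "layer": layers,
            "cell_type": types,
        }
    )
    for j, col in enumerate(INTENSITY_COLUMNS):
        table[col] = intensities[:, j]
    return table


def generate_cohort(
    config: SimulationConfig, n_shared_profile: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a full labeled cohort with ground truth.

    Deterministic given ``config.seed``.  ``n_shared_profile`` forces that
    many progenitors (k >= 2) to share a single integration profile,
    injecting barcode collisions for rarity-filter testing.
    """
    config.validate()
    if n_shared_profile == 1:
        raise ValueError("n_shared_profile must be 0 or >= 2")
    rng = np.random.default_rng(config.seed)
    fate_probs = np.asarray(config.fate_class_probs, dtype=float)

    profiles: dict[int, IntegrationProfile] = {}
    fates: dict[int, str] = {}
    tables: list[pd.DataFrame] = []
    shared: IntegrationProfile | None = None
    if n_shared_profile > 0:
        if config.n_progenitors < n_shared_profile:
            raise ValueError("n_shared_profile exceeds n_progenitors")
        shared = sample_integration_profile(config, rng)

    for pid in range(config.n_progenitors):
        if shared is not None and pid < n_shared_profile:
            profile = shared
        else:
            profile = sample_integration_profile(config, rng)
        fate = FATE_CLASSES[int(rng.choice(len(FATE_CLASSES), p=fate_probs))]
        profiles[pid] = profile
        fates[pid] = fate
        clone = sample_clone(profile, fate, config, rng, progenitor_id=pid)
        tables.append(clone.assign(_pid=pid))

    if tables:
        cells = pd.concat(tables, ignore_index=True)
    else:
        cells = sample_clone(
            IntegrationProfile(copies=(1,) + (0,) * 11), "Ast", config,
            np.random.default_rng(0),
        ).iloc[0:0].assign(_pid=pd.Series(dtype=int))
    assignments = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "progenitor_id": cells["_pid"].astype(int),
            "fate_class": cells["_pid"].map(fates),
        }
    )
    cells = cells.drop(columns="_pid")
    return cells, GroundTruth(assignments=assignments, profiles=profiles, fate_classes=fates)


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict form of a config, suitable for YAML serialization."""
    return asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    cfg = SimulationConfig(**d)
    if isinstance(cfg.fate_class_probs, list):
        cfg.fate_class_probs = tuple(cfg.fate_class_probs)
    cfg.validate()
    return cfg
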