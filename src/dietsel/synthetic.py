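"""Synthetic study generator with planted, recoverable group effects.

Emulates the structure of a five-arm rat feeding trial (Control, Tenebrio,
Buffalo, LPS, Tenebrio+LPS; 8 animals per arm) measured over six variable
blocks: metabolic, biochemical, general and intestinal morphometry,
inflammatory markers, and taste-receptor (TASR) relative gene expression
across intestinal segments.  Every downstream stage of the pipeline is
exercised against tables produced here, with the planted effects serving as
recoverable ground truth.

Model
-----
Within a block, variables share a latent sample factor, giving equicorrelation
``rho_b`` (the collinearity the preprocessing stage must prune).  On the
latent standard-normal scale a planted effect shifts the affected groups'
mean by ``d`` within-group standard deviations.  Gaussian blocks are then
mapped to a block-specific location/scale; the expression block is
exponentiated so relative-expression values are positive and right-skewed
around 1, as 2^-ddCt data are.  All randomness derives from a single master
seed through named substreams, so a config reproduces its tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CtTable, SampleTable
from .errors import ConfigurationError

DEFAULT_GROUPS = ("Control", "Tenebrio", "Buffalo", "LPS", "TenebrioLPS")

#: Methods block structure of the emulated study (sums to 89 variables).
DEFAULT_BLOCKS = {
    "metabolic": 4,
    "biochemical": 6,
    "morpho_general": 9,
    "morpho_intestinal": 27,
    "inflammatory": 12,
    "tasr_expression": 31,
}

#: Raw-scale location/scale used for gaussian blocks (arbitrary but fixed
#: units; the pipeline z-scores everything before selection anyway).
_BLOCK_LOCATION = {
    "metabolic": (100.0, 15.0),
    "biochemical": (50.0, 10.0),
    "morpho_general": (20.0, 4.0),
    "morpho_intestinal": (10.0, 2.0),
    "inflammatory": (5.0, 1.5),
}

#: Log-scale SD of the expression block: lognormal(0, 0.5) has median 1 and
#: a right tail comparable to typical relative-expression spreads.
_EXPRESSION_LOG_SD = 0.5

_SEGMENT_CYCLE = ("D", "J", "I", "AC", "DC")


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth group shift for one variable.

    ``d`` is the standardized effect size in units of the within-group SD on
    the variable's latent scale (log scale for the expression block);
    ``direction`` is ``"up"`` or ``"down"`` for the affected groups.
    """

    variable: str
    groups: tuple[str, ...]
    d: float
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ConfigurationError(f"planted effect d must be >= 0, got {self.d}")
        if not self.groups:
            raise ConfigurationError(f"planted effect on {self.variable}: empty group set")
        if self.direction not in ("up", "down"):
            raise ConfigurationError(
                f"planted effect direction must be 'up' or 'down', got {self.direction!r}"
            )

    @property
    def signed_d(self) -> float:
        return self.d if self.direction == "up" else -self.d


@dataclass(frozen=True)
class StudyConfig:
    """Full description of one synthetic study."""

    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: int = 8
    blocks: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BLOCKS))
    planted: tuple[PlantedEffect, ...] = ()
    block_correlation: float = 0.3
    missing_rate: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ConfigurationError(f"n_per_group must be >= 3, got {self.n_per_group}")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ConfigurationError(
                f"block_correlation must be in [0, 1), got {self.block_correlation}"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if any(n < 0 for n in self.blocks.values()):
            raise ConfigurationError("blocks: variable counts must be >= 0")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigurationError("groups: duplicate labels")
        names = set(self.variable_names())
        for eff in self.planted:
            if eff.variable not in names:
                raise ConfigurationError(
                    f"planted: unknown variable {eff.variable!r}"
                )
            unknown = set(eff.groups) - set(self.groups)
            if unknown:
                raise ConfigurationError(
                    f"planted: unknown group(s) {sorted(unknown)} for {eff.variable!r}"
                )

    def variable_names(self) -> list[str]:
        return [
            f"{block}_{i + 1:02d}"
            for block, count in self.blocks.items()
            for i in range(count)
        ]

    def annotations(self) -> pd.DataFrame:
        rows = []
        for block, count in self.blocks.items():
            for i in range(count):
                if block in ("tasr_expression", "morpho_intestinal"):
                    segment = _SEGMENT_CYCLE[i % len(_SEGMENT_CYCLE)]
                elif block in ("biochemical", "inflammatory"):
                    segment = "plasma"
                else:
                    segment = "none"
                rows.append((f"{block}_{i + 1:02d}", block, segment))
        return pd.DataFrame(
            rows, columns=["variable", "block", "segment"]
        ).set_index("variable")


def _substream(master_seed: int, stage: str) -> np.random.Generator:
    """Named, reproducible child stream of the master seed."""
    tag = int.from_bytes(stage.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(tag,)))


def generate_study(config: StudyConfig) -> SampleTable:
    """Draw one study table with the configured planted structure.

    Returns a :class:`SampleTable` with ``len(groups) * n_per_group`` rows and
    one column per block variable.  Planted variables have their affected
    groups' latent mean shifted by ``d`` standard deviations in the stated
    direction; variables within a block are equicorrelated at
    ``block_correlation``.
    """
    rng = _substream(config.master_seed, "study")
    n_samples = len(config.groups) * config.n_per_group
    sample_ids = [
        f"{g}_{i + 1:02d}" for g in config.groups for i in range(config.n_per_group)
    ]
    groups = pd.Series(
        [g for g in config.groups for _ in range(config.n_per_group)],
        index=sample_ids,
        name="group",
    )
    planted_by_var: dict[str, PlantedEffect] = {e.variable: e for e in config.planted}

    columns: dict[str, np.ndarray] = {}
    rho = config.block_correlation
    for block, count in config.blocks.items():
        if count == 0:
            continue
        shared = rng.standard_normal(n_samples)  # latent block factor
        eps = rng.standard_normal((n_samples, count))
        latent = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * eps
        for i in range(count):
            name = f"{block}_{i + 1:02d}"
            z = latent[:, i]
            eff = planted_by_var.get(name)
            if eff is not None:
                z = z + np.where(groups.isin(eff.groups), eff.signed_d, 0.0)
            if block == "tasr_expression":
                columns[name] = np.exp(_EXPRESSION_LOG_SD * z)
            else:
                loc, scale = _BLOCK_LOCATION[block] if block in _BLOCK_LOCATION else (0.0, 1.0)
                columns[name] = loc + scale * z
    data = pd.DataFrame(columns, index=sample_ids)

    if config.missing_rate > 0:
        miss_rng = _substream(config.master_seed, "missing")
        mask = miss_rng.random(data.shape) < config.missing_rate
        data = data.mask(mask)

    return SampleTable(data=data, groups=groups, annotations=config.annotations())


def ground_truth(config: StudyConfig) -> list[PlantedEffect]:
    """The planted effects of a config, for recovery scoring."""
    return list(config.planted)


# ---------------------------------------------------------------------------
# Ct table generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtConfig:
    """Describes a synthetic qPCR experiment.

    ``baseline_dct`` is the target-minus-reference Ct difference of each gene
    in the control group; ``group_shifts`` maps gene -> group -> additional
    dCt shift (a shift of -1 doubles the implied relative expression, since
    RE = 2^-ddCt).
    """

    genes: tuple[str, ...] = (
        "Tas1r1", "Tas1r2", "Tas1r3", "Tas2r108",
        "Tas2r119", "Tas2r138", "Tas2r139", "Tas2r143",
    )
    reference_gene: str = "PPIA"
    control_group: str = "Control"
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: int = 8
    baseline_dct: float = 5.0
    group_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.0
    reference_ct: float = 20.0

    def __post_init__(self) -> None:
        if self.reference_gene in self.genes:
            raise ConfigurationError("reference gene must not be listed among target genes")
        if self.control_group not in self.groups:
            raise ConfigurationError(
                f"control group {self.control_group!r} not among groups"
            )
        for gene in self.group_shifts:
            if gene not in self.genes:
                raise ConfigurationError(f"group_shifts: unknown gene {gene!r}")


def generate_ct_table(config: CtConfig, seed: int = 0) -> CtTable:
    """Draw a Ct table whose implied 2^-ddCt matches the configured shifts.

    With ``noise_sd = 0`` the relative expression downstream is exactly
    ``2**-shift`` for every sample of a shifted group and exactly 1 elsewhere.
    """
    rng = _substream(seed, "ct")
    sample_ids = [
        f"{g}_{i + 1:02d}" for g in config.groups for i in range((config.n_per_group))
    ]
    groups = pd.Series(
        [g for g in config.groups for _ in range(config.n_per_group)],
        index=sample_ids,
        name="group",
    )
    n = len(sample_ids)
    cols: dict[str, np.ndarray] = {}
    ref = np.full(n, config.reference_ct) + config.noise_sd * rng.standard_normal(n)
    cols[config.reference_gene] = ref
    for gene in config.genes:
        shift = np.zeros(n)
        for grp, s in config.group_shifts.get(gene, {}).items():
            shift = shift + np.where(groups == grp, s, 0.0)
        cols[gene] = (
            ref + config.baseline_dct + shift + config.noise_sd * rng.standard_normal(n)
        )
    data = pd.DataFrame(cols, index=sample_ids)
    return CtTable(
        data=data,
        groups=groups,
        reference_gene=config.reference_gene,
        control_group=config.control_group,
    )


def plant_effects(
    config: StudyConfig,
    variables: list[str],
    groups: tuple[str, ...],
    d: float,
    direction: str = "up",
) -> StudyConfig:
    """Convenience: return a copy of ``config`` with effects planted on
    ``variables`` for the given groups at standardized size ``d``."""
    effects = tuple(
        PlantedEffect(variable=v, groups=tuple(groups), d=d, direction=direction)
        for v in variables
    )
    return replace(config, planted=config.planted + effects)
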