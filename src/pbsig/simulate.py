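"""Synthetic study generator.

Emulates the two-week oral lead-exposure study design in mice: three
drinking-water groups (control, low Pb, high Pb), a bleed at the end of
exposure and a second bleed after a two-week recovery on clean water.
Dose-specific sets of probes are planted with additive mean shifts so that
every downstream stage (signature building, cross-prediction, persistence,
composition, pathway scoring, enrichment) has a known ground truth.

The default planting layout reproduces the probe bookkeeping of the
two-dose design: 250 high-dose probes (91 up, 159 down), 250 low-dose
probes (170 up, 80 down), 28 probes in common of which 10 are up in both,
7 down in both and 11 discordant (up at the low dose, down at the high
dose).

The generative model is deliberately simple: value = probe baseline +
planted effect + i.i.d. Gaussian noise on the log2 scale.  Effects are
+/- delta*sigma at the exposure bleed; at the recovery bleed they are
multiplied by the carry-over factor rho (0 = full reversion to baseline).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .formats import BridgingMap, ExpressionMatrix

__all__ = [
    "StudyDesign",
    "PlantConfig",
    "ConfigError",
    "CATEGORIES",
    "generate_study",
    "generate_pathway_training",
    "generate_bridge_map",
    "plant_pathway_effect",
]

EXPOSURE = "exposure"
RECOVERY = "recovery"

# planting categories: (name, doses with an effect, direction per dose)
CATEGORIES = {
    "high_only_up": {"high": +1},
    "high_only_down": {"high": -1},
    "low_only_up": {"low": +1},
    "low_only_down": {"low": -1},
    "shared_up": {"high": +1, "low": +1},
    "shared_down": {"high": -1, "low": -1},
    "discordant": {"high": -1, "low": +1},  # up at low dose, down at high
}


class ConfigError(ValueError):
    """Inconsistent generator configuration."""


@dataclasses.dataclass
class StudyDesign:
    """Groups and per-(group, timepoint) bleed counts.

    The default mirrors the study: at the exposure bleed half the controls
    (7) and all exposed mice (15 + 15); at the recovery bleed the other 7
    controls, 15 low-dose and 13 high-dose mice (one death, one
    contaminated sample) — 72 samples in all.
    """

    groups: tuple[str, ...] = ("control", "low", "high")
    control_group: str = "control"
    bleed_schedule: dict = dataclasses.field(
        default_factory=lambda: {
            ("control", EXPOSURE): 7,
            ("low", EXPOSURE): 15,
            ("high", EXPOSURE): 15,
            ("control", RECOVERY): 7,
            ("low", RECOVERY): 15,
            ("high", RECOVERY): 13,
        }
    )

    def __post_init__(self) -> None:
        for key, n in self.bleed_schedule.items():
            if n < 0:
                raise ConfigError(f"negative sample count for {key}")
            if key[0] not in self.groups:
                raise ConfigError(f"schedule group {key[0]!r} not declared")

    @property
    def n_samples(self) -> int:
        return sum(self.bleed_schedule.values())

    def sample_table(self) -> pd.DataFrame:
        """Deterministic sample enumeration (id, group, timepoint)."""
        rows = []
        for (group, timepoint), n in self.bleed_schedule.items():
            for i in range(n):
                rows.append((f"{group}_{timepoint}_{i + 1:02d}", group, timepoint))
        return pd.DataFrame(rows, columns=["sample_id", "group", "timepoint"]).set_index(
            "sample_id"
        )


@dataclasses.dataclass
class PlantConfig:
    """Ground-truth planting: which probes move, where, and how much.

    ``effect_size`` is in units of the noise standard deviation; planted
    probes are shifted by ``+/- effect_size * noise_sd`` log2 units in the
    exposed groups at the exposure bleed.  ``reversion`` scales the shift
    at the recovery bleed (0 = effects vanish after exposure ends).
    """

    n_probes: int = 5000
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 1.0
    effect_size: float = 3.0
    reversion: float = 0.0
    blocks: dict = dataclasses.field(
        default_factory=lambda: {
            "high_only_up": 81,
            "high_only_down": 141,
            "low_only_up": 149,
            "low_only_down": 73,
            "shared_up": 10,
            "shared_down": 7,
            "discordant": 11,
        }
    )
    seed: int = 42

    def __post_init__(self) -> None:
        unknown = set(self.blocks) - set(CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown planting categories: {sorted(unknown)}")
        if self.total_planted > self.n_probes:
            raise ConfigError(
                f"{self.total_planted} planted probes exceed n_probes={self.n_probes}"
            )
        if not 0.0 <= self.reversion <= 1.0:
            raise ConfigError("reversion must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")

    @property
    def total_planted(self) -> int:
        return sum(self.blocks.values())

    def dose_counts(self) -> dict[str, dict[str, int]]:
        """Planted probe counts per dose and direction."""
        out: dict[str, dict[str, int]] = {}
        for cat, n in self.blocks.items():
            for dose, sign in CATEGORIES[cat].items():
                d = out.setdefault(dose, {"up": 0, "down": 0})
                d["up" if sign > 0 else "down"] += n
        return out


def _assign_plants(config: PlantConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Pick disjoint probe indices for each category (ground-truth table)."""
    order = [c for c in CATEGORIES if config.blocks.get(c, 0) > 0]
    chosen = rng.permutation(config.n_probes)[: config.total_planted]
    rows = []
    offset = 0
    for cat in order:
        n = config.blocks[cat]
        for idx in np.sort(chosen[offset : offset + n]):
            effects = CATEGORIES[cat]
            dose = "both" if len(effects) == 2 else next(iter(effects))
            direction = ";".join(
                f"{d}:{'up' if s > 0 else 'down'}" for d, s in effects.items()
            )
            rows.append((int(idx), dose, direction, cat))
        offset += n
    table = pd.DataFrame(rows, columns=["probe_index", "dose", "direction", "category"])
    return table


def generate_study(
    design: StudyDesign | None = None,
    plant: PlantConfig | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the full study: matrix plus the ground-truth plant table.

    Deterministic given ``plant.seed``.  Random streams are spawned per
    sample from the master seed, so extending the bleed schedule leaves
    the draws of earlier samples untouched.

    Returns (matrix, truth) where ``truth`` lists every planted probe with
    its probe_id, dose, per-dose direction and category.
    """
    design = design or StudyDesign()
    plant = plant or PlantConfig()

    width = len(str(plant.n_probes))
    probe_ids = [f"probe_{i:0{width}d}" for i in range(plant.n_probes)]

    master = np.random.SeedSequence(plant.seed)
    base_ss, plant_ss, sample_root = master.spawn(3)
    baseline = np.random.default_rng(base_ss).normal(
        plant.baseline_mean, plant.baseline_sd, size=plant.n_probes
    )
    truth = _assign_plants(plant, np.random.default_rng(plant_ss))
    truth.insert(0, "probe_id", [probe_ids[i] for i in truth["probe_index"]])

    # per-(dose) signed effect vectors over probes
    effect = {g: np.zeros(plant.n_probes) for g in design.groups}
    for _, row in truth.iterrows():
        for dose, sign in CATEGORIES[row["category"]].items():
            if dose in effect:
                effect[dose][row["probe_index"]] = sign * plant.effect_size * plant.noise_sd

    samples = design.sample_table()
    cols = {}
    for child, (sample_id, ann) in zip(
        sample_root.spawn(len(samples)), samples.iterrows()
    ):
        rng = np.random.default_rng(child)
        noise = rng.normal(0.0, plant.noise_sd, size=plant.n_probes)
        shift = effect[ann["group"]]
        if ann["timepoint"] == RECOVERY:
            shift = shift * plant.reversion
        cols[sample_id] = baseline + shift + noise
    data = pd.DataFrame(cols, index=probe_ids)
    matrix = ExpressionMatrix(data, samples)
    return matrix, truth.drop(columns=["probe_index"])


def generate_pathway_training(
    n_probes: int = 2000,
    n_control: int = 10,
    n_activated: int = 10,
    n_pathway_genes: int = 100,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    probe_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Simulate an in-vitro perturbation training set for pathway scoring.

    Control samples (class 'control') sit at baseline; activated samples
    (class 'activated') are shifted by +effect_size * noise_sd on the
    planted pathway genes.  Returns (matrix, planted gene list); the group
    annotation carries the binary class.
    """
    if min(n_probes, n_control, n_activated, n_pathway_genes) <= 0:
        raise ConfigError("all counts must be positive")
    if n_pathway_genes > n_probes:
        raise ConfigError("n_pathway_genes exceeds n_probes")
    master = np.random.SeedSequence(seed)
    base_ss, plant_ss, noise_ss = master.spawn(3)
    if probe_ids is None:
        width = len(str(n_probes))
        probe_ids = [f"probe_{i:0{width}d}" for i in range(n_probes)]
    elif len(probe_ids) != n_probes:
        raise ConfigError("probe_ids length must equal n_probes")
    baseline = np.random.default_rng(base_ss).normal(7.0, 1.5, size=n_probes)
    planted_idx = np.sort(
        np.random.default_rng(plant_ss).permutation(n_probes)[:n_pathway_genes]
    )
    n = n_control + n_activated
    noise = np.random.default_rng(noise_ss).normal(0.0, noise_sd, size=(n_probes, n))
    values = baseline[:, None] + noise
    values[planted_idx[:, None], n_control:] += effect_size * noise_sd
    sample_ids = [f"ctrl_{i + 1:02d}" for i in range(n_control)] + [
        f"activated_{i + 1:02d}" for i in range(n_activated)
    ]
    ann = pd.DataFrame(
        {
            "group": ["control"] * n_control + ["activated"] * n_activated,
            "timepoint": ["invitro"] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids), ann)
    return matrix, [probe_ids[i] for i in planted_idx]


def plant_pathway_effect(
    matrix: ExpressionMatrix,
    genes: list[str],
    group: str,
    effect: float,
    timepoint: str | None = None,
) -> ExpressionMatrix:
    """Shift the given genes by ``effect`` in one group's samples.

    Utility for building test cohorts with a known pathway activation
    (e.g. a pathway turned on only in high-dose animals).
    """
    out = matrix.copy()
    cols = out.groups() == group
    if timepoint is not None:
        cols &= out.timepoints() == timepoint
    present = [g for g in genes if g in out.data.index]
    out.data.loc[present, cols.to_numpy()] += effect
    return out


def generate_bridge_map(
    source_probes: list[str],
    target_probes: list[str],
    duplicate_fraction: float = 0.0,
    seed: int = 0,
) -> BridgingMap:
    """Build a synthetic cross-platform bridging map.

    Every source maps to exactly one target; a ``duplicate_fraction`` share
    of the used targets receive at least two sources (so translation has to
    average duplicates).  With duplicate_fraction 0 the map is a bijective
    prefix mapping: source i -> target i.
    """
    if not source_probes or not target_probes:
        raise ConfigError("probe lists must be non-empty")
    if not 0.0 <= duplicate_fraction <= 1.0:
        raise ConfigError("duplicate_fraction must lie in [0, 1]")
    n_src = len(source_probes)
    m = min(len(target_probes), n_src)
    d = round(duplicate_fraction * m)
    while m > 1 and n_src - m < d:
        m -= 1
        d = round(duplicate_fraction * m)
    pairs = [(source_probes[i], target_probes[i]) for i in range(m)]
    extras = list(range(m, n_src))
    rng = np.random.default_rng(seed)
    if extras:
        if d > 0:
            # guarantee each duplicated target one extra source, spread the rest
            recipients = list(range(d))
            for j, src_i in enumerate(extras):
                tgt = recipients[j] if j < d else int(rng.integers(0, d))
                pairs.append((source_probes[src_i], target_probes[tgt]))
        else:
            for src_i in extras:
                pairs.append((source_probes[src_i], target_probes[int(rng.integers(0, m))]))
    return BridgingMap(pairs)
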