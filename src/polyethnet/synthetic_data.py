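"""Synthetic ant colonies with planted task groups, age polyethism and circadian rhythm.

The generator emulates the scan-sampling design used for the real colonies:
8 scans per day (00:00, 03:00, ..., 21:00) over 3 days, one behaviour per ant
per scan, with scans occasionally missing (lost identifications). Each ant
carries a latent role (nurse, forager, walker, inactive specialist or
generalist) that fixes its baseline propensity vector over the six behaviours;
age tilts that vector towards foraging and away from brood care and
inactivity; an optional circadian term modulates foraging/walking by time of
day. The planted roles are returned as ground truth so that community
detection, specialization scores and the age analyses can be validated
against a known data-generating process.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd
import yaml

from .io_network import BEHAVIOURS, SLOTS, validate_observations

ROLES: tuple[str, ...] = (
    "nurse",
    "forager",
    "walker",
    "inactive_specialist",
    "generalist",
)

#: Baseline behaviour propensities per latent role (rows sum to 1). Chosen to
#: resemble monomorphic ponerine colonies: nurses concentrate on brood care,
#: foragers leave the nest, walkers are the active in-nest state, inactive
#: specialists are mostly immobile, generalists spread across everything.
DEFAULT_PROPENSITIES: dict[str, dict[str, float]] = {
    "nurse": {
        "walking": 0.15,
        "inactive": 0.10,
        "egg_care": 0.20,
        "larva_care": 0.30,
        "pupa_care": 0.20,
        "foraging": 0.05,
    },
    "forager": {
        "walking": 0.20,
        "inactive": 0.15,
        "egg_care": 0.02,
        "larva_care": 0.02,
        "pupa_care": 0.01,
        "foraging": 0.60,
    },
    "walker": {
        "walking": 0.55,
        "inactive": 0.20,
        "egg_care": 0.04,
        "larva_care": 0.04,
        "pupa_care": 0.02,
        "foraging": 0.15,
    },
    "inactive_specialist": {
        "walking": 0.15,
        "inactive": 0.70,
        "egg_care": 0.04,
        "larva_care": 0.04,
        "pupa_care": 0.02,
        "foraging": 0.05,
    },
    "generalist": {
        "walking": 0.25,
        "inactive": 0.20,
        "egg_care": 0.12,
        "larva_care": 0.13,
        "pupa_care": 0.10,
        "foraging": 0.20,
    },
}

DEFAULT_ROLE_MIX: dict[str, float] = {
    "nurse": 0.30,
    "forager": 0.25,
    "walker": 0.20,
    "inactive_specialist": 0.15,
    "generalist": 0.10,
}

#: Behaviours pushed down by age under positive age coupling.
_YOUNG_BEHAVIOURS = ("egg_care", "larva_care", "pupa_care", "inactive")


class ConfigError(ValueError):
    """Invalid synthetic colony configuration."""


@dataclass
class SyntheticColonyConfig:
    """Parameters of the synthetic colony generator.

    Parameters
    ----------
    n_ants, n_days
        Colony size and number of observation days (field colonies had
        33-122 analysed ants over 3 days).
    age_range_days
        Worker ages are drawn uniformly on this interval (lifespan ~1 year).
    role_mix
        Proportions of the latent roles; ants are assigned roles by a single
        multinomial draw.
    propensity_matrix
        role -> {behaviour: probability}; each row must sum to 1.
    age_coupling
        Dimensionless exponential tilt: an ant of age ``a`` has its foraging
        propensity multiplied by ``exp(k * (a - mid)/365)`` and its brood-care
        and inactive propensities by the inverse, ``mid`` being the age-range
        midpoint, before renormalization. 0 disables age polyethism; the
        default 1.5 produces slopes of the order seen in real colonies.
    circadian_amplitude
        In [0, 1]; foraging and walking propensities are multiplied by
        ``1 + A*cos(2*pi*(slot - 13.5)/24)`` (peak mid-afternoon, matching a
        diurnal species) and renormalized. 0 means no rhythm.
    detection_prob
        Probability that a scan yields a record for an ant (tag losses and
        out-of-view ants make real matrices incomplete).
    markov_persistence
        Probability of simply repeating the previous scan's behaviour instead
        of drawing fresh; 0 (default) treats scans as exchangeable.
    brood_present
        When False, all brood-care propensities are zeroed (colonies without
        brood), mass renormalized.
    """

    n_ants: int = 60
    n_days: int = 3
    age_range_days: tuple[float, float] = (0.0, 365.0)
    role_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ROLE_MIX))
    propensity_matrix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {r: dict(v) for r, v in DEFAULT_PROPENSITIES.items()}
    )
    age_coupling: float = 1.5
    circadian_amplitude: float = 0.0
    detection_prob: float = 0.95
    markov_persistence: float = 0.0
    brood_present: bool = True
    include_queen: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_ants < 1 or self.n_days < 1:
            raise ConfigError("n_ants and n_days must be >= 1")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ConfigError("detection_prob must be in [0, 1]")
        if not 0.0 <= self.circadian_amplitude <= 1.0:
            raise ConfigError("circadian_amplitude must be in [0, 1]")
        if not 0.0 <= self.markov_persistence <= 1.0:
            raise ConfigError("markov_persistence must be in [0, 1]")
        if self.age_range_days[0] < 0 or self.age_range_days[1] < self.age_range_days[0]:
            raise ConfigError("age_range_days must be a non-negative interval")
        mix = np.array([self.role_mix.get(r, 0.0) for r in ROLES], dtype=float)
        if (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
            raise ConfigError("role_mix proportions must be non-negative and sum to 1")
        unknown = set(self.role_mix) - set(ROLES)
        if unknown:
            raise ConfigError(f"unknown roles in role_mix: {sorted(unknown)}")
        for role, props in self.propensity_matrix.items():
            if role not in ROLES:
                raise ConfigError(f"unknown role {role!r} in propensity_matrix")
            p = np.array([props.get(b, 0.0) for b in BEHAVIOURS], dtype=float)
            if (p < 0).any() or (p > 1).any() or not np.isclose(p.sum(), 1.0):
                raise ConfigError(f"propensities for role {role!r} must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticColonyConfig":
        raw = yaml.safe_load(open(path)) or {}
        if "age_range_days" in raw:
            raw["age_range_days"] = tuple(raw["age_range_days"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class SyntheticColony:
    """Generated records + metadata + planted ground truth roles."""

    records: pd.DataFrame
    metadata: pd.DataFrame
    planted_roles: dict[str, str]
    colony_id: str = "synthetic"


def _propensity_vector(
    base: np.ndarray,
    age: float,
    age_mid: float,
    age_coupling: float,
    slot: int,
    circadian_amplitude: float,
) -> np.ndarray:
    p = base.copy()
    if age_coupling != 0.0:
        tilt = np.exp(age_coupling * (age - age_mid) / 365.0)
        p[BEHAVIOURS.index("foraging")] *= tilt
        for b in _YOUNG_BEHAVIOURS:
            p[BEHAVIOURS.index(b)] /= tilt
    if circadian_amplitude > 0.0:
        mod = 1.0 + circadian_amplitude * np.cos(2 * np.pi * (slot - 13.5) / 24.0)
        p[BEHAVIOURS.index("foraging")] *= mod
        p[BEHAVIOURS.index("walking")] *= mod
    total = p.sum()
    if total <= 0:
        raise ConfigError("degenerate propensity vector (all mass removed)")
    return p / total


def generate_colony(config: SyntheticColonyConfig) -> SyntheticColony:
    """Draw a full synthetic colony under ``config`` (deterministic given seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    mix = np.array([config.role_mix.get(r, 0.0) for r in ROLES], dtype=float)
    roles = [ROLES[k] for k in rng.choice(len(ROLES), size=config.n_ants, p=mix)]
    lo, hi = config.age_range_days
    ages = rng.uniform(lo, hi, size=config.n_ants)
    age_mid = (lo + hi) / 2.0

    base = {}
    for role in ROLES:
        props = config.propensity_matrix.get(role, DEFAULT_PROPENSITIES[role])
        p = np.array([props.get(b, 0.0) for b in BEHAVIOURS], dtype=float)
        if not config.brood_present:
            for b in ("egg_care", "larva_care", "pupa_care"):
                p[BEHAVIOURS.index(b)] = 0.0
            p = p / p.sum()
        base[role] = p

    ant_ids = [f"w{k + 1:03d}" for k in range(config.n_ants)]
    is_queen = [False] * config.n_ants
    if config.include_queen:
        ant_ids[0] = "Q"
        is_queen[0] = True
        roles[0] = "nurse"  # the gamergate stays in-nest with the brood
        ages[0] = hi

    rows = []
    for k, ant in enumerate(ant_ids):
        prev = None
        for day in range(1, config.n_days + 1):
            for slot in SLOTS:
                detected = rng.random() < config.detection_prob
                if (
                    prev is not None
                    and config.markov_persistence > 0.0
                    and rng.random() < config.markov_persistence
                ):
                    behaviour = prev
                else:
                    p = _propensity_vector(
                        base[roles[k]],
                        ages[k],
                        age_mid,
                        config.age_coupling,
                        slot,
                        config.circadian_amplitude,
                    )
                    behaviour = BEHAVIOURS[rng.choice(len(BEHAVIOURS), p=p)]
                prev = behaviour
                if detected:
                    rows.append(("synthetic", ant, day, slot, behaviour))

    records = pd.DataFrame(
        rows, columns=["colony_id", "ant_id", "day", "slot", "behaviour"]
    )
    records = validate_observations(records)
    metadata = pd.DataFrame(
        {"ant_id": ant_ids, "age_days": ages, "is_queen": is_queen}
    )
    return SyntheticColony(
        records=records,
        metadata=metadata,
        planted_roles=dict(zip(ant_ids, roles)),
    )
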