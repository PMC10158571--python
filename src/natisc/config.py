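"""Study configuration: condition taxonomy, networks, and simulation parameters.

The naturalistic-ISC design crosses two binary stimulus dimensions — whether a
condition contains linguistic input (+Lang/−Lang) and whether it contains
mental-state (theory-of-mind) content (+ToM/−ToM) — plus a resting-state
control.  Each functional network (language, ToM, ...) couples to the shared
stimulus-locked signal of a condition with a network- and condition-specific
strength ``a >= 0``; coupling zero means the network carries no stimulus-locked
signal in that condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

#: The four condition types of the design.
CONDITION_TYPES = ("+Lang+ToM", "-Lang+ToM", "+Lang-ToM", "rest")


@dataclass(frozen=True)
class Condition:
    """A naturalistic stimulus condition and its type label."""

    name: str
    ctype: str

    def __post_init__(self) -> None:
        if self.ctype not in CONDITION_TYPES:
            raise ValueError(
                f"unknown condition type {self.ctype!r}; expected one of {CONDITION_TYPES}"
            )

    @property
    def has_language(self) -> bool:
        return self.ctype.startswith("+Lang")

    @property
    def has_tom(self) -> bool:
        return self.ctype.endswith("+ToM")


@dataclass(frozen=True)
class NetworkSpec:
    """A named functional network made of equally sized parcels."""

    name: str
    n_parcels: int
    voxels_per_parcel: int

    def __post_init__(self) -> None:
        if self.n_parcels < 1 or self.voxels_per_parcel < 1:
            raise ValueError("networks need at least one parcel with one voxel")


# The seven conditions of interest plus the resting-state reality check,
# mirroring the study design (three +Lang+ToM, three −Lang+ToM, one +Lang−ToM).
DEFAULT_CONDITIONS: Tuple[Condition, ...] = (
    Condition("story", "+Lang+ToM"),
    Condition("audio_play", "+Lang+ToM"),
    Condition("dialogue", "+Lang+ToM"),
    Condition("animated_film", "-Lang+ToM"),
    Condition("live_action_film", "-Lang+ToM"),
    Condition("shapes_animation", "-Lang+ToM"),
    Condition("expository_text", "+Lang-ToM"),
    Condition("rest", "rest"),
)

# Language network: five left-hemisphere parcels; ToM network: six parcels
# (bilateral TPJ, PC, and dorsomedial PFC), as in the group-constrained
# localization scheme this generator stands in for.
DEFAULT_NETWORKS: Tuple[NetworkSpec, ...] = (
    NetworkSpec("language", 5, 24),
    NetworkSpec("tom", 6, 24),
)


def default_couplings(
    networks: Sequence[NetworkSpec] = DEFAULT_NETWORKS,
    conditions: Sequence[Condition] = DEFAULT_CONDITIONS,
    *,
    lang_preferred: float = 0.35,
    lang_nonpreferred: float = 0.10,
    tom_preferred: float = 0.30,
    tom_nonpreferred: float = 0.10,
) -> Dict[Tuple[str, str], float]:
    """Coupling map planting the language/ToM dissociation.

    The language network couples strongly to +Lang conditions and weakly to
    −Lang ones; the ToM network couples strongly to +ToM conditions and weakly
    to −ToM ones.  Rest has zero coupling everywhere.  Networks whose name is
    neither ``language`` nor ``tom`` default to the non-preferred weight for
    every non-rest condition.
    """
    coupling: Dict[Tuple[str, str], float] = {}
    for net in networks:
        for cond in conditions:
            if cond.ctype == "rest":
                a = 0.0
            elif net.name == "language":
                a = lang_preferred if cond.has_language else lang_nonpreferred
            elif net.name == "tom":
                a = tom_preferred if cond.has_tom else tom_nonpreferred
            else:
                a = lang_nonpreferred
            coupling[(net.name, cond.name)] = a
    return coupling


@dataclass
class SimulationConfig:
    """Parameters of the multi-subject synthetic BOLD generator.

    Defaults emulate the study conditions the pipeline is built for:
    ~30 subjects per condition, ~5–7 min runs sampled at TR = 2 s, a shared
    band-limited stimulus-locked signal inside the 0.008–0.09 Hz analysis band,
    subject-global noise shared across a subject's voxels (but independent
    across subjects), independent voxel noise, and nuisance contamination
    (slow drift, motion-locked artifacts, WM/CSF compartment signals) at half
    the shared-signal amplitude.

    All standard deviations are in arbitrary BOLD units; couplings are
    unitless multipliers on the shared signal.
    """

    n_subjects: int = 30
    n_timepoints: int = 160
    tr: float = 2.0
    conditions: Tuple[Condition, ...] = DEFAULT_CONDITIONS
    networks: Tuple[NetworkSpec, ...] = DEFAULT_NETWORKS
    coupling: Dict[Tuple[str, str], float] = field(default_factory=default_couplings)
    sigma_shared: float = 1.0
    sigma_subject: float = 0.5
    sigma_voxel: float = 1.0
    drift_amplitude: float = 0.5
    motion_amplitude: float = 0.5
    noise_roi_amplitude: float = 0.5
    n_noise_pcs_sources: int = 3
    passband: Tuple[float, float] = (0.008, 0.09)
    grid_shape: Tuple[int, int, int] = (20, 20, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects for ISC")
        low, high = self.passband
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0 < low < high < nyquist):
            raise ValueError(
                f"passband {self.passband} must satisfy 0 < low < high < Nyquist={nyquist}"
            )
        for sd_name in ("sigma_shared", "sigma_subject", "sigma_voxel",
                        "drift_amplitude", "motion_amplitude", "noise_roi_amplitude"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        for net in self.networks:
            for cond in self.conditions:
                key = (net.name, cond.name)
                if key not in self.coupling:
                    raise ValueError(f"coupling undefined for {key}")
                if self.coupling[key] < 0:
                    raise ValueError(f"coupling for {key} must be >= 0")
        n_vox = int(np.prod(self.grid_shape))
        needed = sum(n.n_parcels * n.voxels_per_parcel for n in self.networks)
        # parcels must fit in the gray-matter compartment (~55% of the grid)
        if needed > int(0.55 * n_vox):
            raise ValueError(
                f"{needed} parcel voxels do not fit in the gray matter of grid {self.grid_shape}"
            )

    def condition(self, name: str) -> Condition:
        for cond in self.conditions:
            if cond.name == name:
                return cond
        raise KeyError(f"unknown condition {name!r}")

    def with_updates(self, **kwargs) -> "SimulationConfig":
        """Return a copy with fields replaced (re-validated)."""
        return replace(self, **kwargs)


def small_config(**overrides) -> SimulationConfig:
    """A reduced-size configuration for replicate studies and quick runs.

    Same generative structure as the default, on a smaller voxel grid with
    fewer voxels per parcel so that many independent replicates fit in a
    desk-scale compute budget.
    """
    params = dict(
        n_subjects=20,
        grid_shape=(12, 12, 6),
        networks=(NetworkSpec("language", 3, 12), NetworkSpec("tom", 3, 12)),
    )
    params.update(overrides)
    if "coupling" not in params:
        params["coupling"] = default_couplings(
            params["networks"], params.get("conditions", DEFAULT_CONDITIONS)
        )
    return SimulationConfig(**params)
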