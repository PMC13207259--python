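"""Per-code occurrence profiles driving the synthetic claims generator.

A :class:`CodeProfile` states, for one billing code, the probability that a
patient has at least one claim with that code within +/-90, +/-180 and
+/-365 days of the index date, separately for TED and non-TED patients, plus
a repeat model (mean number of extra claims given occurrence).  Window
probabilities are nested (90 <= 180 <= 365) because the windows are.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .codes import CODE_SYSTEMS, normalize_code
from .errors import ConfigurationError

WINDOWS = (90, 180, 365)

#: Non-TED occurrence defaults to this multiple of the TED probability when a
#: profile does not state class-specific values.
DEFAULT_NONTED_RATIO = 0.6


@dataclass(frozen=True)
class CodeProfile:
    code: str
    system: str
    description: str
    prob_ted_window: tuple[float, float, float]    # +/-90, +/-180, +/-365
    prob_nonted_window: tuple[float, float, float]
    mean_repeats: float = 1.0  # Poisson mean of extra claims given occurrence

    def __post_init__(self):
        if self.system not in CODE_SYSTEMS:
            raise ConfigurationError(f"{self.code}: unknown system {self.system!r}")
        for probs in (self.prob_ted_window, self.prob_nonted_window):
            if len(probs) != 3:
                raise ConfigurationError(f"{self.code}: need 3 window probabilities")
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ConfigurationError(f"{self.code}: probabilities outside [0,1]")
            if not (probs[0] <= probs[1] <= probs[2]):
                raise ConfigurationError(
                    f"{self.code}: window probabilities must be nondecreasing "
                    f"across nested windows, got {probs}"
                )
        if self.mean_repeats < 0:
            raise ConfigurationError(f"{self.code}: mean_repeats < 0")

    @property
    def key(self) -> str:
        """Stable column key: system + normalized code."""
        return f"{self.system}:{normalize_code(self.code, self.system)}"


def load_profiles(path: str | Path) -> list[CodeProfile]:
    """Load code profiles from YAML (see data/code_profile.yaml for layout)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    profiles = []
    for entry in raw:
        ted = tuple(float(p) for p in entry["ted"])
        nonted = entry.get("nonted")
        if nonted is None:
            nonted = tuple(round(DEFAULT_NONTED_RATIO * p, 6) for p in ted)
        else:
            nonted = tuple(float(p) for p in nonted)
        profiles.append(
            CodeProfile(
                code=str(entry["code"]),
                system=str(entry["system"]),
                description=str(entry.get("description", "")),
                prob_ted_window=ted,
                prob_nonted_window=nonted,
                mean_repeats=float(entry.get("mean_repeats", 1.0)),
            )
        )
    return profiles


def default_profiles() -> list[CodeProfile]:
    """The profile set shipped with the package."""
    with resources.as_file(
        resources.files("tedclaims.data") / "code_profile.yaml"
    ) as p:
        return load_profiles(p)


def noise_profiles(
    n_codes: int,
    rng: np.random.Generator,
    prob_range: tuple[float, float] = (0.01, 0.15),
) -> list[CodeProfile]:
    """Uninformative filler codes: identical occurrence in both classes.

    Emulates the long tail of claims codes that carry no disease signal;
    probabilities are drawn once per code and shared across classes so any
    classifier using only these codes performs at chance.
    """
    profiles = []
    for i in range(n_codes):
        p365 = float(rng.uniform(*prob_range))
        probs = (round(0.5 * p365, 6), round(0.75 * p365, 6), round(p365, 6))
        profiles.append(
            CodeProfile(
                code=f"R{6800 + i}",
                system="HCPCS",
                description=f"synthetic background service code {i}",
                prob_ted_window=probs,
                prob_nonted_window=probs,
            )
        )
    return profiles
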