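"""Medical code normalization and named code sets.

Claims carry codes from five US coding systems (ICD-9, ICD-10-CM, CPT, HCPCS,
NDC).  ICD codes are compared dot-insensitively and case-insensitively;
procedure codes are passed through uppercased.  Code sets are data, not code:
they ship as an editable YAML file mapping concept names (hyperthyroidism,
exophthalmos, diplopia, ...) to lists of ``[system, code]`` entries, where a
trailing ``*`` marks a prefix wildcard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError, InputError

CODE_SYSTEMS = frozenset({"ICD-9", "ICD-10-CM", "CPT", "HCPCS", "NDC"})
ICD_SYSTEMS = frozenset({"ICD-9", "ICD-10-CM"})
#: Systems usable as ML features (diagnosis and procedure codes; drugs excluded).
DIAGNOSIS_PROCEDURE_SYSTEMS = frozenset({"ICD-9", "ICD-10-CM", "CPT", "HCPCS"})


def normalize_code(raw: str, system: str) -> str:
    """Normalize a raw code string for comparison.

    ICD codes are uppercased and stripped of the decimal point, so ``e05.00``
    and ``E0500`` compare equal; CPT/HCPCS/NDC codes are uppercased only.
    Idempotent by construction.
    """
    if system not in CODE_SYSTEMS:
        raise InputError(f"unknown code system: {system!r}")
    code = str(raw).strip().upper()
    if not code:
        raise InputError("empty code string")
    if system in ICD_SYSTEMS:
        code = code.replace(".", "")
    return code


@dataclass(frozen=True)
class CodeSet:
    """A named set of (system, code) entries with optional prefix wildcards."""

    name: str
    exact: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    prefixes: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.exact and not self.prefixes:
            raise ConfigurationError(f"code set {self.name!r} is empty")

    @classmethod
    def from_entries(cls, name: str, entries: list[tuple[str, str]]) -> "CodeSet":
        exact, prefixes = set(), set()
        for system, code in entries:
            if system not in CODE_SYSTEMS:
                raise ConfigurationError(
                    f"code set {name!r}: unknown system {system!r}"
                )
            if code.endswith("*"):
                stem = code[:-1]
                if not stem:
                    raise ConfigurationError(
                        f"code set {name!r}: bare wildcard entry not allowed"
                    )
                prefixes.add((system, normalize_code(stem, system)))
            else:
                exact.add((system, normalize_code(code, system)))
        return cls(name, frozenset(exact), frozenset(prefixes))

    def matches(self, system: str, normalized_code: str) -> bool:
        if (system, normalized_code) in self.exact:
            return True
        return any(
            system == s and normalized_code.startswith(p) for s, p in self.prefixes
        )


def load_codelists(path: str | Path) -> dict[str, CodeSet]:
    """Load named code sets from a YAML file of ``name: [[system, code], ...]``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"code-list file {path}: expected a mapping")
    return {
        name: CodeSet.from_entries(name, [tuple(e) for e in entries])
        for name, entries in raw.items()
    }


def default_codelists() -> dict[str, CodeSet]:
    """The code sets shipped with the package (editable YAML under data/)."""
    with resources.as_file(
        resources.files("tedclaims.data") / "codelists.yaml"
    ) as p:
        return load_codelists(p)
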