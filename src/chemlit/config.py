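"""Tunable constants for the extraction pipeline.

Every heuristic the pipeline applies (chemical suffix list, relation
trigger verbs, range-expansion caps, matching distance metric) lives here
so it can be inspected, tested, and overridden from a key=value config
file rather than being buried in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

#: Morphological suffixes that mark a word as a likely chemical name.
DEFAULT_CHEMICAL_SUFFIXES: tuple[str, ...] = (
    "ol", "ole", "ine", "ide", "in", "ane", "ene", "yne", "one", "ate",
    "mycin", "olide", "oside", "icin", "azole", "idine",
)

#: Passive-voice verbs that assert a compound came out of an organism.
DEFAULT_TRIGGER_VERBS: tuple[str, ...] = (
    "isolated", "extracted", "obtained", "purified", "produced",
)


@dataclass(frozen=True)
class PipelineConfig:
    chemical_suffixes: tuple[str, ...] = DEFAULT_CHEMICAL_SUFFIXES
    min_suffix_token_len: int = 5
    trigger_verbs: tuple[str, ...] = DEFAULT_TRIGGER_VERBS
    #: "was"/"were" must occur within this many tokens before the trigger.
    passive_window: int = 2
    letter_range_cap: int = 26
    number_range_cap: int = 100
    #: "centroid" or "edge" distance between boxes in structure-label matching.
    distance_metric: str = "centroid"

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


DEFAULT_CONFIG = PipelineConfig()


def load_config(path: str | Path) -> PipelineConfig:
    """Read a key=value file; unknown keys are rejected.

    List-valued keys (suffixes, trigger verbs) take comma-separated values.
    """
    overrides: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in ("chemical_suffixes", "trigger_verbs"):
            overrides[key] = tuple(v.strip() for v in value.split(",") if v.strip())
        elif key in ("min_suffix_token_len", "passive_window",
                     "letter_range_cap", "number_range_cap"):
            overrides[key] = int(value)
        elif key == "distance_metric":
            if value not in ("centroid", "edge"):
                raise ValueError(f"{path}:{lineno}: unknown distance metric {value!r}")
            overrides[key] = value
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    return DEFAULT_CONFIG.with_overrides(**overrides)
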