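"""Single YAML run configuration shared by every pipeline stage."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .note_io import DEFAULT_END_MARKER, DEFAULT_HEADER_LEXICON, DEFAULT_START_MARKER
from .provenance import ProvenanceParams
from .synthetic_data import GeneratorConfig
from .time_model import TimeModelParams

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    """Everything a run needs: markers, lexicon, speeds, thresholds, seed."""

    start_marker: str = DEFAULT_START_MARKER
    end_marker: str = DEFAULT_END_MARKER
    header_lexicon: dict[str, tuple[str, ...]] = Field(
        default_factory=lambda: dict(DEFAULT_HEADER_LEXICON)
    )
    time: TimeModelParams = Field(default_factory=TimeModelParams)
    provenance: ProvenanceParams = Field(default_factory=ProvenanceParams)
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    chars_include_whitespace: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
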