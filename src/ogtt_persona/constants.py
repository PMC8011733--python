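"""Versioned reference parameterization: load/validate the constants file.

One JSON file ships with the package holding the population-level
:class:`~ogtt_persona.model.ModelConstants` and the reference average-healthy
:class:`~ogtt_persona.model.ModelParameters` used as the anchor for
sensitivity analysis, as multi-start centers, and as the fixed values of
non-estimated parameters.  Users may point any CLI command at their own file.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .model import ModelConstants, ModelParameters

__all__ = ["ConstantsFile", "load_constants_file", "reference_parameters", "reference_constants"]

SCHEMA_VERSION = "1"


class _ParamsSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k1: float = Field(gt=0)
    k2: float = Field(gt=0)
    k3: float = Field(gt=0)
    k4: float = Field(gt=0)
    k5: float = Field(gt=0)
    k6: float = Field(gt=0)
    k7: float = Field(gt=0)
    k8: float = Field(gt=0)
    k9: float = Field(gt=0)
    sigma: float = Field(ge=1.0)
    km: float = Field(gt=0)


class _ConstantsSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    Gb: float = Field(gt=0)
    Ib: float = Field(gt=0)
    BW: float = Field(gt=0)
    vG: float = Field(gt=0)
    vI: float = Field(gt=0)
    f: float = Field(gt=0, le=1)
    Gth: float = Field(gt=0)
    c1: float = Field(gt=0)
    tau_i: float = Field(gt=0)
    tau_d: float = Field(gt=0)
    beta: float = Field(gt=0)
    c_liv: float = Field(gt=0)
    uii_b_flux: float = Field(gt=0)


class ConstantsFile(BaseModel):
    """Schema of the versioned constants file."""

    model_config = ConfigDict(extra="forbid")
    schema_version: str
    description: str = ""
    changelog: list[str] = []
    constants: _ConstantsSchema
    reference_parameters: _ParamsSchema

    def to_objects(self) -> tuple[ModelParameters, ModelConstants]:
        p = ModelParameters(**self.reference_parameters.model_dump())
        c = ModelConstants(**self.constants.model_dump())
        return p, c


def _builtin_text() -> str:
    return (
        resources.files("ogtt_persona").joinpath("data/reference_constants.json").read_text()
    )


def load_constants_file(path: str | Path | None = None) -> ConstantsFile:
    """Load and schema-validate a constants file (``None`` = packaged file)."""
    text = Path(path).read_text() if path is not None else _builtin_text()
    return ConstantsFile.model_validate(json.loads(text))


def reference_parameters() -> ModelParameters:
    """The packaged average-healthy reference parameterization."""
    return load_constants_file().to_objects()[0]


def reference_constants() -> ModelConstants:
    """The packaged population-level constants."""
    return load_constants_file().to_objects()[1]
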