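"""Run configuration: data-file paths and calling/thermo parameters.

A config is a flat JSON object; unknown keys are rejected so typos fail
loudly. Every field has a packaged default, so a config file is optional.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from typing import Optional

from .genotyper import GelModel
from .thermo import ThermoParams


@dataclass
class RunConfig:
    primer_panel_path: Optional[str] = None   # None -> packaged panel
    enzyme_path: Optional[str] = None
    assay_path: Optional[str] = None
    size_tolerance: float = 5.0
    min_detectable: float = 30.0
    primer_concentration_c: float = 0.25e-6
    potassium_mM: float = 50.0
    salt_correction: str = "schildkraut"
    seed: int = 0
    verbosity: int = 0

    def gel_model(self) -> GelModel:
        return GelModel(size_tolerance=self.size_tolerance,
                        min_detectable=self.min_detectable)

    def thermo_params(self) -> ThermoParams:
        return ThermoParams(primer_concentration_c=self.primer_concentration_c,
                            potassium_mM=self.potassium_mM,
                            salt_correction=self.salt_correction)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
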