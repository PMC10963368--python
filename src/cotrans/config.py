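"""Run configuration: every tunable parameter of the pipeline with its default.

The defaults encode the analysis conventions used throughout: the strict
>64-read coverage filter, the inclusive r >= 0.6 replicate-reproducibility
threshold, the twofold stable-crossing onset rule, the -2 kcal/mol hotspot
threshold, and the ~35-residue exit-tunnel offset of the onset model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .exceptions import ConfigError


@dataclass
class RunConfig:
    # SeRP enrichment
    pseudocount: float = 0.5          # RPM added to both ratio terms
    min_reads: int = 64               # coverage filter, strict >
    min_pearson: float = 0.6          # replicate QC, inclusive >=
    onset_threshold: float = 2.0      # fold enrichment for onset
    stability_fraction: float = 0.9   # fraction of downstream codons above threshold
    # Onset-prediction model
    tunnel_length: int = 35           # codons buried in the exit tunnel
    energy_fraction_f: float = 0.5    # cluster-group |energy| fraction to qualify
    margin: int = 35                  # codons before stop needed for engagement
    # Energetics
    hotspot_threshold: float = -2.0   # kcal/mol, strict <
    cluster_gap: int = 10             # residues, linear single-linkage
    spatial_cutoff: float = 8.0       # Angstrom, Cα–Cα single-linkage
    # Contacts
    contact_cutoff: float = 4.0       # Angstrom, interface / ribosome contact
    hbond_distance: float = 3.5       # Angstrom, N/O donor–acceptor
    hbond_angle: float = 120.0        # degrees, D–H...A when hydrogens exist
    # Dynamics
    equilibration_window_ns: float = 10.0
    equilibration_sd_tol: float = 0.3  # Angstrom
    welch_ttest: bool = True
    random_seed: int = 0

    _RANGES = {
        "pseudocount": (0.0, None, False),
        "min_reads": (0, None, True),
        "min_pearson": (-1.0, 1.0, True),
        "onset_threshold": (0.0, None, False),
        "stability_fraction": (0.0, 1.0, True),
        "tunnel_length": (0, None, True),
        "energy_fraction_f": (0.0, 1.0, True),
        "margin": (0, None, True),
        "cluster_gap": (0, None, True),
        "spatial_cutoff": (0.0, None, False),
        "contact_cutoff": (0.0, None, False),
        "hbond_distance": (0.0, None, False),
        "hbond_angle": (0.0, 180.0, True),
        "equilibration_window_ns": (0.0, None, False),
        "equilibration_sd_tol": (0.0, None, True),
    }

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name, (lo, hi, lo_inclusive) in self._RANGES.items():
            v = getattr(self, name)
            if lo is not None and (v < lo if lo_inclusive else v <= lo):
                raise ConfigError(f"{name}={v} below valid range")
            if hi is not None and v > hi:
                raise ConfigError(f"{name}={v} above valid range")
        if self.hotspot_threshold >= 0:
            raise ConfigError("hotspot_threshold must be negative (favorable energy)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
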