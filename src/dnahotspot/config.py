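"""Run configuration: every threshold of the pipeline with its documented
default, loadable from a flat ``key: value`` YAML file.  CLI flags override
file values, which override the defaults."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import IO, Optional, Union

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # interface rules
    delta_asa_min: float = 1.0        # A^2, dASA rule threshold
    rasa_min_pct: float = 5.0         # %, unbound-RASA rule threshold
    distance_cutoff: float = 5.0      # A, heavy-atom distance rule (strict <)
    interface_policy: str = "union"   # union | intersection of the two rules
    # labeling / dataset
    ddg_hot_threshold: float = 1.0    # kcal/mol, inclusive
    identity_threshold_pct: float = 40.0  # redundancy clustering (strict >)
    # geometry
    probe_radius: float = 1.4         # A, solvent probe
    sphere_points: int = 960          # SASA lattice density
    hse_radius: float = 13.0          # A, half-sphere exposure / CN radius
    # interaction criteria (A)
    hbond_max: float = 3.5
    vdw_slack: float = 0.5
    disulfide_max: float = 2.5
    salt_bridge_max: float = 4.0
    pi_pi_max: float = 5.5
    pi_cation_max: float = 6.0
    # cross-validation / model
    cv_folds: int = 10
    cv_repeats: int = 30              # final reporting
    selection_repeats: int = 3        # per SBS candidate evaluation
    seed: int = 0
    model_profile: str = "reference"  # reference | fast
    feature_profile: str = "structure_only"  # structure_only | full
    output_dir: str = "."

    def override(self, **kwargs) -> "RunConfig":
        """New config with non-None keyword overrides applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)

    def hash(self) -> str:
        payload = repr(sorted(dataclasses.asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(source: Optional[Union[str, IO[str]]] = None) -> RunConfig:
    """Defaults, updated from a flat YAML mapping when given."""
    cfg = RunConfig()
    if source is None:
        return cfg
    text = source.read() if hasattr(source, "read") else open(source).read()
    data = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg.override(**data)
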