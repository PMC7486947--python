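"""Structured-text (YAML) serialization for policies and species configs,
so reference points and biology can be inspected, versioned and reloaded."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .opmodel import SpeciesConfig
from .policy import HarvestPolicy


def save_policy(policy: HarvestPolicy, path: str | Path) -> None:
    doc = {
        "b0": {k: float(v) for k, v in policy.b0.items()},
        "f_target": {k: float(v) for k, v in policy.f_target.items()},
        "cutoff_frac": policy.cutoff_frac,
        "target_frac": policy.target_frac,
        "ref_window": list(policy.ref_window),
        "cap": policy.cap,
        "hcr_form": policy.hcr_form,
        "tier3_alpha": policy.tier3_alpha,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_policy(path: str | Path) -> HarvestPolicy:
    doc = yaml.safe_load(Path(path).read_text())
    doc["ref_window"] = tuple(doc["ref_window"])
    return HarvestPolicy(**doc)


def save_species_configs(cfgs: dict[str, SpeciesConfig], path: str | Path) -> None:
    doc = {}
    for sp, c in cfgs.items():
        doc[sp] = {
            "maturity": c.maturity.tolist(),
            "selectivity": c.selectivity.tolist(),
            "m1": c.m1.tolist(),
            "base_weight": c.base_weight.tolist(),
            "thermal_weight_sens": c.thermal_weight_sens,
            "ref_temp": c.ref_temp,
            "init_recruits": c.init_recruits,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_species_configs(path: str | Path) -> dict[str, SpeciesConfig]:
    doc = yaml.safe_load(Path(path).read_text())
    out = {}
    for sp, d in doc.items():
        out[sp] = SpeciesConfig(
            name=sp,
            maturity=np.array(d["maturity"]),
            selectivity=np.array(d["selectivity"]),
            m1=np.array(d["m1"]),
            base_weight=np.array(d["base_weight"]),
            thermal_weight_sens=d["thermal_weight_sens"],
            ref_temp=d["ref_temp"],
            init_recruits=d["init_recruits"],
        )
    return out
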