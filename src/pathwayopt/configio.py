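"""YAML campaign/benchmark configuration loading.

One file describes a whole run::

    design_space:
      factors: [crtE, crtB, crtI]
      levels: [24, 24, 24]
    campaign:
      rounds: 3
      batch_size: 46
      replicates: 4
      control_point: [12, 12, 12]
      max_evaluations: 400
      noise_rate: 0.0
      seed: 1
      mode: simulate
    acquisition:
      n_fantasies: 10
      xi: 0.0
      exclude_evaluated: true
    fit:
      kernel: matern52
      restarts: 10
    generator:
      k_min: 1
      k_max: 1
      width_min: 0.55
      width_max: 1.1
      center_min: -1.25
      center_max: 2.25
      scale: 9.0

Every block is optional; omitted keys take the package defaults.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .gridspace import DesignPoint, DesignSpace, make_design_space
from .landscapes import GMMGeneratorParams, NoiseModel
from .gp import FitConfig
from .campaign import CampaignConfig

__all__ = ["load_config"]


def _space_from(block: dict | None) -> DesignSpace:
    if not block:
        return make_design_space(3, [24, 24, 24], ["crtE", "crtB", "crtI"])
    levels = block["levels"]
    names = block.get("factors")
    return make_design_space(len(levels), levels, names)


def load_config(path: str | Path) -> dict:
    """Parse a YAML config into typed objects.

    Returns a dict with keys ``space``, ``campaign``, ``fit``, ``generator``
    and ``acquisition`` (the latter raw, merged into the campaign where it
    overlaps).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    space = _space_from(raw.get("design_space"))

    camp = dict(raw.get("campaign", {}))
    noise = NoiseModel(float(camp.pop("noise_rate", 0.0)))
    control = camp.pop("control_point", "default")
    if control == "default":
        control = DesignPoint((12, 12, 12)) if space.levels_per_factor == (24, 24, 24) \
            else None
    elif control is not None:
        control = DesignPoint(control)
    acq = dict(raw.get("acquisition", {}))
    campaign = CampaignConfig(
        noise=noise, control_point=control,
        n_fantasies=int(acq.get("n_fantasies", 10)),
        **{k: v for k, v in camp.items()
           if k in ("rounds", "batch_size", "replicates", "max_evaluations",
                    "seed", "mode", "fit_restarts")},
    )

    fit_block = {k: v for k, v in raw.get("fit", {}).items()
                 if k in ("kernel", "restarts", "seed", "mode")}
    fit = replace(FitConfig(), **fit_block)

    gen_block = {k: v for k, v in raw.get("generator", {}).items()
                 if k in ("k_min", "k_max", "width_min", "width_max",
                          "center_min", "center_max", "scale")}
    generator = GMMGeneratorParams(**gen_block)

    return {"space": space, "campaign": campaign, "fit": fit,
            "generator": generator, "acquisition": acq}
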