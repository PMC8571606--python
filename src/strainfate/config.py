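"""Community configuration files.

A community is described by a small YAML document::

    strains: [focalRFP, rivalA, rivalB]
    focal: focalRFP
    selection_vs_focal:
      rivalA: -0.05
      rivalB: 0.18
    initial_focal_frequency: 0.5

``selection_vs_focal`` lists the per-generation selection coefficient of the
focal strain against each rival (positive = focal advantage).
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .dynamics import Community

__all__ = ["load_community", "dump_community"]


def load_community(path: str | Path) -> Community:
    """Load a :class:`~strainfate.dynamics.Community` from a YAML config."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: community config must be a mapping")
    missing = {"strains", "focal", "selection_vs_focal"} - set(data)
    if missing:
        raise ValueError(f"{path}: missing keys {sorted(missing)}")
    return Community(
        strain_names=tuple(str(s) for s in data["strains"]),
        focal=str(data["focal"]),
        selection_vs_focal={str(k): float(v) for k, v in data["selection_vs_focal"].items()},
        initial_focal_frequency=float(data.get("initial_focal_frequency", 0.5)),
    )


def dump_community(community: Community, path: str | Path) -> None:
    doc = {
        "strains": list(community.strain_names),
        "focal": community.focal,
        "selection_vs_focal": dict(community.selection_vs_focal),
        "initial_focal_frequency": community.initial_focal_frequency,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
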