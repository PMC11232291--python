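"""Pipeline configuration.

A single flat-ish dataclass carries every tunable of the reconstruction
chain. Defaults mirror the study workflow where the workflow fixes them
(PatchDiam grid, three expansion layers, 20-model ensembles, 30 cm depth
threshold, 1 cm coarse-root diameter) and otherwise record this package's
own documented choices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
import yaml

#: PatchDiam sweep grid in millimetres (18 values).
DEFAULT_GRID_MM: tuple[float, ...] = (
    5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0, 25.0, 30.0,
    35.0, 40.0, 45.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0,
)


@dataclass
class QsmConfig:
    """All tunables of the cover/segmentation/cylinder/trait chain.

    Units are stated per field; millimetres for patch-scale quantities,
    metres for scene-scale ones, centimetres for root diameters (the
    field-measurement convention).
    """

    # -- cover ---------------------------------------------------------
    cover_adjacency_factor: float = 1.0   # adjacency threshold = factor * PatchDiam
    cover_seed: int = 0

    # -- frame / density -----------------------------------------------
    frame_north: tuple[float, float, float] = (1.0, 0.0, 0.0)
    frame_up: tuple[float, float, float] = (0.0, 0.0, 1.0)
    frame_invert: bool = False
    density_probe_patch_diam_mm: float = 20.0

    # -- stump / segmentation ------------------------------------------
    stump_radius_factor: float = 1.5      # x estimated taproot radius
    stump_radius_m: float | None = None   # override; None -> estimate
    stump_depth_m: float = 0.30
    segmentation_base_layers: int = 3
    segmentation_proximity: float = 0.5   # x base-cylinder radius
    segmentation_straightness: float = 0.9
    segmentation_min_persist: int = 3     # patches a side-component must reach to spawn a child

    # -- cylinder modelling --------------------------------------------
    cyl_length_multipliers: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0)
    cyl_azimuth_cells: int = 8
    taproot_max_angle_deg: float = 30.0   # base axis within this of vertical -> taproot continuation
    taproot_max_offset_factor: float = 1.0  # x stump radius, horizontal offset bound

    # -- traits --------------------------------------------------------
    min_proximal_diam_cm: float = 1.0
    depth_threshold_m: float = 0.30
    max_order: int = 3                    # orders above are lumped into this class
    include_taproot: bool = False         # include order-0 chain in totals

    # -- optimization --------------------------------------------------
    grid_mm: tuple[float, ...] = DEFAULT_GRID_MM
    sweep_replicates: int = 3
    # brute-force refinement bracket, as multiples of the interpolated
    # optimum; deliberately wide — the interpolation line can meet a
    # curved trait response far from where the response itself crosses
    # the reference, and the refinement is what recovers from that
    refine_candidates: tuple[float, ...] = (0.6, 0.8, 0.9, 1.0, 1.1,
                                            1.25, 1.6, 2.0, 2.5)
    n_refine: int = 5
    n_models: int = 20

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        """Deterministic short hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "QsmConfig":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for k, v in d.items():
            if k not in fields:
                raise KeyError(f"unknown config key: {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "QsmConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "QsmConfig":
        return dataclasses.replace(self, **kwargs)
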