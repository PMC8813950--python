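"""Per-pixel land-state classification from tree cover, loss, gain and masks.

Pixels are sorted into five mutually exclusive states that drive every
paired comparison downstream:

* ``UNCHANGED_FOREST``    — baseline tree cover > 0.5 and little disturbance
* ``UNCHANGED_NONFOREST`` — baseline tree cover < 0.5, little disturbance,
  and a land-cover class outside the excluded set (water, wetland, snow/ice)
* ``FOREST_LOSS``         — net forest loss above the loss threshold
* ``CHANGED_OTHER``       — everything else (including excluded non-forest)
* ``MASKED``              — nodata in any input

Two readings of "net forest cover change" exist for the unchanged test:
gross turnover (loss + gain — a pixel that lost and regained 0.2 is still
disturbed) and the signed quantity gain − loss. The classifier defaults to
turnover for the "unchanged" / window-trigger tests and to the signed net
loss for the loss test, and exposes the choice via ``change_metric``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .grid import GridField, GridStack
from .synth import EXCLUDED_NONFOREST_CLASSES

__all__ = [
    "SurfaceClass",
    "ClassifierConfig",
    "SurfaceClassMap",
    "compute_change",
    "classify_pixels",
    "classify_scene",
    "buffer_water_mask",
    "mask_snow",
]


class SurfaceClass(IntEnum):
    MASKED = 0
    UNCHANGED_FOREST = 1
    UNCHANGED_NONFOREST = 2
    FOREST_LOSS = 3
    CHANGED_OTHER = 4


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the land-state classifier (all fractions)."""

    forest_threshold: float = 0.5
    change_threshold: float = 0.05
    loss_threshold: float = 0.15
    excluded_nonforest_classes: frozenset[int] = EXCLUDED_NONFOREST_CLASSES
    #: "turnover" (loss + gain) or "signed" (|gain − loss|) for the
    #: unchanged / window-trigger change test.
    change_metric: str = "turnover"

    def __post_init__(self) -> None:
        for name in ("forest_threshold", "change_threshold", "loss_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        if self.loss_threshold < self.change_threshold:
            raise ValueError("loss_threshold must be >= change_threshold")
        if self.change_metric not in ("turnover", "signed"):
            raise ValueError("change_metric must be 'turnover' or 'signed'")


@dataclass
class SurfaceClassMap:
    """Per-pixel land state plus the change fields it was derived from."""

    labels: GridField            # SurfaceClass codes
    turnover: GridField          # Σ loss + gain
    net_signed_change: GridField  # gain − Σ loss
    config: ClassifierConfig

    def where(self, cls: SurfaceClass) -> np.ndarray:
        return self.labels.values == int(cls)

    def change_magnitude(self) -> np.ndarray:
        """The change quantity the config compares against change_threshold."""
        if self.config.change_metric == "turnover":
            return self.turnover.values
        return np.abs(self.net_signed_change.values)

    def counts(self) -> dict[str, int]:
        return {c.name: int(np.sum(self.labels.values == int(c)))
                for c in SurfaceClass}


def compute_change(
    tree2000: GridField,
    yearly_loss: Mapping[int, GridField] | Iterable[GridField],
    gain: GridField,
) -> tuple[GridField, GridField]:
    """Accumulate yearly loss and gain into turnover and signed change.

    Returns ``(turnover, net_signed_change)`` where turnover = Σ loss + gain
    (gross disturbance) and net_signed_change = gain − Σ loss (direction;
    the net loss is its negation).
    """
    tree2000.require_same_geometry(gain)
    losses = (list(yearly_loss.values()) if isinstance(yearly_loss, Mapping)
              else list(yearly_loss))
    total_loss = np.zeros(tree2000.shape)
    for fld in losses:
        tree2000.require_same_geometry(fld)
        total_loss += fld.values
    turnover = tree2000.like(total_loss + gain.values, variable="turnover")
    net = tree2000.like(gain.values - total_loss, variable="net_signed_change")
    return turnover, net


def classify_pixels(
    tree2000: GridField,
    turnover: GridField,
    net_signed_change: GridField,
    landcover: GridField,
    config: ClassifierConfig = ClassifierConfig(),
) -> SurfaceClassMap:
    """Assign each pixel one of the five land states.

    Precedence: nodata → MASKED; net loss above the loss threshold →
    FOREST_LOSS; then the unchanged tests; everything else CHANGED_OTHER.
    """
    for fld in (turnover, net_signed_change, landcover):
        tree2000.require_same_geometry(fld)
    tree = tree2000.values
    change = (turnover.values if config.change_metric == "turnover"
              else np.abs(net_signed_change.values))
    net_loss = -net_signed_change.values
    lc = landcover.values
    excluded = np.isin(lc, list(config.excluded_nonforest_classes))

    labels = np.full(tree.shape, int(SurfaceClass.CHANGED_OTHER), dtype=np.int64)
    loss = net_loss > config.loss_threshold
    labels[loss] = int(SurfaceClass.FOREST_LOSS)
    unchanged = change < config.change_threshold
    uf = unchanged & (tree > config.forest_threshold) & ~loss
    labels[uf] = int(SurfaceClass.UNCHANGED_FOREST)
    # forest needs strictly > threshold, so exactly-threshold pixels fall
    # on the non-forest side
    unf = unchanged & (tree <= config.forest_threshold) & ~excluded & ~loss
    labels[unf] = int(SurfaceClass.UNCHANGED_NONFOREST)
    nodata = (tree2000.mask | turnover.mask | net_signed_change.mask
              | landcover.mask)
    labels[nodata] = int(SurfaceClass.MASKED)

    return SurfaceClassMap(
        labels=tree2000.like(labels, mask=np.zeros_like(nodata),
                             variable="surface_class", units="class"),
        turnover=turnover, net_signed_change=net_signed_change, config=config,
    )


def classify_scene(scene, config: ClassifierConfig = ClassifierConfig()) -> SurfaceClassMap:
    """Convenience: change accumulation + classification for a scene."""
    turnover, net = compute_change(scene.tree2000, scene.yearly_loss, scene.gain)
    return classify_pixels(scene.tree2000, turnover, net, scene.landcover, config)


def buffer_water_mask(water_mask: GridField) -> GridField:
    """Water pixels plus their one-pixel (8-neighbor) buffer."""
    water = water_mask.values.astype(bool)
    buffered = ndimage.binary_dilation(water, structure=np.ones((3, 3), bool))
    return water_mask.like(buffered.astype(float), variable="water_buffer")


def mask_snow(cloud_stack: GridStack, snow_flags: Mapping) -> GridStack:
    """Set cloud values nodata at snow-flagged (pixel, time) slots.

    ``snow_flags`` maps a time label — or, for monthly stacks, the month —
    to a boolean flag field; labels without flags pass through unchanged.
    """
    out_fields = []
    for lab, fld in zip(cloud_stack.time, cloud_stack.fields):
        key = lab
        if key not in snow_flags and isinstance(lab, tuple):
            key = lab[1]  # (year, month) stacks flagged per month
        if key in snow_flags:
            flag = snow_flags[key].values.astype(bool)
            out_fields.append(fld.like(fld.values.copy(),
                                       mask=fld.mask | flag))
        else:
            out_fields.append(fld)
    return GridStack(out_fields, list(cloud_stack.time))
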