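"""Interpretation of learned feature spaces.

Two complementary probes of what a featurization encodes:

* *axis walks* — because a structure cannot be deformed along an axis of a
  nonlinear feature space, we instead hop between real ensemble members
  whose embeddings lie close to a line parallel to a chosen latent axis.
  The line is anchored at the median of the off-axis coordinates; evenly
  spaced anchor points along the axis each pick the nearest embedded
  structure within a band.  Rendering the selected structures left to right
  shows the collective motion the axis encodes.

* *PC deformation* — for a linear featurization, a reference structure
  (conventionally the native) is deformed directly along a principal
  component: S = S_ref + i * lambda * PC for integer steps i.  The default
  sweep i in -25..25 excluding 0 yields 50 structures at step scale
  lambda = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import EmbeddingResult
from .errors import GapError, InvalidSpecError, ShapeError
from .structure_io import Conformation, DecoyEnsemble

__all__ = ["WalkSpec", "DeformationSpec", "axis_walk", "pc_deformation"]


@dataclass
class WalkSpec:
    """How to walk along one latent axis.

    ``band_width`` is the tolerance (latent units) within which a structure
    counts as lying on the line; ``range`` defaults to the embedding's
    empirical range along the axis.
    """

    axis: int = 0
    n_stops: int = 6
    band_width: float = 1.0
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_stops < 2:
            raise InvalidSpecError("a walk needs at least 2 stops")
        if self.band_width <= 0:
            raise InvalidSpecError("band_width must be positive")


@dataclass
class DeformationSpec:
    """A principal-component deformation sweep: S_ref + i * step_scale * pc."""

    pc: np.ndarray = None
    step_scale: float = 0.5
    i_range: tuple[int, ...] = field(
        default_factory=lambda: tuple(i for i in range(-25, 26) if i != 0)
    )

    def __post_init__(self) -> None:
        if self.pc is None:
            raise InvalidSpecError("a deformation needs a principal component")
        self.pc = np.asarray(self.pc, dtype=float).reshape(-1)
        norm = np.linalg.norm(self.pc)
        if abs(norm - 1.0) > 1e-9:
            raise InvalidSpecError(
                f"principal component must be unit-norm, got |pc| = {norm:.3g}"
            )


def axis_walk(
    embedding: EmbeddingResult, ensemble: DecoyEnsemble, spec: WalkSpec
) -> list[int]:
    """Indices of structures forming a monotone walk along one latent axis.

    Embedding rows must correspond to ensemble members, in order.  Anchors
    are evenly spaced along the axis range on the line fixed at the median
    of the off-axis coordinates; each anchor selects the nearest embedded
    structure within ``band_width`` whose walked coordinate strictly exceeds
    the previous selection's (ties: smaller distance, then lower index).

    Raises :class:`GapError`, naming the anchor, when no structure
    qualifies; the caller may widen the band.
    """
    codes = np.asarray(embedding.codes, dtype=float)
    if codes.shape[0] != len(ensemble):
        raise ShapeError(
            f"embedding has {codes.shape[0]} rows for {len(ensemble)} structures"
        )
    if not (0 <= spec.axis < codes.shape[1]):
        raise InvalidSpecError(f"axis {spec.axis} out of range for {codes.shape[1]}-D codes")

    walked = codes[:, spec.axis]
    off_axis = np.delete(codes, spec.axis, axis=1)
    line_point = np.median(off_axis, axis=0) if off_axis.shape[1] else np.empty(0)
    lo, hi = spec.range if spec.range is not None else (walked.min(), walked.max())
    anchors = np.linspace(lo, hi, spec.n_stops)

    selected: list[int] = []
    last_coord = -np.inf
    for stop, a in enumerate(anchors):
        anchor = np.empty(codes.shape[1])
        anchor[spec.axis] = a
        if off_axis.shape[1]:
            mask = np.ones(codes.shape[1], dtype=bool)
            mask[spec.axis] = False
            anchor[mask] = line_point
        dist = np.linalg.norm(codes - anchor, axis=1)
        ok = (dist <= spec.band_width) & (walked > last_coord)
        ok[selected] = False
        if not ok.any():
            raise GapError(
                f"anchor {stop} at axis value {a:.4g}: no structure within "
                f"band_width {spec.band_width:.4g}"
            )
        # nearest within band; ties by lowest index (argmin is first minimum)
        candidates = np.flatnonzero(ok)
        pick = int(candidates[np.argmin(dist[candidates])])
        selected.append(pick)
        last_coord = walked[pick]
    return selected


def pc_deformation(reference: Conformation, spec: DeformationSpec) -> list[Conformation]:
    """Deform a reference structure along a principal component.

    One conformation per step i, coordinates ``reference + i * step_scale *
    pc``; the default sweep produces exactly 50 structures, mirror-symmetric
    about the reference.
    """
    n = reference.n_atoms
    if spec.pc.size != 3 * n:
        raise ShapeError(
            f"principal component length {spec.pc.size} does not match 3n = {3 * n}"
        )
    direction = spec.pc.reshape(n, 3)
    return [
        Conformation(
            coords=reference.coords + i * spec.step_scale * direction,
            id=f"{reference.id or 'reference'}_pc_step{i:+d}",
        )
        for i in spec.i_range
    ]
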