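"""Worldwide projection of predicted Ho, restricted to the MESS-valid area.

A fitted forest is evaluated at every grid cell with complete predictor
values; cells the validity mask excludes, or with any nodata predictor, stay
nodata.  Because a regression forest predicts averages of leaf means, every
finite projected cell necessarily lies within the [min, max] of the training
Ho — the map interpolates the observed diversity range, it never invents
values outside it.  Both the masked and the unmasked surface are produced so
the extrapolation cost of the mask can be inspected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridMismatchError, PredictorStack, Raster
from .mess import ValidityMask
from .rf import RFFit


@dataclass
class ProjectionResult:
    predicted: Raster            # masked surface (NaN outside keep & complete)
    unmasked: Raster             # same prediction without the MESS mask
    mask: ValidityMask
    n_predicted: int
    ho_range: tuple[float, float]
    model_n_trees: int


def project_ho(fit: RFFit, stack: PredictorStack, mask: ValidityMask) -> ProjectionResult:
    """Evaluate the fitted forest on each complete, mask-approved cell."""
    geom = stack.geometry
    keep = np.asarray(mask.keep, dtype=bool)
    if keep.shape != geom.shape:
        raise GridMismatchError(
            f"mask shape {keep.shape} does not match stack grid {geom.shape}"
        )
    if mask.geometry is not None and mask.geometry != geom:
        raise GridMismatchError("mask georeferencing differs from stack")
    complete = stack.complete()
    arrays = stack.as_array()

    def _predict(cells: np.ndarray) -> Raster:
        values = np.full(geom.shape, np.nan)
        if cells.any():
            X = arrays[:, cells].T
            values[cells] = fit.model.predict(X)
        return Raster(values=values, geometry=geom)

    unmasked = _predict(complete)
    predicted = _predict(complete & keep)
    return ProjectionResult(
        predicted=predicted,
        unmasked=unmasked,
        mask=mask,
        n_predicted=int((complete & keep).sum()),
        ho_range=fit.ho_range,
        model_n_trees=fit.n_trees,
    )
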