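"""Scalar fields on a regular lattice with an observation mask.

The method operates on D-dimensional images (D = 2 or 3) sampled on a
regular grid: subject contrast maps, standard-deviation maps, noise-free
signals.  :class:`FieldLattice` is the common carrier for all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FieldLattice:
    """A D-dimensional scalar field with an observation mask.

    Parameters
    ----------
    values : ndarray
        Field values, shape ``(n_1, ..., n_D)`` with D in {2, 3} (1-D is
        also accepted for small worked examples).
    mask : ndarray of bool, optional
        Voxels where the field is observed.  Defaults to all-True.
    """

    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = self.mask
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError(
                f"mask shape {mask.shape} != values shape {values.shape}"
            )
        if not mask.any():
            raise ValueError("mask is empty")
        if not np.all(np.isfinite(values[mask])):
            raise ValueError("non-finite field values inside the mask")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @property
    def dim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "FieldLattice":
        """A new lattice with the same mask and new values."""
        return FieldLattice(np.asarray(values, dtype=float), self.mask)


def as_lattice(field_or_array, mask: np.ndarray | None = None) -> FieldLattice:
    """Coerce an array (or pass through a :class:`FieldLattice`)."""
    if isinstance(field_or_array, FieldLattice):
        return field_or_array
    return FieldLattice(np.asarray(field_or_array, dtype=float), mask)
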