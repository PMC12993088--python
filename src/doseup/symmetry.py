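"""The eight symmetries of the square (dihedral group D4).

Used for training-data augmentation and for the equivariance loss.  Element
``g`` in ``range(8)`` encodes: ``g < 4`` a counter-clockwise rotation by
``90 * g`` degrees; ``g >= 4`` a left-right flip followed by a rotation by
``90 * (g - 4)`` degrees.
"""

from __future__ import annotations

import numpy as np

__all__ = ["D4", "d4_apply", "d4_inverse"]

D4 = tuple(range(8))


def d4_apply(a: np.ndarray, g: int, axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Apply square symmetry ``g`` to array ``a`` over the given spatial axes."""
    if g not in D4:
        raise ValueError(f"not a square symmetry index: {g}")
    out = np.flip(a, axis=axes[1]) if g >= 4 else a
    return np.rot90(out, k=g % 4, axes=axes)


def d4_inverse(g: int) -> int:
    """Index of the inverse symmetry (reflections are involutions)."""
    if g not in D4:
        raise ValueError(f"not a square symmetry index: {g}")
    return (4 - g) % 4 if g < 4 else g
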