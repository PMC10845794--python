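"""The 5x5 stimulus grid and its fixed location indexing.

Locations are numbered 1-25 in row-major order: the top-left cell is 1, the
first row runs 1-5 left to right, and the central (foveal) cell is 13.  This
indexing is fixed across the whole package — CSV columns ``ori_01..ori_25``,
design-matrix columns, weight maps and serial-position matrices all use it.
Under this convention the cell directly above the center is 8 and the cell
directly to its left is 12.
"""

from __future__ import annotations

import numpy as np

GRID_ROWS = 5
GRID_COLS = 5
N_LOCATIONS = GRID_ROWS * GRID_COLS

#: 1-based indices of the three locations where ensemble reports are biased:
#: the fovea and its immediate upward and leftward neighbours.
CENTER_LOCATION = 13
UPWARD_LOCATION = 8
LEFTWARD_LOCATION = 12

ORI_COLUMNS = [f"ori_{k:02d}" for k in range(1, N_LOCATIONS + 1)]
ONSET_COLUMNS = [f"onset_{k:02d}" for k in range(1, N_LOCATIONS + 1)]
DEV_COLUMNS = [f"dev_{k:02d}" for k in range(1, N_LOCATIONS + 1)]
RANK_COLUMNS = [f"rank_{k:02d}" for k in range(1, N_LOCATIONS + 1)]


def location_to_rowcol(location: int) -> tuple[int, int]:
    """Map a 1-based location index to 0-based (row, col) grid coordinates."""
    if not 1 <= location <= N_LOCATIONS:
        raise ValueError(f"location must be in 1..{N_LOCATIONS}, got {location}")
    return (location - 1) // GRID_COLS, (location - 1) % GRID_COLS


def values_to_grid(values) -> np.ndarray:
    """Reshape a length-25 location vector into the 5x5 row-major grid."""
    values = np.asarray(values, dtype=float)
    if values.shape != (N_LOCATIONS,):
        raise ValueError(f"expected {N_LOCATIONS} values, got shape {values.shape}")
    return values.reshape(GRID_ROWS, GRID_COLS)
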