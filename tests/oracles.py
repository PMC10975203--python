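"""Independent brute-force reference implementations.

Deliberately dumb: explicit Python loops and per-cell numpy percentile
calls, sharing no code with the package's vectorized pipeline.
"""

import numpy as np


def brute_force_radial_cells(r, theta, phi, grid, percentile):
    """Map {(row, col): furthest inlier distance} by explicit loops."""
    cells = {}
    for ri, ti, pi in zip(r, theta, phi):
        row = int(pi // grid.delta_phi)
        if row > grid.n_rows - 1:
            row = grid.n_rows - 1
        col = int(ti // grid.delta_theta) % grid.n_cols
        cells.setdefault((row, col), []).append(float(ri))
    out = {}
    for key, ds in cells.items():
        threshold = np.percentile(ds, percentile)
        kept = [d for d in ds if d <= threshold]
        out[key] = max(kept)
    return out
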