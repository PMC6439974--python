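"""Shared brute-force oracles, independent of the library's solver paths."""

import numpy as np


def grid_lp_objective(spec, step: float = 0.01):
    """Minimum of sum|w - w0| over the feasible weight simplex, enumerated
    at the given step; None when no grid point is feasible.  K in {2, 3}."""
    k = len(spec.schema)
    s = spec.norm_target
    n_steps = int(round(s / step))
    rows = [(a - b) for a, b in (*spec.monotonic_rows, *spec.smoothing_rows)]
    rows = np.array(rows) if rows else np.empty((0, k))
    if k == 2:
        grid_a = np.arange(n_steps + 1) * step
        pts = np.column_stack([grid_a, s - grid_a])
    elif k == 3:
        pts = []
        for i in range(n_steps + 1):
            for j in range(n_steps + 1 - i):
                pts.append((i * step, j * step, s - (i + j) * step))
        pts = np.array(pts)
    else:
        raise NotImplementedError("grid oracle supports K <= 3")
    if len(rows):
        feas = np.all(pts @ rows.T <= 1e-9, axis=1)
    else:
        feas = np.ones(len(pts), bool)
    if not feas.any():
        return None
    return float(np.abs(pts[feas] - spec.w0.values).sum(axis=1).min())
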