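"""Independent brute-force oracles, deliberately naive and loop-based.

These re-derive expected results from the algorithm definitions without
sharing any code path with the package: plain-Python neighbor recounts for
the radial iteration, an unrestricted-pool step-by-step re-simulation of the
greedy diametral growth, and a dense proper-rotation grid for the
superposition minimum.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def brute_rtc_winner(values: np.ndarray, available, theta: float):
    """Exhaustive neighbor recount: (winner seed, members, tied winners)."""
    available = sorted(int(i) for i in available)
    neighbor_sets = {
        k: [i for i in available if values[k][i] < theta] for k in available
    }
    best = max(len(s) for s in neighbor_sets.values())
    winners = [k for k in available if len(neighbor_sets[k]) == best]
    chosen = min(winners)
    return chosen, sorted(neighbor_sets[chosen]), winners


def brute_qtc_grow(values: np.ndarray, k: int, available, theta: float):
    """Step-by-step greedy growth over the *unrestricted* available pool.

    Members are returned in inclusion order.  Ties on the resulting
    diameter go to the lowest index (scanning in ascending order with a
    strict improvement test).
    """
    available = sorted(int(i) for i in available)
    members = [int(k)]
    diameter = 0.0
    while True:
        best_c, best_d = None, None
        for c in available:
            if c in members:
                continue
            new_d = max([diameter] + [values[c][m] for m in members])
            if new_d < theta and (best_d is None or new_d < best_d):
                best_c, best_d = c, new_d
        if best_c is None:
            break
        members.append(best_c)
        diameter = best_d
    return members, diameter


def grid_min_rmsd(mobile: np.ndarray, reference: np.ndarray, step_deg: float = 6.0):
    """Minimum RMSD over a dense grid of proper rotations.

    Centers both configurations, then scans intrinsic Euler angles on a
    regular grid.  Upper-bounds the true minimum; the gap is at most about
    r_max * step (in radians).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    a = mobile - mobile.mean(0)
    b = reference - reference.mean(0)
    angles = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    half = np.deg2rad(np.arange(0.0, 180.0 + step_deg, step_deg))
    best = np.inf
    for alpha in angles:
        for beta in half:
            rots = Rotation.from_euler(
                "zyz", np.column_stack([
                    np.full_like(angles, alpha),
                    np.full_like(angles, beta),
                    angles,
                ])
            )
            cand = np.einsum("rij,aj->rai", rots.as_matrix(), a)
            d = cand - b
            rmsds = np.sqrt(np.einsum("rai,rai->r", d, d) / a.shape[0])
            best = min(best, float(rmsds.min()))
    return best
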