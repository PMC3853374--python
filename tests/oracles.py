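"""Independent brute-force oracles used to validate the optimized routines.

These deliberately share no code with the package implementation: the
surface-area oracle walks every voxel and its six neighbors in Python, and
the Cox oracle evaluates the Breslow partial log-likelihood by direct
summation over risk sets.
"""

from __future__ import annotations

import numpy as np


def brute_force_surface_area(binary: np.ndarray, spacing) -> float:
    """Per-voxel 6-face enumeration: each face of a True voxel whose neighbor
    is False or out of bounds contributes the face's physical area."""
    dx, dy, dz = spacing
    face = {0: dy * dz, 1: dx * dz, 2: dx * dy}
    nx, ny, nz = binary.shape
    total = 0.0
    for x, y, z in zip(*np.nonzero(binary)):
        for axis, step in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
            nb = [x, y, z]
            nb[axis] += step
            inside = 0 <= nb[0] < nx and 0 <= nb[1] < ny and 0 <= nb[2] < nz
            if not inside or not binary[nb[0], nb[1], nb[2]]:
                total += face[axis]
    return total


def brute_force_face_counts(binary: np.ndarray) -> tuple[int, int, int]:
    """Exposed-face counts per axis by per-voxel 6-neighbor enumeration."""
    nx, ny, nz = binary.shape
    counts = [0, 0, 0]
    for x, y, z in zip(*np.nonzero(binary)):
        for axis, step in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
            nb = [x, y, z]
            nb[axis] += step
            inside = 0 <= nb[0] < nx and 0 <= nb[1] < ny and 0 <= nb[2] < nz
            if not inside or not binary[nb[0], nb[1], nb[2]]:
                counts[axis] += 1
    return tuple(counts)


def breslow_partial_loglik(time, event, X, beta) -> float:
    """Direct risk-set evaluation of the Breslow partial log-likelihood."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T
    beta = np.asarray(beta, float)
    eta = X @ beta
    ll = 0.0
    for t in np.unique(time[event]):
        deaths = event & (time == t)
        at_risk = time >= t
        d = int(deaths.sum())
        ll += eta[deaths].sum() - d * np.log(np.exp(eta[at_risk]).sum())
    return ll
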