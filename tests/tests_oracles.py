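"""Shared brute-force oracles, independent of the library code paths."""

import numpy as np


def brute_force_eig3(A: np.ndarray):
    """Eigendecomposition of a symmetric 3x3 matrix from the characteristic
    polynomial: roots of -l^3 + tr(A) l^2 - m2(A) l + det(A), eigenvectors
    from row cross-products of (A - l I)."""
    trace = np.trace(A)
    minors = (
        A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
        + A[0, 0] * A[2, 2] - A[0, 2] * A[2, 0]
        + A[1, 1] * A[2, 2] - A[1, 2] * A[2, 1]
    )
    det = np.linalg.det(A)
    lams = np.sort(np.roots([-1.0, trace, -minors, det]).real)[::-1]
    vecs = []
    for lam in lams:
        B = A - lam * np.eye(3)
        candidates = [np.cross(B[i], B[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        v = max(candidates, key=np.linalg.norm)
        vecs.append(v / np.linalg.norm(v))
    return lams, np.array(vecs).T
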