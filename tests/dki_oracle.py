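"""Independent brute-force diffusion-kurtosis oracle for cross-checks.

Fits the full 22-parameter cumulant model (diffusion tensor + kurtosis
tensor) by linear least squares on a dense multi-shell protocol, completely
independent of the fast two-shell closed form it is used to validate.
"""

from __future__ import annotations

from itertools import combinations_with_replacement
from math import factorial

import numpy as np

# unique index tuples of the symmetric D (6) and W (15) tensors
D_IDX = list(combinations_with_replacement(range(3), 2))
W_IDX = list(combinations_with_replacement(range(3), 4))


def _multiplicity(idx: tuple[int, ...]) -> int:
    counts = [idx.count(i) for i in set(idx)]
    m = factorial(len(idx))
    for c in counts:
        m //= factorial(c)
    return m


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def random_dw_pair(rng: np.random.Generator, kurt_scale: float = 0.1):
    """Random SPD diffusion tensor and fully symmetric kurtosis tensor."""
    a = rng.normal(size=(3, 3)) * 0.25
    dtensor = a @ a.T + np.eye(3) * 0.5
    raw = rng.normal(scale=kurt_scale, size=(3, 3, 3, 3))
    w = np.zeros_like(raw)
    from itertools import permutations

    for perm in set(permutations(range(4))):
        w += raw.transpose(perm)
    w /= 24.0
    return dtensor, w


def design_row(b: float, n: np.ndarray) -> np.ndarray:
    """One row of the log-linear DKI design: [1, -b * n_i n_j terms,
    (b^2/6) * n_i n_j n_k n_l terms] with symmetry multiplicities."""
    d_terms = [-b * _multiplicity(idx) * n[idx[0]] * n[idx[1]] for idx in D_IDX]
    w_terms = [
        (b**2 / 6.0) * _multiplicity(idx) * n[idx[0]] * n[idx[1]] * n[idx[2]] * n[idx[3]]
        for idx in W_IDX
    ]
    return np.array([1.0, *d_terms, *w_terms])


def fit_dki_lls(signals: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray):
    """Weighted-free LLS fit of ln S; returns (D tensor, W tensor, s0).

    The kurtosis block estimates MD^2 * W; W is recovered by dividing by
    the fitted MD^2.
    """
    X = np.stack([design_row(b, n) for b, n in zip(bvals, bvecs)])
    coef, *_ = np.linalg.lstsq(X, np.log(signals), rcond=None)
    s0 = float(np.exp(coef[0]))
    dtensor = np.zeros((3, 3))
    for val, (i, j) in zip(coef[1:7], D_IDX):
        dtensor[i, j] = dtensor[j, i] = val
    md = np.trace(dtensor) / 3.0
    wtensor = np.zeros((3, 3, 3, 3))
    for val, idx in zip(coef[7:], W_IDX):
        from itertools import permutations

        for perm in set(permutations(idx)):
            wtensor[perm] = val
    wtensor /= md**2
    return dtensor, wtensor, s0


def mean_kurtosis_tensor(w: np.ndarray) -> float:
    """Spherical average of W(n): the kurtosis-tensor mean."""
    return float(
        (w[0, 0, 0, 0] + w[1, 1, 1, 1] + w[2, 2, 2, 2]) / 5.0
        + 2.0 / 5.0 * (w[0, 0, 1, 1] + w[0, 0, 2, 2] + w[1, 1, 2, 2])
    )


def oracle_protocol(n_dirs: int = 60, shells=(0.5, 1.0, 2.0)):
    """Dense protocol: one b0 plus ``n_dirs`` directions per shell."""
    dirs = fibonacci_sphere(n_dirs)
    bvals = [0.0]
    bvecs = [np.array([0.0, 0.0, 1.0])]
    for b in shells:
        for n in dirs:
            bvals.append(b)
            bvecs.append(n)
    return np.array(bvals), np.stack(bvecs)
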