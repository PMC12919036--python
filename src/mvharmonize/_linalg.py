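"""Small shared linear-algebra helpers (symmetric roots, ridging, sign fixes)."""

from __future__ import annotations

import numpy as np

#: default ridge added to sample covariances before inversion
RIDGE = 1e-8
#: eigenvalue floor used when forming matrix square roots
EIG_FLOOR = 1e-10


def ridge_psd(S: np.ndarray, eps: float = RIDGE) -> np.ndarray:
    """Return ``S + eps*I`` (symmetrized)."""
    S = np.asarray(S, dtype=float)
    return 0.5 * (S + S.T) + eps * np.eye(S.shape[0])


def sym_inv_sqrt(S: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Symmetric (spectral) inverse square root of a PSD matrix.

    Eigenvalues are floored at ``floor`` so near-singular matrices whiten
    to a well-defined transform instead of raising.
    """
    S = 0.5 * (np.asarray(S, dtype=float) + np.asarray(S, dtype=float).T)
    w, V = np.linalg.eigh(S)
    w = np.maximum(w, floor)
    return (V / np.sqrt(w)) @ V.T


def sym_sqrt(S: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Symmetric (spectral) square root of a PSD matrix."""
    S = 0.5 * (np.asarray(S, dtype=float) + np.asarray(S, dtype=float).T)
    w, V = np.linalg.eigh(S)
    w = np.maximum(w, floor)
    return (V * np.sqrt(w)) @ V.T


def fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Eigenvector/PC signs are arbitrary; this convention makes
    decompositions reproducible across runs and BLAS builds.
    """
    vectors = np.asarray(vectors)
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def is_pd(S: np.ndarray, tol: float = 0.0) -> bool:
    w = np.linalg.eigvalsh(0.5 * (S + S.T))
    return bool(w.min() > tol)
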