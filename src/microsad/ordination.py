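"""Principal coordinates analysis (classical metric MDS).

Gower double centering of ``-0.5 * d^2`` followed by a symmetric
eigendecomposition. Eigenvalues are reported in full, negatives included
(they flag a non-Euclidean distance matrix); coordinates are returned
only for positive eigenvalues, scaled so that axis ``k`` has sum of
squares ``lambda_k``. No negative-eigenvalue correction is applied by
default; Cailliez or Lingoes corrections are available explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OrdinationResult", "pcoa"]

_EIG_TOL = 1e-10


@dataclass
class OrdinationResult:
    """Eigenstructure of a PCoA embedding.

    ``coordinates`` has one column per positive eigenvalue (axes P1,
    P2, ...); ``proportion_explained`` divides each positive eigenvalue by
    the sum of positive eigenvalues.
    """

    eigenvalues: np.ndarray  # all eigenvalues, descending
    coordinates: pd.DataFrame  # samples x positive axes
    proportion_explained: np.ndarray  # per positive axis

    def summary(self) -> str:
        lines = ["Principal coordinates analysis"]
        for k, (lam, prop) in enumerate(zip(self.eigenvalues, np.append(
                self.proportion_explained,
                [np.nan] * (len(self.eigenvalues) - len(self.proportion_explained)))), 1):
            pct = f"{100 * prop:.1f}%" if prop == prop else "-"
            lines.append(f"  axis {k}: eigenvalue {lam: .4g}  explained {pct}")
        return "\n".join(lines)


def pcoa(d: pd.DataFrame | np.ndarray, correction: str | None = None) -> OrdinationResult:
    """Embed a symmetric distance matrix into principal coordinates.

    Parameters
    ----------
    d
        Square symmetric distance matrix (labels taken from the DataFrame
        index when given).
    correction : {None, "cailliez", "lingoes"}
        Optional additive correction applied when negative eigenvalues
        occur; the default reports them unchanged with a warning.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        mat = d.to_numpy(dtype=float)
    else:
        mat = np.asarray(d, dtype=float)
        labels = [f"s{i}" for i in range(mat.shape[0])]
    n = mat.shape[0]
    if mat.shape != (n, n) or n < 2:
        raise ValueError("need a square matrix over >= 2 samples")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")

    eigvals, coords = _pcoa_eig(mat)
    if np.any(eigvals < -_EIG_TOL * max(1.0, abs(eigvals[0]))):
        if correction == "cailliez":
            # smallest c making d + c (off-diagonal) Euclidean
            c = _cailliez_constant(mat)
            corrected = mat + c
            np.fill_diagonal(corrected, 0.0)
            eigvals, coords = _pcoa_eig(corrected)
        elif correction == "lingoes":
            c = -eigvals[-1]
            corrected = np.sqrt(np.maximum(mat**2 + 2 * c, 0.0))
            np.fill_diagonal(corrected, 0.0)
            eigvals, coords = _pcoa_eig(corrected)
        elif correction is None:
            warnings.warn(
                "negative eigenvalues retained (non-Euclidean distances); "
                "pass correction='cailliez' or 'lingoes' to adjust"
            )
        else:
            raise ValueError(f"unknown correction {correction!r}")

    pos = eigvals > _EIG_TOL * max(1.0, abs(eigvals[0]) if eigvals.size else 1.0)
    pos_vals = eigvals[pos]
    axes = coords[:, pos]
    # deterministic sign: largest-magnitude coordinate on each axis is positive
    for k in range(axes.shape[1]):
        idx = np.argmax(np.abs(axes[:, k]))
        if axes[idx, k] < 0:
            axes[:, k] = -axes[:, k]
    prop = pos_vals / pos_vals.sum() if pos_vals.size else pos_vals
    coord_df = pd.DataFrame(
        axes, index=labels, columns=[f"P{k+1}" for k in range(axes.shape[1])]
    )
    return OrdinationResult(eigenvalues=eigvals, coordinates=coord_df, proportion_explained=prop)


def _pcoa_eig(mat: np.ndarray):
    n = mat.shape[0]
    A = -0.5 * mat**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J  # Gower-centered
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = np.sqrt(np.maximum(eigvals, 0.0))
    return eigvals, eigvecs * scale  # axis k sum of squares = lambda_k


def _cailliez_constant(mat: np.ndarray) -> float:
    n = mat.shape[0]
    d1 = -0.5 * mat**2
    d2 = -0.5 * mat
    J = np.eye(n) - np.ones((n, n)) / n
    top = np.block([[np.zeros((n, n)), 2 * (J @ d1 @ J)], [-np.eye(n), -4 * (J @ d2 @ J)]])
    eig = np.linalg.eigvals(top)
    return float(np.max(eig.real))
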