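"""Published PCA bookkeeping tables for sugarcane leaf image features.

A published sugarcane study reports, for each growth stage (tillering,
elongation) and each feature block (CF: 24 color features, TF: 5 texture
features), the first five principal-component eigenvalues and cumulative
variance contribution rates (CVCR, percent).  Those printed tables are used
here as a fixed worked example for the Kaiser-retention and CVCR bookkeeping:
recomputing the cumulative rates from the printed eigenvalues must reproduce
the printed percentages, and eigenvalue-> 1 retention must give three color
components and one texture component per stage.

Only the block's *implied total variance* is unknown (the tables list five of
24 color components, and the texture total does not equal the feature count).
Each printed row k implies a total ``T_k = 100 * cumsum(E)_k / CVCR_k``; the
block's total is estimated as the value most consistent with every printed
row (minimax deviation), which keeps the recomputation within the rounding of
the printed three-decimal eigenvalues (anchoring on PC1 alone propagates that
rounding to ~0.012 percentage points on the texture blocks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "REFERENCE_PCA_TABLES",
    "implied_total_variance",
    "recompute_cvcr",
    "pc1_anchor_cvcr",
]

#: stage -> block -> {"eigenvalues": ..., "cvcr": ...} (top five PCs, printed values)
REFERENCE_PCA_TABLES: dict[str, dict[str, dict[str, tuple[float, ...]]]] = {
    "tillering": {
        "CF": {
            "eigenvalues": (14.427, 5.465, 2.249, 0.483, 0.314),
            "cvcr": (61.726, 85.106, 94.729, 96.795, 98.137),
        },
        "TF": {
            "eigenvalues": (3.319, 0.546, 0.244, 0.041, 0.002),
            "cvcr": (79.941, 93.091, 98.967, 99.944, 100.0),
        },
    },
    "elongation": {
        "CF": {
            "eigenvalues": (12.204, 8.409, 2.513, 0.566, 0.368),
            "cvcr": (50.002, 84.456, 94.750, 97.071, 98.578),
        },
        "TF": {
            "eigenvalues": (3.988, 0.731, 0.351, 0.013, 0.002),
            "cvcr": (78.437, 92.804, 99.716, 99.966, 100.0),
        },
    },
}


def implied_total_variance(eigenvalues, cvcr) -> float:
    """Block total most consistent with all printed rows (minimax deviation).

    Each row k implies ``T_k = 100 * cumsum(E)_k / CVCR_k``; the minimax
    estimate minimizes the largest recomputation error over the rows, which is
    the right notion of "the single total the printed table was computed
    from" once the eigenvalues have been rounded for printing.
    """
    from scipy.optimize import minimize_scalar

    e = np.asarray(eigenvalues, dtype=float)
    c = np.asarray(cvcr, dtype=float)
    if e.shape != c.shape or e.size == 0:
        raise ValueError("eigenvalues and cvcr must be equal-length, nonempty")
    cum = np.cumsum(e)
    implied = 100.0 * cum / c
    res = minimize_scalar(
        lambda t: np.abs(100.0 * cum / t - c).max(),
        bounds=(implied.min(), implied.max()),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def recompute_cvcr(eigenvalues, total: float) -> np.ndarray:
    """Cumulative variance contribution rates (percent) given a total."""
    return 100.0 * np.cumsum(np.asarray(eigenvalues, dtype=float)) / total


def pc1_anchor_cvcr(eigenvalues, cvcr1: float) -> np.ndarray:
    """CVCR recomputed with the total implied by PC1 alone (``T = 100*E1/CVCR1``)."""
    e = np.asarray(eigenvalues, dtype=float)
    return recompute_cvcr(e, 100.0 * e[0] / cvcr1)
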