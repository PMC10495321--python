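"""Correlation screening and blockwise PCA; assembly of model input variants.

Two reduction routes feed the regression layer.  The SCT ("strongly
correlated term") route keeps raw features whose absolute Pearson correlation
with leaf N exceeds a threshold (0.7 by default).  The PCA route standardizes
the color block (24 features) and the texture block (5 features) separately,
eigendecomposes each correlation matrix, and keeps components with eigenvalue
> 1 (Kaiser criterion, with a retain-one floor).  Six input variants result:
CF-SCT, TF-SCT, CTIF-SCT and CF-PCA, TF-PCA, C-T-PCA (color + texture scores
concatenated).

Everything here has an explicit fit/transform split so cross-validation can
refit selectors inside each training fold (no test-fold leakage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import COLOR_FEATURE_NAMES, TEXTURE_FEATURE_NAMES

__all__ = [
    "VARIANT_NAMES",
    "CorrelationReport",
    "PcaModel",
    "InputVariant",
    "pearson_screen",
    "fit_pca",
    "kaiser_retain",
    "pca_transform",
    "VariantBuilder",
    "assemble_variant",
]

VARIANT_NAMES = ("CF-SCT", "TF-SCT", "CTIF-SCT", "CF-PCA", "TF-PCA", "C-T-PCA")

_BLOCKS = {"CF": list(COLOR_FEATURE_NAMES), "TF": list(TEXTURE_FEATURE_NAMES)}


@dataclass
class CorrelationReport:
    r: pd.Series  # Pearson r per feature
    threshold: float
    flagged_constant: list[str]

    @property
    def selected(self) -> list[str]:
        return [name for name, v in self.r.items() if abs(v) > self.threshold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.r, "abs_r": self.r.abs(), "selected": self.r.abs() > self.threshold}
        )


def pearson_screen(table: pd.DataFrame, y: np.ndarray, threshold: float = 0.7) -> CorrelationReport:
    """Per-feature sample Pearson correlation with ``y``; select on |r|.

    Constant (or NaN-containing) columns get r = 0 and are flagged rather than
    dropped silently.
    """
    y = np.asarray(y, dtype=float)
    if len(table) != len(y):
        raise ValueError("table and y lengths differ")
    if len(y) < 3:
        raise ValueError("need at least 3 samples for correlation screening")
    if np.std(y) < 1e-15:
        raise ValueError("y is constant")
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    rs: dict[str, float] = {}
    flagged: list[str] = []
    for name in table.columns:
        x = table[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)) or np.std(x) < 1e-15:
            rs[name] = 0.0
            flagged.append(name)
            continue
        xc = x - x.mean()
        rs[name] = float((xc @ yc) / np.sqrt((xc @ xc) * ss_y))
    return CorrelationReport(r=pd.Series(rs), threshold=threshold, flagged_constant=flagged)


@dataclass
class PcaModel:
    """Standardized (correlation-matrix) PCA of one feature block."""

    block: str
    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # feature x component
    eigenvalues: np.ndarray  # descending
    k_retained: int
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def contribution_rates(self) -> np.ndarray:
        """Per-component variance contribution, percent of total."""
        return self.eigenvalues / self.eigenvalues.sum() * 100.0

    @property
    def cvcr(self) -> np.ndarray:
        """Cumulative variance contribution rates, percent."""
        return np.cumsum(self.contribution_rates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": self.block,
                "PC": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": self.eigenvalues,
                "CVCR": self.cvcr,
            }
        )


def fit_pca(table: pd.DataFrame, block: str = "CF", standardize: bool = True) -> PcaModel:
    """Eigendecompose the (correlation) matrix of a feature block.

    Constant columns are dropped with a warning.  Sign convention: each
    loading vector's largest-magnitude entry is positive.  With ``n <= d`` a
    rank-deficiency warning is emitted but the decomposition proceeds.
    """
    X = table.to_numpy(dtype=float)
    if len(table) < 2:
        raise ValueError("PCA needs more than one sample")
    if not np.all(np.isfinite(X)):
        raise ValueError("PCA input contains non-finite values")
    sds = X.std(axis=0, ddof=1)
    keep = sds > 1e-12
    dropped = [n for n, k in zip(table.columns, keep) if not k]
    if dropped:
        warnings.warn(f"fit_pca: dropping constant columns {dropped}", stacklevel=2)
    if not keep.any():
        raise ValueError("all columns constant; nothing to decompose")
    names = [n for n, k in zip(table.columns, keep) if k]
    X = X[:, keep]
    n, d = X.shape
    if n <= d:
        warnings.warn(f"fit_pca: n={n} <= d={d}; correlation matrix is rank deficient", stacklevel=2)
    means = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1) if standardize else np.ones(d)
    Z = (X - means) / scale
    corr = Z.T @ Z / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    return PcaModel(
        block=block,
        feature_names=names,
        means=means,
        sds=scale,
        loadings=evecs,
        eigenvalues=evals,
        k_retained=kaiser_retain(evals),
        dropped_constant=dropped,
    )


def kaiser_retain(eigenvalues: np.ndarray) -> int:
    """Number of components with eigenvalue > 1; floor of one with a warning."""
    evals = np.asarray(eigenvalues, dtype=float)
    if evals.size == 0:
        raise ValueError("empty eigenvalue sequence")
    if np.any(np.diff(evals) > 1e-9):
        raise ValueError("eigenvalues must be nonincreasing")
    k = int((evals > 1.0).sum())
    if k == 0:
        warnings.warn("kaiser_retain: no eigenvalue > 1; retaining one component", stacklevel=2)
        return 1
    return k


def pca_transform(model: PcaModel, table: pd.DataFrame, k: int | None = None) -> np.ndarray:
    """Project rows onto the retained loadings (standardized by the model)."""
    missing = [n for n in model.feature_names if n not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    k = model.k_retained if k is None else k
    X = table.loc[:, model.feature_names].to_numpy(dtype=float)
    Z = (X - model.means) / model.sds
    return Z @ model.loadings[:, :k]


@dataclass
class InputVariant:
    name: str
    X: np.ndarray  # n x d design matrix
    provenance: list[str]  # one entry per column

    @property
    def d(self) -> int:
        return self.X.shape[1]


class VariantBuilder:
    """Fit/transform wrapper producing one named input variant.

    ``fit`` sees training rows only; ``transform`` may then be applied to any
    rows with the same columns, which is what keeps cross-validation honest.
    """

    def __init__(self, name: str, threshold: float = 0.7):
        if name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")
        self.name = name
        self.threshold = threshold
        self._selected: list[str] | None = None
        self._pca: dict[str, PcaModel] = {}

    def fit(self, table: pd.DataFrame, y: np.ndarray) -> "VariantBuilder":
        if self.name.endswith("SCT"):
            blocks = {"CF-SCT": ["CF"], "TF-SCT": ["TF"], "CTIF-SCT": ["CF", "TF"]}[self.name]
            selected: list[str] = []
            for blk in blocks:
                report = pearson_screen(table.loc[:, _BLOCKS[blk]], y, self.threshold)
                selected.extend(report.selected)
            if not selected:
                raise ValueError(f"variant {self.name}: no feature passed |r| > {self.threshold}")
            self._selected = selected
        else:
            blocks = {"CF-PCA": ["CF"], "TF-PCA": ["TF"], "C-T-PCA": ["CF", "TF"]}[self.name]
            self._pca = {blk: fit_pca(table.loc[:, _BLOCKS[blk]], block=blk) for blk in blocks}
        return self

    def transform(self, table: pd.DataFrame) -> InputVariant:
        if self._selected is not None:
            X = table.loc[:, self._selected].to_numpy(dtype=float)
            return InputVariant(self.name, X, list(self._selected))
        if not self._pca:
            raise RuntimeError("VariantBuilder not fitted")
        cols, prov = [], []
        for blk, model in self._pca.items():
            scores = pca_transform(model, table)
            cols.append(scores)
            prov.extend(f"{blk}-PC{i + 1}" for i in range(scores.shape[1]))
        return InputVariant(self.name, np.column_stack(cols), prov)

    def fit_transform(self, table: pd.DataFrame, y: np.ndarray) -> InputVariant:
        return self.fit(table, y).transform(table)


def assemble_variant(
    name: str, table: pd.DataFrame, y: np.ndarray, threshold: float = 0.7
) -> InputVariant:
    """Convenience: fit the variant's selectors on all rows and transform them."""
    return VariantBuilder(name, threshold=threshold).fit_transform(table, y)
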