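"""Machine-learning curation of the extended library: LASSO descriptor
selection and support-vector regression of CCS and RT from molecular
descriptors.

The workflow mirrors QSPR practice for ion-mobility libraries: molecular
descriptors are computed from SMILES (or loaded from file), reduced by
LASSO at the minimum-CV-MSE lambda (10-fold), and an RBF-kernel SVR is
trained on the standardized selected descriptors.  Defaults: C = 23 and
γ = 0.1/12 for CCS; C = 29 and γ = 0.25/24 for RT; ε = 0.1.

Validation metrics: squared Pearson correlation R² (coefficient of
determination also reported), median relative error (MRE, %) for CCS and
median absolute error (ME, s) for RT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin, clone
from sklearn.linear_model import LassoCV, lasso_path
from sklearn.model_selection import KFold, LeaveOneOut
from sklearn.svm import SVR

__all__ = [
    "LassoDescriptorSelector", "SterolPropertyPredictor", "ValidationMetrics",
    "validate", "loo_validate", "compute_descriptors", "read_descriptors",
    "read_split",
]

SVR_DEFAULTS = {
    "ccs": {"C": 23.0, "gamma": 0.1 / 12},
    "rt": {"C": 29.0, "gamma": 0.25 / 24},
}


class LassoDescriptorSelector(BaseEstimator, TransformerMixin):
    """Select descriptors with nonzero LASSO coefficients at the
    minimum-mean-squared-error lambda from k-fold cross-validation.

    Falls back (with a warning) to the largest lambda yielding at least one
    nonzero coefficient when the CV-optimal model is empty.
    """

    def __init__(self, n_folds: int = 10, seed: int = 0):
        self.n_folds = n_folds
        self.seed = seed

    def fit(self, X: pd.DataFrame, y):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y):
            raise ValueError("X rows must align with y")
        if len(X) < self.n_folds:
            raise ValueError(f"fewer rows ({len(X)}) than folds ({self.n_folds})")
        if X.columns.duplicated().any():
            raise ValueError("descriptor names must be unique")
        cv = KFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter on tiny folds
            model = LassoCV(cv=cv, random_state=self.seed,
                            max_iter=50_000).fit(X.values, y)
        mask = model.coef_ != 0
        if not mask.any():
            warnings.warn("LASSO selected no descriptors at the CV-optimal lambda; "
                          "falling back to the largest lambda with a nonzero coefficient")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                alphas, coefs, _ = lasso_path(X.values, y, alphas=model.alphas_)
            nz = (coefs != 0).any(axis=0)
            if nz.any():
                mask = coefs[:, int(np.argmax(nz))] != 0
        self.alpha_ = float(model.alpha_)
        self.support_ = np.asarray(mask)
        self.selected_ = [c for c, m in zip(X.columns, mask) if m]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_]


class SterolPropertyPredictor(BaseEstimator, RegressorMixin):
    """SVR prediction of CCS (Å²) or RT (s) from molecular descriptors.

    Pipeline: median imputation → optional LASSO selection → training-set
    standardization → RBF-kernel SVR.  Deterministic given the seed.

    Parameters
    ----------
    target : {"ccs", "rt"}
        Chooses the default hyperparameters (C, γ).
    C, gamma, epsilon : float or None
        Explicit SVR hyperparameters; ``None`` uses the target defaults.
    select : bool
        Run LASSO descriptor selection before the SVR.
    n_folds, seed : int
        Cross-validation folds and RNG seed for the selector.
    """

    def __init__(self, target: str = "ccs", C: float | None = None,
                 gamma: float | None = None, epsilon: float = 0.1,
                 select: bool = True, n_folds: int = 10, seed: int = 0):
        self.target = target
        self.C = C
        self.gamma = gamma
        self.epsilon = epsilon
        self.select = select
        self.n_folds = n_folds
        self.seed = seed

    def _check_finite(self, X: pd.DataFrame) -> None:
        bad = ~np.isfinite(X.values)
        if bad.any():
            rows = list(X.index[bad.any(axis=1)])[:5]
            cols = list(X.columns[bad.any(axis=0)])[:5]
            raise ValueError(f"non-finite descriptor values (rows {rows}, columns {cols})")

    def fit(self, X: pd.DataFrame, y):
        if self.target not in SVR_DEFAULTS:
            raise ValueError(f"target must be 'ccs' or 'rt', got {self.target!r}")
        X = pd.DataFrame(X).apply(pd.to_numeric)
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite target values")
        # median imputation with training statistics
        self.impute_medians_ = X.median()
        X = X.fillna(self.impute_medians_)
        self._check_finite(X)
        if self.select:
            self.selector_ = LassoDescriptorSelector(self.n_folds, self.seed).fit(X, y)
            sel = self.selector_.selected_
            X = X[sel] if sel else X  # degenerate fallback: keep all
            self.selected_descriptors_ = sel if sel else list(X.columns)
        else:
            self.selector_ = None
            self.selected_descriptors_ = list(X.columns)
        self.mean_ = X.mean().values
        scale = X.std(ddof=0).values
        self.scale_ = np.where(scale > 0, scale, 1.0)
        Z = (X.values - self.mean_) / self.scale_
        defaults = SVR_DEFAULTS[self.target]
        self.svr_ = SVR(kernel="rbf",
                        C=self.C if self.C is not None else defaults["C"],
                        gamma=self.gamma if self.gamma is not None else defaults["gamma"],
                        epsilon=self.epsilon)
        self.svr_.fit(Z, y)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X).apply(pd.to_numeric)
        X = X.reindex(columns=list(self.impute_medians_.index)).fillna(self.impute_medians_)
        X = X[self.selected_descriptors_]
        self._check_finite(X)
        Z = (X.values - self.mean_) / self.scale_
        return self.svr_.predict(Z)


@dataclass(frozen=True)
class ValidationMetrics:
    """External/LOO validation summary."""

    r_squared: float          # squared Pearson correlation
    r2_cod: float             # coefficient of determination
    mre: float | None         # median relative error, % (CCS mode)
    me: float | None          # median absolute error, s (RT mode)
    n: int


def validate(pred, obs, mode: str = "ccs") -> ValidationMetrics:
    """Compare predictions against observations.

    CCS mode reports the median relative error (% of observed); pairs with
    zero observed value are excluded with a warning.  RT mode reports the
    median absolute error in seconds.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size != obs.size or pred.size < 2:
        raise ValueError("pred and obs must have equal length >= 2")
    if mode not in ("ccs", "rt"):
        raise ValueError(f"mode must be 'ccs' or 'rt', got {mode!r}")
    if mode == "ccs" and np.any(obs == 0):
        warnings.warn("excluding pairs with zero observed CCS from relative error")
        keep = obs != 0
        pred, obs = pred[keep], obs[keep]
    resid = pred - obs
    if np.std(obs) > 0 and np.std(pred) > 0:
        r2 = float(pearsonr(pred, obs).statistic ** 2)
    else:
        r2 = 1.0 if np.allclose(pred, obs) else 0.0
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    cod = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    mre = float(np.median(np.abs(resid) / np.abs(obs)) * 100.0) if mode == "ccs" else None
    me = float(np.median(np.abs(resid))) if mode == "rt" else None
    return ValidationMetrics(r_squared=r2, r2_cod=cod, mre=mre, me=me, n=int(obs.size))


def loo_validate(X: pd.DataFrame, y, predictor: SterolPropertyPredictor | None = None,
                 mode: str | None = None) -> ValidationMetrics:
    """Leave-one-out validation: each point predicted by a model fitted on
    the remaining n−1."""
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float).ravel()
    if len(X) < 3:
        raise ValueError("LOO validation needs at least 3 rows")
    base = predictor if predictor is not None else SterolPropertyPredictor()
    preds = np.empty_like(y)
    for train_idx, test_idx in LeaveOneOut().split(X):
        model = clone(base).fit(X.iloc[train_idx], y[train_idx])
        preds[test_idx] = model.predict(X.iloc[test_idx])
    return validate(preds, y, mode=mode if mode is not None else base.target)


# --- descriptor sources -----------------------------------------------------

def compute_descriptors(smiles: list[str], names: list[str] | None = None) -> pd.DataFrame:
    """Compute molecular descriptors from SMILES with RDKit.

    Returns a compounds × descriptors frame restricted to finite numeric
    descriptors.  The descriptor set is the RDKit 2-D collection — a
    different toolkit's set will differ in membership, which is why a file
    loader is provided for externally computed matrices.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    rows = []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES at row {i}: {smi!r}")
        rows.append(Descriptors.CalcMolDescriptors(mol))
    df = pd.DataFrame(rows, index=names if names is not None else range(len(smiles)))
    df = df.apply(pd.to_numeric, errors="coerce")
    df = df.replace([np.inf, -np.inf], np.nan)
    return df.dropna(axis=1, how="any")


def read_descriptors(path: str | Path) -> pd.DataFrame:
    """Load a descriptor matrix: first column compound name, header row
    descriptor names."""
    from .library import _read_delimited

    df = _read_delimited(path)
    df = df.set_index(df.columns[0])
    if df.columns.duplicated().any():
        raise ValueError("descriptor names must be unique")
    return df.apply(pd.to_numeric)


def read_split(path: str | Path) -> pd.Series:
    """Load a two-column (name, train|validation) split file."""
    from .library import _read_delimited

    df = _read_delimited(path)
    s = df.set_index(df.columns[0])[df.columns[1]].astype(str)
    bad = sorted(set(s) - {"train", "validation"})
    if bad:
        raise ValueError(f"split labels must be train/validation, got {bad}")
    return s
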