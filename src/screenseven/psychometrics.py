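"""Instrument-validation battery for the seven questionnaire items.

Inter-item Pearson correlations, Kaiser–Meyer–Olkin sampling adequacy,
Bartlett's test of sphericity, principal-component factor extraction with
the Kaiser eigenvalue-greater-than-one retention rule, and Cronbach's
alpha.  All statistics are computed from their defining formulas on the
item-score matrix (ordinal scores treated as numeric, Pearson
correlations; unbiased n-1 variances throughout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import StatisticalError
from .scoring import ITEM_NAMES, score_items
from .survey import SurveyRecord


def item_matrix(records: list[SurveyRecord]) -> np.ndarray:
    """n x 7 matrix of rubric item scores, columns in the fixed item order."""
    return np.array(
        [score_items(r.response).as_tuple() for r in records], dtype=float
    )


def correlation_matrix(items: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the item columns."""
    items = np.asarray(items, dtype=float)
    sd = items.std(axis=0, ddof=1)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = ", ".join(ITEM_NAMES[i] if i < len(ITEM_NAMES) else str(i)
                          for i in dead)
        raise StatisticalError(f"zero-variance item column(s): {names}")
    return np.corrcoef(items, rowvar=False)


def kmo(correlations: np.ndarray) -> tuple[float, np.ndarray]:
    """Overall and per-item Kaiser–Meyer–Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, with q the
    anti-image partial correlations from the scaled inverse correlation
    matrix.  An identity correlation matrix has no shared variance; KMO is
    undefined and returned as 0 with a warning.
    """
    R = np.asarray(correlations, dtype=float)
    k = R.shape[0]
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise StatisticalError(
            "correlation matrix is singular; consider removing an item"
        ) from exc
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    off = ~np.eye(k, dtype=bool)
    r2 = (R[off] ** 2).sum()
    q2 = (Q[off] ** 2).sum()
    if r2 + q2 == 0:
        warnings.warn("no shared variance between items; KMO undefined, "
                      "returning 0", stacklevel=2)
        return 0.0, np.zeros(k)
    per_item = np.empty(k)
    for i in range(k):
        m = np.ones(k, dtype=bool)
        m[i] = False
        ri = (R[i, m] ** 2).sum()
        qi = (Q[i, m] ** 2).sum()
        per_item[i] = ri / (ri + qi) if ri + qi > 0 else 0.0
    return float(r2 / (r2 + q2)), per_item


def bartlett_sphericity(
    correlations: np.ndarray, n: int
) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2k + 5)/6) * ln det R on k(k-1)/2 degrees of freedom.
    """
    R = np.asarray(correlations, dtype=float)
    k = R.shape[0]
    if n <= k:
        raise StatisticalError(f"need more respondents ({n}) than items ({k})")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise StatisticalError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * k + 5) / 6) * logdet
    df = k * (k - 1) // 2
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    n_factors: int
    loadings: np.ndarray  # k x n_factors
    factor_assignment: np.ndarray  # item index -> factor index


def pca_factors(
    correlations: np.ndarray, n_factors: int | None = None
) -> PcaResult:
    """Principal-component extraction from the correlation matrix.

    Components with eigenvalue strictly > 1 are retained (Kaiser rule)
    unless a fixed ``n_factors`` is requested; loadings are eigenvector *
    sqrt(eigenvalue); each item is assigned to the factor on which it has
    the largest absolute loading.
    """
    R = np.asarray(correlations, dtype=float)
    w, v = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    retain = int((w > 1).sum()) if n_factors is None else int(n_factors)
    retain = max(retain, 0)
    loadings = v[:, :retain] * np.sqrt(np.clip(w[:retain], 0, None))
    # sign convention: flip each component so its largest loading is positive
    for j in range(retain):
        i = np.abs(loadings[:, j]).argmax()
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    assignment = (
        np.abs(loadings).argmax(axis=1) if retain
        else np.full(R.shape[0], -1)
    )
    return PcaResult(
        eigenvalues=w, n_factors=retain, loadings=loadings,
        factor_assignment=assignment,
    )


@dataclass
class ReliabilityReport:
    cronbach_alpha: float
    item_variances: np.ndarray
    total_variance: float


def cronbach_alpha(items: np.ndarray) -> ReliabilityReport:
    """alpha = (k/(k-1)) * (1 - sum(var_item) / var(total)) with unbiased
    sample variances of the items and of the row-sum total."""
    items = np.asarray(items, dtype=float)
    n, k = items.shape
    if k < 2:
        raise StatisticalError("Cronbach's alpha needs at least 2 items")
    item_var = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise StatisticalError("total score has zero variance")
    alpha = k / (k - 1) * (1 - item_var.sum() / total_var)
    return ReliabilityReport(
        cronbach_alpha=float(alpha),
        item_variances=item_var,
        total_variance=float(total_var),
    )


@dataclass
class FactorReport:
    """The full validation battery for one item matrix."""

    n: int
    kmo_overall: float
    kmo_per_item: np.ndarray
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    eigenvalues: np.ndarray
    n_factors: int
    loadings: np.ndarray
    factor_assignment: np.ndarray
    cronbach_alpha: float
    item_names: tuple[str, ...] = field(default=ITEM_NAMES)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "kmo": self.kmo_overall,
            "kmo_per_item": dict(zip(self.item_names,
                                     map(float, self.kmo_per_item))),
            "bartlett": {
                "chi2": self.bartlett_chi2,
                "df": self.bartlett_df,
                "p": self.bartlett_p,
            },
            "eigenvalues": [float(x) for x in self.eigenvalues],
            "n_factors": self.n_factors,
            "loadings": [[float(x) for x in row] for row in self.loadings],
            "factor_assignment": {
                name: int(f)
                for name, f in zip(self.item_names, self.factor_assignment)
            },
            "alpha": self.cronbach_alpha,
        }


def validation_battery(
    items: np.ndarray, n_factors: int | None = None
) -> FactorReport:
    """Run the whole battery on an n x 7 item-score matrix."""
    items = np.asarray(items, dtype=float)
    R = correlation_matrix(items)
    kmo_overall, kmo_items = kmo(R)
    chi2, df, p = bartlett_sphericity(R, items.shape[0])
    pca = pca_factors(R, n_factors=n_factors)
    rel = cronbach_alpha(items)
    return FactorReport(
        n=items.shape[0],
        kmo_overall=kmo_overall,
        kmo_per_item=kmo_items,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=p,
        eigenvalues=pca.eigenvalues,
        n_factors=pca.n_factors,
        loadings=pca.loadings,
        factor_assignment=pca.factor_assignment,
        cronbach_alpha=rel.cronbach_alpha,
    )


def battery_by_age_group(
    records: list[SurveyRecord], split_months: int = 48,
    n_factors: int | None = None,
) -> dict[str, FactorReport]:
    """Battery overall and split into younger (<= split) / older (> split)
    age groups, mirroring the 24–48 vs 49–72 month reporting convention."""
    out = {"overall": validation_battery(item_matrix(records), n_factors)}
    young = [r for r in records if r.child_age_months <= split_months]
    old = [r for r in records if r.child_age_months > split_months]
    if young:
        out["24_48_months"] = validation_battery(item_matrix(young), n_factors)
    if old:
        out["49_72_months"] = validation_battery(item_matrix(old), n_factors)
    return out
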