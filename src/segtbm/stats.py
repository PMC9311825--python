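"""Covariate-adjusted group tests per segment and dependent-FDR correction.

Size differences use a Student's t on the group coefficient of a linear model
(equal-variance pooled t when the covariate set is empty).  Shape differences
use the first canonical correlation between the retained component scores and
the group indicator after both are residualized on the covariate design, with
the p-value from Rao's F transform of Wilks' lambda (exact here, since the
indicator set is one-dimensional).  All p-values from all segments, features
and contrasts form one Benjamini-Yekutieli family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CollinearityError, NotComputableError

__all__ = [
    "ContrastSpec",
    "ContrastResults",
    "default_contrasts",
    "build_design",
    "residualize",
    "size_test",
    "shape_test",
    "fdr_dep",
    "run_all_contrasts",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "sex", "site", "family")

MUTATIONS = ("C9orf72", "GRN", "MAPT")
CARRIER_STATUSES = ("asymptomatic", "symptomatic")
NONCARRIER = "non-carrier"


@dataclass(frozen=True)
class ContrastSpec:
    """One carrier group versus the non-carriers of the same mutation."""

    mutation: str
    status: str  # "asymptomatic" or "symptomatic"

    @property
    def name(self) -> str:
        return f"{self.mutation}:{self.status}"

    def subject_mask(self, table: pd.DataFrame) -> np.ndarray:
        return (
            (table["mutation"] == self.mutation)
            & table["status"].isin([self.status, NONCARRIER])
        ).to_numpy()

    def group_indicator(self, table: pd.DataFrame) -> np.ndarray:
        """1 for carriers of interest, 0 for non-carriers, on the full table."""
        return (table["status"] == self.status).to_numpy(dtype=float)


def default_contrasts() -> list:
    """The six mutation x genetic-status contrasts."""
    return [ContrastSpec(m, s) for m in MUTATIONS for s in CARRIER_STATUSES]


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    table: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
) -> tuple[np.ndarray, list]:
    """Intercept + covariate design; categoricals (site, family) dummy-coded.

    Levels with a single subject are dropped with a warning (they absorb one
    observation and carry no between-group information).  Raises
    :class:`CollinearityError` naming aliased columns if the result is rank
    deficient.
    """
    n = len(table)
    cols = [np.ones(n)]
    names = ["intercept"]
    for cov in covariates:
        values = table[cov]
        if cov in ("site", "family") or values.dtype == object:
            levels = sorted(values.unique())
            for lvl in levels[1:]:  # first level is the reference
                indicator = (values == lvl).to_numpy(dtype=float)
                if indicator.sum() < 2:
                    warnings.warn(
                        f"dropping {cov} level {lvl!r} with a single subject",
                        stacklevel=2,
                    )
                    continue
                cols.append(indicator)
                names.append(f"{cov}[{lvl}]")
        else:
            cols.append(values.to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise CollinearityError(
            f"design matrix rank deficient; aliased columns: {aliased}", aliased
        )
    return X, names


def _aliased_columns(X: np.ndarray, names) -> list:
    aliased = []
    kept = X[:, :1]
    for j in range(1, X.shape[1]):
        trial = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(trial) == kept.shape[1]:
            aliased.append(names[j])
        else:
            kept = trial
    return aliased


def residualize(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``values`` on the design matrix."""
    values = np.asarray(values, dtype=float)
    design = np.asarray(design, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise CollinearityError("design matrix rank deficient")
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ beta
    return resid[:, 0] if squeeze else resid


# ---------------------------------------------------------------------------
# tests


def size_test(values: np.ndarray, group: np.ndarray, design_cov: np.ndarray | None = None):
    """t statistic, two-sided p, and df for the group coefficient of
    ``values ~ covariates + group``.

    With no covariates this equals the classical equal-variance pooled
    two-sample t exactly.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group, dtype=float)
    n = values.size
    if design_cov is None:
        design_cov = np.ones((n, 1))
    if min((group == g).sum() for g in np.unique(group)) < 2 or np.unique(group).size < 2:
        raise NotComputableError("each group needs at least 2 subjects")
    X = np.column_stack([design_cov, group])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CollinearityError("group indicator aliased with covariates")
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    df = n - rank
    rss = float(resid @ resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    if rss <= max(1.0, float(values @ values)) * n * np.finfo(float).eps:
        warnings.warn("zero residual variance; p set to 0", stacklevel=2)
        return float(np.sign(beta[-1]) * np.inf), 0.0, df
    sigma2 = rss / df
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    t = float(beta[-1] / se)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, p, df


def shape_test(scores: np.ndarray, group: np.ndarray, design_cov: np.ndarray | None = None):
    """First canonical correlation between shape scores and the group
    indicator, with covariates partialled out of both sets.

    Returns ``(canonical_r, p)``; the p-value comes from Rao's F transform of
    Wilks' lambda, exact for a one-dimensional second set.  With one retained
    component and no covariates this equals the equal-variance t-test p on
    that component.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    group = np.asarray(group, dtype=float)
    n = scores.shape[0]
    if scores.shape[1] < 1:
        raise NotComputableError("no retained shape components")
    if design_cov is None:
        design_cov = np.ones((n, 1))
    c = np.linalg.matrix_rank(design_cov)
    rx = residualize(scores, design_cov)
    ry = residualize(group, design_cov)
    ry_norm = np.linalg.norm(ry)
    if ry_norm == 0:
        raise NotComputableError("group indicator fully explained by covariates")
    # orthonormal basis of the residualized score space; rank-deficient score
    # sets degrade gracefully to their effective dimension
    Q, R = np.linalg.qr(rx)
    diag = np.abs(np.diag(R))
    keep = diag > (diag.max() if diag.size else 0) * max(rx.shape) * np.finfo(float).eps
    if not keep.any():
        raise NotComputableError("score matrix is zero after residualization")
    if keep.sum() < scores.shape[1]:
        warnings.warn("rank-deficient score set; using its effective rank", stacklevel=2)
    Q = Q[:, keep]
    p_dim = Q.shape[1]
    r = float(np.linalg.norm(Q.T @ (ry / ry_norm)))
    r = min(r, 1.0)
    df2 = n - c - p_dim
    if df2 <= 0:
        raise NotComputableError("not enough error degrees of freedom for CCA")
    lam = 1.0 - r**2
    if lam <= 0:
        return 1.0, 0.0
    F = (1.0 - lam) / lam * df2 / p_dim
    p = float(sps.f.sf(F, p_dim, df2))
    return r, p


def fdr_dep(p_values, alpha: float = 0.05):
    """Benjamini-Yekutieli threshold and flags for arbitrary dependence.

    Rejects the largest ``i`` with ``p_(i) <= i * alpha / (m * c(m))`` where
    ``c(m) = sum_{j<=m} 1/j``; the threshold is that order statistic (0 if no
    rejection) and flags mark ``p <= threshold``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    cutoffs = np.arange(1, m + 1) * alpha / (m * c_m)
    passing = np.flatnonzero(sorted_p <= cutoffs)
    if passing.size == 0:
        return 0.0, np.zeros(m, dtype=bool)
    threshold = float(sorted_p[passing[-1]])
    return threshold, p <= threshold


# ---------------------------------------------------------------------------
# the full testing family


@dataclass
class ContrastResults:
    """Tidy per-(segment, contrast, feature) test results plus FDR bookkeeping."""

    frame: pd.DataFrame
    alpha: float
    fdr_threshold: float
    family_size: int
    n_not_computable: int = 0
    warnings_log: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "fdr_threshold": self.fdr_threshold,
            "family_size": self.family_size,
            "n_significant": int(self.frame["significant"].sum()),
            "n_not_computable": self.n_not_computable,
        }


def run_all_contrasts(
    tree,
    features: dict,
    table: pd.DataFrame,
    alpha: float = 0.05,
    contrasts=None,
    covariates=DEFAULT_COVARIATES,
    pooled_fdr: bool = True,
) -> ContrastResults:
    """Size and shape tests for every tree node under every contrast, with one
    pooled dependent-FDR family across all resulting p-values.

    ``features`` maps node id to ``(SizeFeature, ShapeFeature)`` as produced by
    :func:`segtbm.features.compute_tree_features`.  Shape tests with zero
    retained components are recorded as not computable and excluded from the
    FDR family.
    """
    if contrasts is None:
        contrasts = default_contrasts()
    rows = []
    n_skipped = 0
    for contrast in contrasts:
        sel = contrast.subject_mask(table)
        sub = table.loc[sel].reset_index(drop=True)
        group = contrast.group_indicator(table)[sel]
        if group.sum() < 2 or (1 - group).sum() < 2:
            # contrast not represented in this cohort
            n_skipped += 2 * len(features)
            continue
        design, _ = build_design(sub, covariates)
        for node_id in sorted(features):
            size, shape = features[node_id]
            level = tree.nodes[node_id].level
            t, p, _ = size_test(size.values[sel], group, design)
            rows.append((node_id, level, contrast.name, "size", t, p))
            if shape.k_retained >= 1:
                try:
                    r, p = shape_test(shape.scores[sel], group, design)
                    rows.append((node_id, level, contrast.name, "shape", r, p))
                except NotComputableError:
                    n_skipped += 1
            else:
                n_skipped += 1
    frame = pd.DataFrame(
        rows, columns=["segment_id", "level", "contrast", "feature", "statistic", "p"]
    )
    if pooled_fdr:
        threshold, flags = fdr_dep(frame["p"].to_numpy(), alpha)
        frame["significant"] = flags
    else:
        frame["significant"] = False
        threshold = 0.0
        for name, idx in frame.groupby("contrast").groups.items():
            thr, flags = fdr_dep(frame.loc[idx, "p"].to_numpy(), alpha)
            frame.loc[idx, "significant"] = flags
    with np.errstate(divide="ignore"):
        frame["neg_log10_p"] = -np.log10(frame["p"].to_numpy())
    frame = frame[
        ["segment_id", "level", "contrast", "feature", "statistic", "p", "neg_log10_p", "significant"]
    ]
    return ContrastResults(
        frame=frame,
        alpha=alpha,
        fdr_threshold=threshold,
        family_size=len(frame),
        n_not_computable=n_skipped,
    )
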