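"""Background selection and the chromatin landscape model.

Given a query gene set, a background set is sampled from the non-query genes
stratified by a per-gene promoter-activity covariate, so the background has
the same activity profile as the gene universe.  An L1-penalized logistic
regression on normalized chrom-RPs then picks a small panel of informative
chromatin profiles (the penalty found by binary search to cap the panel
size), and an unpenalized refit yields per-profile coefficients alpha_j.
The weighted sum of chrom-RPs is the model-RP; its query-vs-background ROC
AUC measures how well the landscape model discriminates the gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

DEFAULT_BACKGROUND_SIZE = 3000
DEFAULT_BINS = 10
DEFAULT_MAX_PROFILES = 10


@dataclass(frozen=True)
class GeneSetPair:
    """Disjoint query / background gene-id sets and the sampling seed."""

    query: Tuple[str, ...]
    background: Tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.query) & set(self.background):
            raise ValueError("query and background overlap")

    @property
    def all_genes(self) -> Tuple[str, ...]:
        return self.query + self.background

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.query)), np.zeros(len(self.background))]
        ).astype(int)


def select_background(
    query: Set[str],
    universe: Sequence[str],
    covariates: pd.Series,
    n: int = DEFAULT_BACKGROUND_SIZE,
    bins: int = DEFAULT_BINS,
    seed: int = 0,
) -> GeneSetPair:
    """Sample an activity-matched background from the non-query genes.

    The universe is cut into covariate quantile bins; the background is drawn
    without replacement so that each bin contributes in proportion to its
    share of the universe (largest-remainder rounding, deficits refilled from
    the remaining pool).  Deterministic given the seed.
    """
    universe = list(dict.fromkeys(universe))
    query = set(query)
    missing = query - set(universe)
    if missing:
        raise ValueError(f"query genes not in universe: {sorted(missing)[:5]} ...")
    non_query = [g for g in universe if g not in query]
    if not non_query:
        raise ValueError("no non-query genes available for background")
    cov = covariates.reindex(universe)
    if cov.isna().any():
        raise ValueError("covariates missing for some universe genes")
    rng = np.random.default_rng(seed)
    if len(non_query) <= n:
        if len(non_query) < n:
            warnings.warn(
                f"only {len(non_query)} non-query genes available; "
                f"using all as background (requested {n})"
            )
        return GeneSetPair(tuple(sorted(query)), tuple(sorted(non_query)), seed)

    # quantile bins over the full universe (ranks break ties deterministically)
    ranks = rankdata(cov.to_numpy(), method="ordinal")
    bin_of = np.minimum((ranks - 1) * bins // len(universe), bins - 1)
    bin_index = pd.Series(bin_of, index=universe)

    # largest-remainder allocation proportional to universe bin sizes
    sizes = np.array([(bin_index == b).sum() for b in range(bins)], dtype=float)
    exact = n * sizes / sizes.sum()
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:remainder]] += 1

    chosen: List[str] = []
    deficit = 0
    leftover_pool: List[str] = []
    for b in range(bins):
        members = sorted(g for g in non_query if bin_index[g] == b)
        take = min(counts[b], len(members))
        deficit += counts[b] - take
        picked = rng.choice(len(members), size=take, replace=False)
        picked_set = {members[i] for i in picked}
        chosen.extend(sorted(picked_set))
        leftover_pool.extend(sorted(set(members) - picked_set))
    if deficit:
        extra = rng.choice(len(leftover_pool), size=deficit, replace=False)
        chosen.extend(sorted(leftover_pool[i] for i in extra))
    return GeneSetPair(tuple(sorted(query)), tuple(sorted(chosen)), seed)


@dataclass
class ChromModel:
    """Selected chromatin profiles and their logistic coefficients.

    ``alpha`` is on the raw normalized-RP scale (standardization used during
    fitting is folded back in), so model-RP = sum_j alpha_j R'_jk + intercept
    and in silico deletion can reuse the same coefficients directly.
    """

    assay_kind: str
    selected_profiles: List[str]
    alpha: np.ndarray
    intercept: float
    penalty: float
    auc: float = np.nan

    def model_rp(self, normalized_rp: pd.DataFrame) -> np.ndarray:
        """Per-gene model-RP from a genes x profiles normalized-RP frame."""
        X = normalized_rp[self.selected_profiles].to_numpy()
        return X @ self.alpha + self.intercept

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "profile_id": self.selected_profiles,
                "assay_kind": self.assay_kind,
                "alpha": self.alpha,
                "auc": self.auc,
            }
        )


class NoInformativeProfilesError(RuntimeError):
    """No L1 penalty yields any nonzero profile coefficient."""


def _l1_nonzero(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-6,
        random_state=0,
    )
    model.fit(X, y)
    return np.nonzero(np.abs(model.coef_[0]) > 1e-8)[0]


def fit_l1_path(
    X: np.ndarray,
    y: np.ndarray,
    max_profiles: int = DEFAULT_MAX_PROFILES,
    max_iter: int = 50,
) -> Tuple[float, np.ndarray]:
    """Binary-search the L1 penalty so 1 <= #selected <= max_profiles.

    Returns ``(penalty, selected_column_indices)`` where penalty = 1/C is the
    weakest penalty found whose nonzero-coefficient count stays within the
    cap; ties resolve toward fewer profiles (the constrained interval
    endpoint).  Features are standardized internally so the penalty acts
    comparably across profiles.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("need at least one candidate profile")
    if len(np.unique(y)) < 2:
        raise ValueError("both gene classes must be non-empty")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd

    evals = 0

    def count_at(C: float) -> np.ndarray:
        nonlocal evals
        evals += 1
        return _l1_nonzero(Z, y, C)

    # expand bounds: find C_hi with count > cap (or give up at 1e6) and
    # C_lo with count <= cap
    c_lo, c_hi = 1e-4, 1.0
    sel_hi = count_at(c_hi)
    while sel_hi.size <= max_profiles and c_hi < 1e6 and evals < max_iter:
        c_hi *= 10.0
        sel_hi = count_at(c_hi)
    if sel_hi.size == 0:
        raise NoInformativeProfilesError(
            "no informative profiles: L1 selects nothing even at weak penalty"
        )
    if sel_hi.size <= max_profiles:
        return 1.0 / c_hi, sel_hi

    sel_lo = count_at(c_lo)
    while sel_lo.size > max_profiles and c_lo > 1e-8 and evals < max_iter:
        c_lo /= 10.0
        sel_lo = count_at(c_lo)

    best_c, best_sel = None, None
    if 1 <= sel_lo.size <= max_profiles:
        best_c, best_sel = c_lo, sel_lo
    while evals < max_iter and c_hi / c_lo > 1.01:
        c_mid = float(np.sqrt(c_lo * c_hi))
        sel = count_at(c_mid)
        if sel.size <= max_profiles:
            c_lo, sel_lo = c_mid, sel
            if sel.size >= 1 and (best_c is None or c_mid > best_c):
                best_c, best_sel = c_mid, sel
        else:
            c_hi = c_mid
    if best_sel is None or best_sel.size == 0:
        raise NoInformativeProfilesError(
            "no informative profiles: no penalty yields a nonzero coefficient"
        )
    return 1.0 / best_c, best_sel


def fit_final_model(
    X: np.ndarray,
    y: np.ndarray,
    profile_ids: Sequence[str],
    assay_kind: str = "dnase",
    penalty: float = np.nan,
    ridge: float = 1e-6,
    max_iter: int = 2000,
) -> ChromModel:
    """Refit the selected profiles with a near-unpenalized logistic model.

    A very weak ridge (default 1e-6) stabilizes separable fits.  Returned
    coefficients are mapped back to the unstandardized normalized-RP scale.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != len(profile_ids) or X.shape[1] == 0:
        raise ValueError("X columns must match the selected profiles")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    model = LogisticRegression(
        C=1.0 / ridge, solver="lbfgs", max_iter=max_iter, tol=1e-8
    )
    model.fit(Z, y)
    if model.n_iter_[0] >= max_iter:
        raise RuntimeError(
            f"final logistic fit did not converge within {max_iter} iterations"
        )
    coef_std = model.coef_[0]
    alpha = coef_std / sd
    intercept = float(model.intercept_[0] - np.sum(coef_std * mean / sd))
    return ChromModel(
        assay_kind=assay_kind,
        selected_profiles=list(profile_ids),
        alpha=alpha,
        intercept=intercept,
        penalty=penalty,
    )


def model_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) ROC AUC of query (label 1) vs background.

    Tied scores contribute 1/2, via average ranks.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(scores, method="average")
    u = float(np.sum(ranks[labels == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)
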