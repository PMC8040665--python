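"""Per-cohort multiple regression with permutation p-values and q-value FDR.

Each standard-score-normalized immune feature Y_j is regressed on subject
covariates,

    Y_ij = b_j0 + b_jAge Age_i + b_jSex Sex_i + b_jCMV CMV_i
            + b_jHIV HIV_i + b_jHCV HCV_i + e_ij,

fit separately within each cohort; covariates constant within a cohort are
dropped there.  Significance of each coefficient is assessed by permuting
the covariate-of-interest column across subjects (holding the response and
the other covariates fixed), refitting the full model, and counting how
often the permuted |beta| reaches the observed |beta|.  A Freedman-Lane
residual-permutation scheme is available behind ``scheme="freedman-lane"``.
q-values (Storey) convert the permutation p-values into an FDR-controlled
feature selection at the configured threshold (default FDR < 0.2).

The permuted-coefficient computation uses the Frisch-Waugh-Lovell identity:
the full-model coefficient of column x equals (Mx)'y / (Mx)'(Mx) where M
projects out the remaining columns, so each permutation costs one
projection instead of one decomposition.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .datasets import COVARIATES, CohortDataset
from .qvalue import qvalues

__all__ = [
    "ols_fit",
    "permutation_pvalues",
    "PermutationRegression",
    "RegressionResults",
]

_EPS = 1e-12


def ols_fit(y: np.ndarray, X: np.ndarray, names: list[str] | None = None):
    """Ordinary least squares via the normal equations.

    Returns ``(betas, residuals)``.  Constant columns (other than a single
    intercept) must be removed by the caller; a rank-deficient design
    raises with the names of the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        names = names or [f"x{k}" for k in range(p)]
        # columns whose removal restores full rank are the collinear ones
        bad = [
            names[k]
            for k in range(p)
            if np.linalg.matrix_rank(np.delete(X, k, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    betas, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ betas
    return betas, resid


def _encode_design(subjects: pd.DataFrame, standardize_age: bool = True):
    """Numeric covariate columns for one cohort's subjects.

    Sex is encoded F=0 / M=1.  Age is standardized within the cohort by
    default so its coefficient is on the same per-SD scale as the
    normalized response.  Covariates constant within the cohort are
    dropped (returned in ``absent``).
    """
    cols = {}
    age = subjects["age"].to_numpy(dtype=float)
    if standardize_age and np.std(age, ddof=1) > 0:
        age = (age - age.mean()) / age.std(ddof=1)
    cols["age"] = age
    cols["sex"] = (subjects["sex"].to_numpy() == "M").astype(float)
    for c in ("cmv", "hiv", "hcv"):
        cols[c] = subjects[c].to_numpy(dtype=float)
    present, absent = {}, []
    for name, v in cols.items():
        if np.ptp(v) <= _EPS:
            absent.append(name)
        else:
            present[name] = v
    X = np.column_stack([np.ones(len(subjects))] + list(present.values()))
    names = ["intercept"] + list(present.keys())
    return X, names, absent


def _perm_betas_covariate(X, names, Y, covariate, n_perm, seed, cohort,
                          feature_ids, scheme="covariate"):
    """|beta| of the permuted refits, features x permutations.

    The permutation stream is derived per (seed, cohort, covariate,
    feature), so results are independent of feature order and count.
    """
    k = names.index(covariate)
    x = X[:, k]
    Xr = np.delete(X, k, axis=1)
    pinv_r = np.linalg.pinv(Xr)
    n, m = Y.shape[0], Y.shape[1]
    out = np.empty((m, n_perm))
    My = Y - Xr @ (pinv_r @ Y) if scheme == "freedman-lane" else Y
    if scheme == "freedman-lane":
        Zx = x - Xr @ (pinv_r @ x)
        denom_fl = max(float(Zx @ Zx), _EPS)
    for j in range(m):
        rng = derive_rng(seed, "perm", cohort, covariate, feature_ids[j])
        if scheme == "freedman-lane":
            # permute the reduced-model residuals of y instead of x
            ry = My[:, j]
            Py = rng.permuted(np.broadcast_to(ry, (n_perm, n)), axis=1).T
            out[j] = np.abs(Zx @ Py) / denom_fl
        else:
            P = rng.permuted(np.broadcast_to(x, (n_perm, n)), axis=1).T  # n x B
            Z = P - Xr @ (pinv_r @ P)
            denom = np.einsum("ib,ib->b", Z, Z)
            num = Z.T @ Y[:, j]
            out[j] = np.abs(num) / np.maximum(denom, _EPS)
    return out


def _complete_case_perm(
    X, names, y, covariate, n_perm, seed, cohort, feature_id, scheme="covariate"
):
    """Observed beta and permuted |beta| for one feature with missingness.

    Subjects missing the feature are dropped for this feature only; the
    design is re-projected on the remaining rows.
    """
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"feature {feature_id!r}: too few complete cases ({len(y)})"
        )
    perm = _perm_betas_covariate(
        X, names, y[:, None], covariate, n_perm, seed, cohort,
        [feature_id], scheme=scheme,
    )[0]
    k = names.index(covariate)
    betas, *_ = np.linalg.lstsq(X, y, rcond=None)
    return betas[k], perm


def permutation_pvalues(
    dataset: CohortDataset,
    driver_covariate: str,
    n_perm: int = 1000,
    seed: int = 0,
    cohort: str | None = None,
    scheme: str = "covariate",
) -> pd.DataFrame:
    """Permutation p-values for one covariate within one cohort.

    Convenience wrapper around :class:`PermutationRegression` for a single
    driver; returns the result frame restricted to that covariate.
    """
    model = PermutationRegression(
        dataset, cohorts=[cohort] if cohort else None, scheme=scheme
    )
    res = model.fit(n_perm=n_perm, seed=seed)
    frame = res.frame
    return frame[frame["covariate"] == driver_covariate].reset_index(drop=True)


@dataclasses.dataclass
class RegressionResults:
    """Fitted coefficients, permutation p-values, q-values and calls.

    ``frame`` has one row per (cohort, feature, covariate) with columns
    beta, perm_p, perm_p_smoothed, n_perm, q, significant.
    """

    frame: pd.DataFrame
    fdr_threshold: float
    n_perm: int
    excluded: list

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]].reset_index(drop=True)

    def significant_features(self, cohort: str, covariate: str) -> list[str]:
        f = self.frame
        sel = f[
            (f["cohort"] == cohort)
            & (f["covariate"] == covariate)
            & f["significant"]
        ]
        return sel["feature_id"].tolist()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def summary(self) -> str:
        lines = [
            "Permutation regression results",
            f"  permutations per coefficient: {self.n_perm}",
            f"  FDR threshold (q):            {self.fdr_threshold}",
            f"  features excluded:            {len(self.excluded)}",
            "",
            "  significant features per cohort x covariate (q < "
            f"{self.fdr_threshold}):",
        ]
        counts = (
            self.frame[self.frame["significant"]]
            .groupby(["cohort", "covariate"])
            .size()
        )
        for (cohort, cov), n in counts.items():
            lines.append(f"    {cohort:>6} / {cov:<5} : {n}")
        if counts.empty:
            lines.append("    (none)")
        return "\n".join(lines)


class PermutationRegression:
    """Per-cohort OLS with permutation inference over immune features.

    Parameters
    ----------
    dataset
        A :class:`CohortDataset`; normalized in place (standard score
        within cohort) if not already.
    covariates
        Candidate model terms; those constant within a cohort are dropped
        for that cohort.
    cohorts
        Cohorts to fit; defaults to all present.
    scheme
        ``"covariate"`` permutes the covariate-of-interest column;
        ``"freedman-lane"`` permutes reduced-model residuals.
    smooth_p
        When True the reported ``perm_p`` uses add-one smoothing
        (b+1)/(B+1); the plain ratio b/B is the default.  Both are always
        available as columns.
    """

    def __init__(
        self,
        dataset: CohortDataset,
        covariates: list[str] | None = None,
        cohorts: list[str] | None = None,
        scheme: str = "covariate",
        smooth_p: bool = False,
        standardize_age: bool = True,
    ):
        if scheme not in ("covariate", "freedman-lane"):
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        if not dataset.normalized:
            from .datasets import znormalize_within_cohort

            dataset = znormalize_within_cohort(dataset)
        self.dataset = dataset
        self.covariates = list(covariates or COVARIATES)
        self.cohorts = list(cohorts or dataset.cohorts)
        self.scheme = scheme
        self.smooth_p = smooth_p
        self.standardize_age = standardize_age

    def fit(
        self,
        n_perm: int = 1000,
        seed: int = 0,
        fdr_threshold: float = 0.2,
    ) -> RegressionResults:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        ds = self.dataset
        excluded = set(ds.excluded)
        keep = ~ds.features["feature_id"].isin(excluded)
        feature_ids = ds.features.loc[keep, "feature_id"].to_numpy()
        rows = []
        for cohort in self.cohorts:
            mask = (ds.subjects["cohort"] == cohort).to_numpy()
            subj = ds.subjects[mask]
            Y = ds.measurements.loc[mask, feature_ids].to_numpy(dtype=float)
            X, names, absent = _encode_design(subj, self.standardize_age)
            use = [c for c in self.covariates if c in names]
            complete = ~np.isnan(Y).any(axis=0)
            # incomplete features get complete-case refits further down
            Yc = np.where(np.isnan(Y), 0.0, Y)
            betas, *_ = np.linalg.lstsq(X, Yc, rcond=None)
            for covariate in use:
                k = names.index(covariate)
                b_obs = betas[k].copy()
                perm_abs = _perm_betas_covariate(
                    X, names, Yc, covariate, n_perm, seed, cohort,
                    feature_ids, scheme=self.scheme,
                )
                # features with missing entries: pairwise complete-case refit
                for j in np.flatnonzero(~complete):
                    ok = ~np.isnan(Y[:, j])
                    b_obs[j], perm_abs[j] = _complete_case_perm(
                        X[ok], names, Y[ok, j], covariate, n_perm,
                        seed, cohort, feature_ids[j], scheme=self.scheme,
                    )
                exceed = (perm_abs >= np.abs(b_obs)[:, None] - _EPS).sum(axis=1)
                p_ratio = exceed / n_perm
                p_smooth = (exceed + 1) / (n_perm + 1)
                p_used = p_smooth if self.smooth_p else p_ratio
                q, sig = _q_and_call(p_used, fdr_threshold)
                for j, fid in enumerate(feature_ids):
                    rows.append(
                        (
                            cohort,
                            fid,
                            covariate,
                            b_obs[j],
                            p_ratio[j],
                            p_smooth[j],
                            n_perm,
                            q[j],
                            bool(sig[j]),
                        )
                    )
        frame = pd.DataFrame(
            rows,
            columns=[
                "cohort",
                "feature_id",
                "covariate",
                "beta",
                "perm_p",
                "perm_p_smoothed",
                "n_perm",
                "q",
                "significant",
            ],
        )
        return RegressionResults(frame, fdr_threshold, n_perm, sorted(excluded))


def _q_and_call(pvals: np.ndarray, fdr_threshold: float):
    q = qvalues(pvals)
    return q, q < fdr_threshold
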