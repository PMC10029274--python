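"""Group-level analyses of DAR-type distributions.

Covers the annual-cycle quadrimester mapping, start-location k-means,
group-by-cluster contingency comparisons, per-individual temporal
sequences, and the mixed-effects model of DAR size
(sqrt(size) ~ sex + age, random intercepts for individual and date).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .errors import DataError


# ---------------------------------------------------------------------------
# quadrimesters
# ---------------------------------------------------------------------------

def assign_quadrimester(d: date) -> tuple[int, int]:
    """Map a date to (quadrimester, cycle year) of the annual cycle:
    Feb-May -> 1 (breeding), Jun-Sep -> 2 (rearing), Oct-Jan -> 3
    (fall-winter recovery), with January attached to the cycle that began
    the previous October."""
    if 2 <= d.month <= 5:
        return 1, d.year
    if 6 <= d.month <= 9:
        return 2, d.year
    return (3, d.year - 1) if d.month == 1 else (3, d.year)


# ---------------------------------------------------------------------------
# start-location clustering
# ---------------------------------------------------------------------------

class StartLocationKMeans(BaseEstimator):
    """k-means on DAR start points (x, y), with the inertia-vs-k curve
    returned so the caller can apply the elbow heuristic visually.

    Deterministic: fixed seed, ``n_restarts`` restarts.
    """

    def __init__(self, n_clusters: int = 3, k_max: int = 8,
                 n_restarts: int = 25, random_state: int = 0):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if len(X) < self.n_clusters:
            raise DataError(
                f"need >= {self.n_clusters} start points, got {len(X)}")
        km = KMeans(self.n_clusters, n_init=self.n_restarts,
                    random_state=self.random_state).fit(X)
        self.labels_ = km.labels_ + 1
        self.cluster_centers_ = km.cluster_centers_
        self.wss_ = {}
        for k in range(1, min(self.k_max, len(X)) + 1):
            self.wss_[k] = float(KMeans(k, n_init=self.n_restarts,
                                        random_state=self.random_state
                                        ).fit(X).inertia_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_start_locations(start_points: np.ndarray, k: int = 3,
                            k_max: int = 8, n_restarts: int = 25,
                            random_state: int = 0
                            ) -> tuple[np.ndarray, dict[int, float]]:
    est = StartLocationKMeans(k, k_max, n_restarts, random_state).fit(start_points)
    return est.labels_, est.wss_


# ---------------------------------------------------------------------------
# cohort records
# ---------------------------------------------------------------------------

def age_at_date(age_at_assignment: str, birth_date: date | None, when: date) -> str:
    """Young (<= 1 year) vs adult at a given date; falls back to the
    assignment age class when the birth date is unknown."""
    if birth_date is None:
        return age_at_assignment
    return "young" if when <= birth_date + timedelta(days=365) else "adult"


def build_cohort(metrics: pd.DataFrame, labels: np.ndarray | pd.Series,
                 dar_ids: list[str], meta: pd.DataFrame,
                 start_points: pd.DataFrame | None = None,
                 location_labels: np.ndarray | None = None) -> pd.DataFrame:
    """Join cluster labels, metadata, quadrimesters and (optionally)
    start-location clusters into one record per clustered DAR.

    ``meta`` needs columns individual_id, sex, age_class and optionally
    birth_or_assignment_date. Cluster-distribution analyses use the
    assignment age; the mixed model uses ``age_at_dar``.
    """
    lab = pd.DataFrame({"dar_id": dar_ids, "cluster": np.asarray(labels)})
    df = metrics.merge(lab, on="dar_id", how="inner")
    df = df.merge(meta[["individual_id", "sex", "age_class"]
                       + (["birth_or_assignment_date"]
                          if "birth_or_assignment_date" in meta.columns else [])],
                  on="individual_id", how="left")
    if df["sex"].isna().any():
        missing = df.loc[df["sex"].isna(), "individual_id"].unique()
        raise DataError(f"no metadata for individuals: {list(missing)}")
    nd = pd.to_datetime(df["night_date"]).dt.date
    quads = nd.map(assign_quadrimester)
    df["quadrimester"] = [q for q, _ in quads]
    df["cycle_year"] = [y for _, y in quads]
    birth = df.get("birth_or_assignment_date")
    if birth is not None:
        bd = pd.to_datetime(birth, errors="coerce")
        df["age_at_dar"] = [
            age_at_date(a, None if pd.isna(b) else b.date(), d)
            for a, b, d in zip(df["age_class"], bd, nd)]
    else:
        df["age_at_dar"] = df["age_class"]
    df["night_date"] = nd
    if location_labels is not None:
        df["start_location_cluster"] = np.asarray(location_labels)
    elif start_points is not None:
        pts = start_points[["start_x", "start_y"]].to_numpy(dtype=float)
        df["start_location_cluster"] = StartLocationKMeans().fit_predict(pts)
    return df


# ---------------------------------------------------------------------------
# distributions & contingency tests
# ---------------------------------------------------------------------------

GROUPINGS = {"sex": "sex", "age": "age_class", "location": "start_location_cluster",
             "quadrimester": "quadrimester", "individual": "individual_id"}


@dataclass
class DistributionTable:
    counts: pd.DataFrame             # group x cluster counts
    frequencies: pd.DataFrame        # row-normalized
    per_individual_mean: pd.DataFrame
    per_individual_sd: pd.DataFrame


def distribution_table(records: pd.DataFrame, grouping: str) -> DistributionTable:
    """Group-by-cluster counts and frequencies, plus the mean +/- SD of
    per-individual frequencies within each group."""
    if len(records) == 0:
        raise DataError("no cohort records")
    if grouping not in GROUPINGS:
        raise DataError(f"unknown grouping {grouping!r}; one of {sorted(GROUPINGS)}")
    col = GROUPINGS[grouping]
    if col not in records.columns:
        raise DataError(f"records lack column {col!r} for grouping {grouping!r}")
    counts = pd.crosstab(records[col], records["cluster"])
    freqs = counts.div(counts.sum(axis=1), axis=0)
    per_ind = pd.crosstab(records["individual_id"], records["cluster"])
    per_ind = per_ind.div(per_ind.sum(axis=1), axis=0)
    ind_group = records.groupby("individual_id")[col].first()
    per_ind = per_ind.join(ind_group)
    mean = per_ind.groupby(col).mean()
    sd = per_ind.groupby(col).std(ddof=1)
    return DistributionTable(counts, freqs, mean, sd)


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    statistic: float
    dof: int
    p_value: float
    expected: np.ndarray
    low_expected_warning: bool


def chi_squared_test(table: pd.DataFrame | np.ndarray) -> ContingencyResult:
    """Pearson chi-squared contingency test without continuity correction;
    flags tables where any expected count is below 5."""
    obs = pd.DataFrame(table)
    arr = obs.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DataError("contingency table needs >= 2 rows and columns")
    if (arr < 0).any():
        raise DataError("negative counts in contingency table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DataError("zero marginal in contingency table")
    res = stats.chi2_contingency(arr, correction=False)
    return ContingencyResult(obs, float(res.statistic), int(res.dof),
                             float(res.pvalue), res.expected_freq,
                             bool((res.expected_freq < 5).any()))


def temporal_sequence(records: pd.DataFrame, individual_id: str,
                      na_dates: list[date] | None = None) -> pd.DataFrame:
    """Calendar-ordered DAR-type sequence for one individual with explicit
    NA gaps for missing/incomplete nights and quadrimester annotation."""
    sub = records[records["individual_id"] == individual_id]
    if len(sub) == 0:
        raise DataError(f"unknown individual {individual_id!r}")
    have = {d: c for d, c in zip(sub["night_date"], sub["cluster"])}
    na = set(na_dates or [])
    days = sorted(set(have) | na)
    full = [days[0] + timedelta(days=i)
            for i in range((days[-1] - days[0]).days + 1)]
    rows = []
    for d in full:
        q, y = assign_quadrimester(d)
        rows.append({
            "night_date": d,
            "cluster": have.get(d, pd.NA),
            "is_gap": d not in have,
            "quadrimester": q,
            "cycle_year": y,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed-effects size model
# ---------------------------------------------------------------------------

@dataclass
class SizeModelFit:
    """Fitted linear mixed model of sqrt-transformed DAR size."""
    fixed_effects: pd.DataFrame      # index: term; estimate, se, pvalue, ci lo/hi
    random_variances: dict
    aic: float
    bic: float
    loglike: float
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    converged: bool
    formula: str
    aic_no_interaction: float | None = None


def _check_model_frame(records: pd.DataFrame, size_col: str) -> pd.DataFrame:
    df = records.copy()
    for col in (size_col, "sex", "age_at_dar", "individual_id"):
        if col not in df.columns:
            raise DataError(f"size model needs column {col!r}")
    if (df[size_col] < 0).any():
        raise DataError("negative size values; square root undefined")
    for col in ("sex", "age_at_dar"):
        if df[col].nunique() < 2:
            raise DataError(f"fixed factor {col!r} needs >= 2 levels")
    return df


def fit_size_model(records: pd.DataFrame, size_col: str = "composite_size",
                   include_interaction: bool = False,
                   include_date_effect: bool = True,
                   reml: bool = True) -> SizeModelFit:
    """Linear mixed model of sqrt(size) on sex and age with random
    intercepts for individual (always) and calendar date (optional,
    variance component on a single grouping).

    With ``include_interaction`` the sex x age cross-product is added and
    the information criterion (ML AIC) of the additive model is attached
    for the comparison; the interaction model fit itself is reported.
    Non-convergence raises :class:`DataError`.
    """
    df = _check_model_frame(records, size_col)
    df = df.assign(
        sqrt_size=np.sqrt(df[size_col].to_numpy(dtype=float)),
        is_male=(df["sex"] == "male").astype(float),
        is_young=(df["age_at_dar"] == "young").astype(float),
    )
    terms = ["is_male", "is_young"]
    if include_interaction:
        df["male_x_young"] = df["is_male"] * df["is_young"]
        terms.append("male_x_young")
    formula = "sqrt_size ~ " + " + ".join(terms)

    def _fit(fterms: list[str], use_reml: bool):
        f = "sqrt_size ~ " + " + ".join(fterms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if include_date_effect:
                # crossed random intercepts via variance components on a
                # single all-encompassing group
                data = df.assign(_one=1)
                model = sm.MixedLM.from_formula(
                    f, data, groups="_one", re_formula="0",
                    vc_formula={"individual": "0 + C(individual_id)",
                                "date": "0 + C(night_date)"})
            else:
                model = sm.MixedLM.from_formula(f, df, groups=df["individual_id"])
            result = None
            for method in ("bfgs", "lbfgs", "powell", "cg"):
                result = model.fit(reml=use_reml, method=method)
                if result.converged:
                    break
            return model, result

    model, result = _fit(terms, reml)
    if not result.converged:
        raise DataError("mixed model did not converge under any optimizer; "
                        f"parameter norm {np.linalg.norm(result.params):.3g}")

    names = list(result.fe_params.index)
    ci = result.conf_int().loc[names]
    fe = pd.DataFrame({
        "estimate": result.fe_params,
        "se": result.bse.loc[names],
        "pvalue": result.pvalues.loc[names],
        "ci_lo": ci[0],
        "ci_hi": ci[1],
    })
    if include_date_effect:
        rv = {name: float(v)
              for name, v in zip(model.exog_vc.names, result.vcomp)}
    else:
        rv = {"individual": float(result.cov_re.iloc[0, 0])}
    rv["residual"] = float(result.scale)

    # marginal (population-level) residuals: robust to singular random-effect
    # covariances and normally distributed under the model either way
    fitted_marginal = np.asarray(model.exog @ result.fe_params)
    resid_marginal = np.asarray(model.endog) - fitted_marginal

    aic_no_inter = None
    if include_interaction:
        aic_no_inter = float(_fit(["is_male", "is_young"], False)[1].aic)
    if reml or include_interaction:
        result_ml = _fit(terms, False)[1]
        aic, bic = float(result_ml.aic), float(result_ml.bic)
    else:
        aic, bic = float(result.aic), float(result.bic)

    return SizeModelFit(
        fixed_effects=fe, random_variances=rv,
        aic=aic, bic=bic, loglike=float(result.llf),
        residuals=resid_marginal,
        fitted=fitted_marginal,
        n=len(df), converged=bool(result.converged), formula=formula,
        aic_no_interaction=aic_no_inter)


class SizeMixedModel(BaseEstimator):
    """sklearn-style wrapper around :func:`fit_size_model`.

    ``fit(records)`` expects a cohort DataFrame; fitted attributes mirror
    :class:`SizeModelFit` (``fixed_effects_``, ``random_variances_``,
    ``aic_`` ...).
    """

    def __init__(self, size_col: str = "composite_size",
                 include_interaction: bool = False,
                 include_date_effect: bool = True, reml: bool = True):
        self.size_col = size_col
        self.include_interaction = include_interaction
        self.include_date_effect = include_date_effect
        self.reml = reml

    def fit(self, X: pd.DataFrame, y=None):
        res = fit_size_model(X, self.size_col, self.include_interaction,
                             self.include_date_effect, self.reml)
        self.result_ = res
        self.fixed_effects_ = res.fixed_effects
        self.random_variances_ = res.random_variances
        self.aic_ = res.aic
        self.residuals_ = res.residuals
        self.fitted_ = res.fitted
        return self


@dataclass
class ModelDiagnostics:
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    qq_correlation: float
    residual_mean: float
    residual_sd: float
    quintile_sds: pd.Series


def model_diagnostics(fit: SizeModelFit, bins: int = 30) -> ModelDiagnostics:
    """Residual summaries for normality / homoscedasticity checks:
    histogram data, theoretical-vs-sample quantile pairs, and residual SD
    by fitted-value quintile."""
    r = np.asarray(fit.residuals, dtype=float)
    counts, edges = np.histogram(r, bins=bins)
    (theo, sample), _ = stats.probplot(r, dist="norm")
    qq_corr = float(np.corrcoef(theo, sample)[0, 1])
    quint = pd.qcut(fit.fitted, 5, labels=False, duplicates="drop")
    quintile_sds = pd.Series(r).groupby(quint).std(ddof=1)
    return ModelDiagnostics(counts, edges, theo, sample, qq_corr,
                            float(r.mean()), float(r.std(ddof=1)), quintile_sds)
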