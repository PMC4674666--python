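"""Statistical stage of the egg-rejection experiment.

Implements the analysis applied to the nest-outcome table:

* per-group desertion and ejection rates;
* Fisher's exact test for a 2x2 table, with both full enumeration and a
  Monte-Carlo p-value, a conditional-MLE odds ratio, and an exact CI;
* a binomial GLM (logit link) for the eject/accept response of non-deserted
  parasitized nests;
* a negative-binomial GLM (log link, ML-estimated dispersion) for latency
  to ejection (ejectors only, counts of days, same-day = 0);
* variance inflation factors and backward elimination that always retains
  the treatment term.

Term significance is the likelihood-ratio chi-square from single-term
deletion.  Confidence intervals are Wald intervals with a Bonferroni
family-wise adjustment over the reported terms (the analysis reports
"approximate family-wise" intervals without naming a method; Bonferroni is
the conservative default).  Pseudo-R^2 is Nagelkerke's.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import (
    ConfigurationError,
    DegenerateTableError,
    InvalidInputError,
    SingularDesignError,
)

__all__ = [
    "NestOutcome",
    "TermResult",
    "ModelResult",
    "FisherResult",
    "outcomes_to_frame",
    "frame_to_outcomes",
    "proportion_summary",
    "desertion_table",
    "fisher_exact",
    "fit_response_model",
    "fit_latency_model",
    "backward_eliminate",
    "vif",
]

TREATMENTS = ("control", "constant", "rearranged")
PARASITIZED = ("constant", "rearranged")
RESPONSES = ("eject", "accept", "desert", "unknown")

#: default covariate set of the response/latency models
DEFAULT_TERMS = ("treatment", "nest_age", "laying_date", "clutch_size")


@dataclass
class NestOutcome:
    """Behavioural outcome of one experimental nest.

    ``latency_days`` is days from parasitism to ejection (0 = same day) and
    is only meaningful for ejectors; ``response`` "unknown" marks a nest
    whose post-manipulation fate could not be scored (kept in desertion
    denominators, excluded from ejection denominators).
    """

    nest_id: str
    treatment: str
    response: str
    latency_days: int | None = None
    clutch_size: int | None = None
    nest_age_days: float | None = None
    laying_date: float | None = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise InvalidInputError(f"unknown treatment {self.treatment!r}")
        if self.response not in RESPONSES:
            raise InvalidInputError(f"unknown response {self.response!r}")
        if self.treatment == "control" and self.response == "eject":
            raise InvalidInputError("control nests contain no foreign egg to eject")
        if self.response != "eject" and self.latency_days is not None:
            raise InvalidInputError("latency_days only applies to ejectors")
        if self.latency_days is not None and (
            self.latency_days < 0 or self.latency_days != int(self.latency_days)
        ):
            raise InvalidInputError("latency_days must be a non-negative integer")


_OUTCOME_COLUMNS = [
    "nest_id", "treatment", "response", "latency_days",
    "clutch_size", "nest_age_days", "laying_date",
]


def outcomes_to_frame(outcomes: list[NestOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "nest_id": o.nest_id,
                "treatment": o.treatment,
                "response": o.response,
                "latency_days": o.latency_days,
                "clutch_size": o.clutch_size,
                "nest_age_days": o.nest_age_days,
                "laying_date": o.laying_date,
            }
            for o in outcomes
        ],
        columns=_OUTCOME_COLUMNS,
    )


def frame_to_outcomes(df: pd.DataFrame) -> list[NestOutcome]:
    out = []
    for row in df.itertuples(index=False):
        lat = row.latency_days
        lat = None if lat is None or (isinstance(lat, float) and math.isnan(lat)) else int(lat)
        out.append(
            NestOutcome(
                nest_id=str(row.nest_id),
                treatment=row.treatment,
                response=row.response,
                latency_days=lat,
                clutch_size=None if pd.isna(row.clutch_size) else int(row.clutch_size),
                nest_age_days=None if pd.isna(row.nest_age_days) else float(row.nest_age_days),
                laying_date=None if pd.isna(row.laying_date) else float(row.laying_date),
            )
        )
    return out


def _as_frame(outcomes) -> pd.DataFrame:
    if isinstance(outcomes, pd.DataFrame):
        return outcomes
    return outcomes_to_frame(list(outcomes))


def proportion_summary(outcomes) -> pd.DataFrame:
    """Per-treatment desertion and ejection rates (percentages).

    Desertion uses the full group as denominator; ejection uses only
    non-deserted parasitized nests with a scored eject/accept response.
    Undefined rates (empty denominator, or ejection for controls) are NaN.
    """
    df = _as_frame(outcomes)
    if df.empty:
        raise InvalidInputError("no outcomes supplied")
    rows = []
    for trt, grp in df.groupby("treatment", sort=False):
        n = len(grp)
        n_desert = int((grp.response == "desert").sum())
        n_eject = int((grp.response == "eject").sum())
        n_accept = int((grp.response == "accept").sum())
        scored = n_eject + n_accept
        rows.append(
            {
                "treatment": trt,
                "n": n,
                "n_deserted": n_desert,
                "desertion_pct": 100.0 * n_desert / n if n else np.nan,
                "n_scored": scored,
                "n_ejected": n_eject,
                "ejection_pct": (
                    100.0 * n_eject / scored if scored and trt in PARASITIZED else np.nan
                ),
            }
        )
    order = [t for t in TREATMENTS if t in {r["treatment"] for r in rows}]
    out = pd.DataFrame(rows).set_index("treatment")
    return out.loc[order + [t for t in out.index if t not in order]]


def desertion_table(outcomes) -> np.ndarray:
    """2x2 desertion table: rows = (control, parasitized), cols = (deserted, not)."""
    df = _as_frame(outcomes)
    ctrl = df[df.treatment == "control"]
    par = df[df.treatment.isin(PARASITIZED)]
    return np.array(
        [
            [int((ctrl.response == "desert").sum()), int((ctrl.response != "desert").sum())],
            [int((par.response == "desert").sum()), int((par.response != "desert").sum())],
        ]
    )


# --- Fisher's exact test ------------------------------------------------------


@dataclass(frozen=True)
class FisherResult:
    """Two-sided Fisher exact test of a 2x2 table."""

    table: tuple
    odds_ratio: float  # conditional MLE
    ci_low: float
    ci_high: float
    p_enumeration: float
    p_monte_carlo: float | None
    n_reps: int | None


def _fisher_params(table: np.ndarray) -> tuple[int, int, int, int]:
    a = int(table[0, 0])
    total = int(table.sum())
    n_col1 = int(table[:, 0].sum())
    n_row1 = int(table[0, :].sum())
    return a, total, n_col1, n_row1


def _cond_mean(log_or: float, total: int, n_col1: int, n_row1: int) -> float:
    return float(
        sps.nchypergeom_fisher.mean(total, n_col1, n_row1, math.exp(log_or))
    )


def fisher_exact(
    table,
    n_reps: int | None = 100_000,
    seed=None,
    conf_level: float = 0.95,
) -> FisherResult:
    """Two-sided Fisher exact test with enumeration and Monte-Carlo p-values.

    The enumeration p sums the conditional (hypergeometric) probabilities of
    all tables no more probable than the observed one.  The Monte-Carlo p
    draws ``n_reps`` tables from the conditional null and uses the
    add-one estimator ``(1 + #{p(sim) <= p(obs)}) / (n_reps + 1)``.  The
    odds ratio is the conditional MLE with an exact (central) CI, matching
    the convention of R's ``fisher.test``.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any() or not np.allclose(table, np.round(table)):
        raise InvalidInputError("table must be 2x2 with non-negative integer cells")
    table = table.astype(int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("a margin of the 2x2 table is zero")

    a, total, n_col1, n_row1 = _fisher_params(table)
    lo = max(0, n_row1 + n_col1 - total)
    hi = min(n_row1, n_col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, total, n_col1, n_row1)
    p_obs = pmf[a - lo]
    rel = 1.0 + 1e-7  # R-style relative tolerance for "no more probable"
    p_enum = float(min(1.0, pmf[pmf <= p_obs * rel].sum()))

    p_mc = None
    if n_reps:
        rng = np.random.default_rng(seed)
        draws = rng.hypergeometric(n_col1, total - n_col1, n_row1, size=n_reps)
        p_mc = float((1 + np.sum(pmf[draws - lo] <= p_obs * rel)) / (n_reps + 1))

    # conditional MLE of the odds ratio: solve E_or[X] = a
    if a == lo:
        or_mle = 0.0
    elif a == hi:
        or_mle = math.inf
    else:
        or_mle = math.exp(
            optimize.brentq(lambda lg: _cond_mean(lg, total, n_col1, n_row1) - a, -36, 36)
        )

    alpha = 1.0 - conf_level
    if a == lo:
        ci_low = 0.0
    else:
        ci_low = math.exp(
            optimize.brentq(
                lambda lg: sps.nchypergeom_fisher.sf(
                    a - 1, total, n_col1, n_row1, math.exp(lg)
                )
                - alpha / 2,
                -36,
                36,
            )
        )
    if a == hi:
        ci_high = math.inf
    else:
        ci_high = math.exp(
            optimize.brentq(
                lambda lg: sps.nchypergeom_fisher.cdf(a, total, n_col1, n_row1, math.exp(lg))
                - alpha / 2,
                -36,
                36,
            )
        )

    return FisherResult(
        table=tuple(map(tuple, table)),
        odds_ratio=or_mle,
        ci_low=ci_low,
        ci_high=ci_high,
        p_enumeration=p_enum,
        p_monte_carlo=p_mc,
        n_reps=n_reps,
    )


# --- design matrices and VIF --------------------------------------------------


def build_design(df: pd.DataFrame, terms) -> pd.DataFrame:
    """Design matrix with an intercept; each model term maps to one column.

    ``treatment`` -> indicator of "rearranged" (constant is the reference);
    ``clutch_size`` -> indicator of a 5-egg clutch; continuous covariates
    enter as given.
    """
    cols = {"const": np.ones(len(df))}
    for term in terms:
        if term == "treatment":
            cols["treatment"] = (df.treatment == "rearranged").astype(float).to_numpy()
        elif term == "clutch_size":
            cols["clutch_size"] = (df.clutch_size == 5).astype(float).to_numpy()
        elif term == "nest_age":
            cols["nest_age"] = df.nest_age_days.astype(float).to_numpy()
        elif term in df.columns:
            cols[term] = df[term].astype(float).to_numpy()
        else:
            raise InvalidInputError(f"unknown model term {term!r}")
    return pd.DataFrame(cols, index=df.index)


def vif(design) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j) where R^2_j is
    from regressing predictor j on the other predictors (plus intercept).

    ``design`` may include a column named "const"/"Intercept"; it is used in
    the auxiliary regressions but no VIF is reported for it.
    """
    X = pd.DataFrame(design).astype(float)
    pred_cols = [c for c in X.columns if c not in ("const", "Intercept", "intercept")]
    if len(pred_cols) < 2:
        raise InvalidInputError("VIF needs at least two predictors")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    if "const" not in X.columns:
        X = X.copy()
        X["const"] = 1.0
    out = {}
    for col in pred_cols:
        others = X.drop(columns=[col])
        res = sm.OLS(X[col].to_numpy(), others.to_numpy()).fit()
        r2 = min(res.rsquared, 1 - 1e-12)
        out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out)


# --- GLM fitting --------------------------------------------------------------


@dataclass
class TermResult:
    """One model-term row: estimate, family-wise CI, LR chi-square, VIF."""

    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    chi2: float | None
    df: int
    p: float | None
    vif: float | None


@dataclass
class ModelResult:
    """Fitted GLM summary in the shape of the experiment's model tables."""

    family: str
    link: str
    terms: list[TermResult]
    pseudo_r2: float | None
    n: int
    llf: float | None
    ll_null: float | None
    dispersion_alpha: float | None = None
    separation: bool = False
    notes: list[str] = field(default_factory=list)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    @property
    def term_names(self) -> list[str]:
        return [t.term for t in self.terms if t.term != "(Intercept)"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.term,
                    "estimate": t.estimate,
                    "se": t.se,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "chi2": t.chi2,
                    "df": t.df,
                    "p": t.p,
                    "vif": t.vif,
                }
                for t in self.terms
            ]
        )


def _nagelkerke(llf: float, ll_null: float, n: int) -> float:
    cs = 1.0 - math.exp(2.0 / n * (ll_null - llf))
    max_cs = 1.0 - math.exp(2.0 / n * ll_null)
    return cs / max_cs if max_cs > 0 else float("nan")


def _familywise_z(k: int, alpha: float) -> float:
    return float(sps.norm.ppf(1.0 - alpha / (2.0 * max(k, 1))))


def _binom_fit(y: np.ndarray, X: pd.DataFrame):
    model = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    return res


def _assemble(
    family: str,
    link: str,
    term_names: list[str],
    params: np.ndarray,
    ses: np.ndarray,
    lrs: dict[str, float],
    vifs: pd.Series | None,
    llf: float,
    ll_null: float,
    n: int,
    alpha: float,
    dispersion_alpha: float | None = None,
    separation: bool = False,
    notes: list[str] | None = None,
) -> ModelResult:
    names = ["(Intercept)"] + term_names
    z = _familywise_z(len(names), alpha)
    rows = []
    for i, name in enumerate(names):
        chi2 = lrs.get(name)
        rows.append(
            TermResult(
                term=name,
                estimate=float(params[i]),
                se=float(ses[i]),
                ci_low=float(params[i] - z * ses[i]),
                ci_high=float(params[i] + z * ses[i]),
                chi2=chi2,
                df=1,
                p=None if chi2 is None else float(sps.chi2.sf(chi2, 1)),
                vif=(
                    float(vifs[name])
                    if vifs is not None and name in vifs.index
                    else (1.0 if name != "(Intercept)" else None)
                ),
            )
        )
    return ModelResult(
        family=family,
        link=link,
        terms=rows,
        pseudo_r2=_nagelkerke(llf, ll_null, n) if llf is not None else None,
        n=n,
        llf=llf,
        ll_null=ll_null,
        dispersion_alpha=dispersion_alpha,
        separation=separation,
        notes=notes or [],
    )


def _prune_constant_terms(
    X: pd.DataFrame, terms: list[str]
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Drop terms with no variation in the analysis subset (inestimable)."""
    notes = []
    keep = []
    for t in terms:
        if np.ptp(X[t].to_numpy()) == 0.0:
            notes.append(f"term {t!r} is constant in the analysis subset; dropped")
            X = X.drop(columns=[t])
        else:
            keep.append(t)
    # drop aliased (exactly collinear) terms, later terms first
    cols = ["const"] + keep
    M = X[cols].to_numpy()
    while np.linalg.matrix_rank(M) < M.shape[1] and keep:
        t = keep.pop()
        notes.append(f"term {t!r} is collinear in the analysis subset; dropped")
        X = X.drop(columns=[t])
        cols = ["const"] + keep
        M = X[cols].to_numpy()
    return X, keep, notes


def response_subset(outcomes) -> pd.DataFrame:
    """Non-deserted parasitized nests with a scored eject/accept response."""
    df = _as_frame(outcomes)
    return df[
        df.treatment.isin(PARASITIZED) & df.response.isin(["eject", "accept"])
    ].reset_index(drop=True)


def fit_response_model(outcomes, terms=DEFAULT_TERMS, alpha: float = 0.05) -> ModelResult:
    """Binomial (logit) GLM of ejection vs acceptance on parasitized nests.

    Returns ML estimates with single-term-deletion LR chi-squares, VIFs and
    Nagelkerke pseudo-R^2.  Complete/quasi-complete separation is flagged
    (``separation=True``) and estimates from a lightly L2-penalized fit are
    reported instead, with inference columns set to NaN.
    """
    d = response_subset(outcomes)
    if d.empty:
        raise InvalidInputError("no scored parasitized nests")
    terms = list(terms)
    y = (d.response == "eject").to_numpy(float)
    X = build_design(d, terms)
    X, terms, prune_notes = _prune_constant_terms(X, terms)
    n = len(d)

    try:
        res = _binom_fit(y, X)
        separation = bool(np.max(np.abs(res.params)) > 15)
    except PerfectSeparationError:
        res, separation = None, True

    if separation or res is None or (y == y[0]).all():
        model = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pen = model.fit_regularized(alpha=1e-3, L1_wt=0.0)
        params = np.asarray(pen.params)
        nan = np.full(len(params), np.nan)
        return _assemble(
            "binomial", "logit", terms, params, nan, {}, None, None, None, n, alpha,
            separation=True,
            notes=prune_notes
            + ["perfect separation (or degenerate response); L2-penalized estimates shown"],
        )

    lrs = {}
    for term in terms:
        Xr = X.drop(columns=[term])
        res_r = _binom_fit(y, Xr)
        lrs[term] = float(2.0 * (res.llf - res_r.llf))
    ll_null = float(_binom_fit(y, X[["const"]]).llf)
    vifs = vif(X) if len(terms) >= 2 else None
    return _assemble(
        "binomial", "logit", terms, np.asarray(res.params), np.asarray(res.bse),
        lrs, vifs, float(res.llf), ll_null, n, alpha, notes=prune_notes,
    )


_NB_ALPHA_FLOOR = 1e-6


def _nb_fit(y: np.ndarray, X: pd.DataFrame):
    model = NegativeBinomial(y, X.to_numpy(), loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=500, method="bfgs")
        except Exception:
            res = model.fit(disp=0, maxiter=500, method="nm")
    return res


def fit_latency_model(outcomes, terms=DEFAULT_TERMS, alpha: float = 0.05) -> ModelResult:
    """Negative-binomial (log link) GLM of latency to ejection, ejectors only.

    The NB2 dispersion parameter is estimated by maximum likelihood.  When
    the dispersion collapses to (near) zero or the NB fit fails — e.g. for
    equidispersed or degenerate latencies — the model falls back to a
    Poisson GLM and records a note.
    """
    df = _as_frame(outcomes)
    d = df[df.response == "eject"].reset_index(drop=True)
    if d.empty:
        raise InvalidInputError("no ejectors in the outcome table")
    terms = list(terms)
    y = d.latency_days.to_numpy(float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise InvalidInputError("latencies must be non-negative integers")
    X = build_design(d, terms)
    X, terms, notes = _prune_constant_terms(X, terms)
    n = len(d)

    use_poisson = False
    try:
        res = _nb_fit(y, X)
        disp = float(res.params[-1])
        if not np.isfinite(res.llf) or disp < _NB_ALPHA_FLOOR:
            use_poisson = True
    except Exception:
        use_poisson = True

    if use_poisson:
        notes.append("dispersion at the Poisson limit; refitted as Poisson GLM")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = lambda Xd: sm.GLM(y, Xd.to_numpy(), family=sm.families.Poisson()).fit(maxiter=200)
            res = fit(X)
            params, ses = np.asarray(res.params), np.asarray(res.bse)
            lrs = {t: float(2.0 * (res.llf - fit(X.drop(columns=[t])).llf)) for t in terms}
            ll_null = float(fit(X[["const"]]).llf)
        family, disp = "poisson", None
    else:
        params, ses = np.asarray(res.params[:-1]), np.asarray(res.bse[:-1])
        lrs = {t: float(2.0 * (res.llf - _nb_fit(y, X.drop(columns=[t])).llf)) for t in terms}
        ll_null = float(_nb_fit(y, X[["const"]]).llf)
        family = "negative binomial"

    vifs = vif(X) if len(terms) >= 2 else None
    return _assemble(
        family, "log", terms, params, ses, lrs, vifs,
        float(res.llf), ll_null, n, alpha, dispersion_alpha=disp,
        notes=notes,
    )


def backward_eliminate(
    outcomes,
    fit,
    terms=DEFAULT_TERMS,
    alpha: float = 0.05,
    protected=("treatment",),
) -> tuple[ModelResult, ModelResult]:
    """Backward elimination: repeatedly drop the least significant
    unprotected term with p > alpha, refit, and stop when every remaining
    unprotected term is significant.  ``protected`` terms (the treatment of
    main interest) are never removed.  Returns (full model, final model).

    ``fit`` is a callable ``fit(outcomes, terms) -> ModelResult`` such as
    :func:`fit_response_model` or :func:`fit_latency_model`.
    """
    terms = list(terms)
    protected = set(protected)
    if not protected <= set(terms):
        raise ConfigurationError("protected terms must be part of the model terms")
    full = fit(outcomes, terms)
    current_terms = list(terms)
    current = full
    while True:
        candidates = [t for t in current_terms if t not in protected]
        if not candidates:
            break
        # NaN p-values (separation) and terms pruned as inestimable count
        # as least significant
        def term_p(t):
            try:
                p = current.term(t).p
            except KeyError:
                return 1.2
            return p if p is not None else 1.1

        pvals = {t: term_p(t) for t in candidates}
        worst = max(candidates, key=lambda t: (pvals[t], t))
        if pvals[worst] <= alpha:
            break
        current_terms.remove(worst)
        current = fit(outcomes, current_terms)
    return full, current
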