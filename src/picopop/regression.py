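"""Driver attribution: isolation-by-distance vs isolation-by-environment.

Normalized genomic distances y = FST / (1 - FST) between station pairs are
regressed on up to four explanatory distances,

    y = b0 + b_geo * x_geo + b_env * x_env + b_pc * x_pc + b_mct * x_mct + e,

by ordinary least squares.  The optimal covariate subset is found by
exhaustive search over all 2^4 submodels (the intercept is always included)
minimizing BIC = n*ln(RSS/n) + k*ln(n), with k counting all estimated
coefficients including the intercept.  The selected model is tested against
the intercept-only null with an F test, and individual coefficients with
two-sided t tests at the 0.05 threshold.  Pairs sharing a station are not
independent, so the OLS p-values are anti-conservative; an optional
Mantel-style permutation p-value is provided as a cross-check.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_tables import DistanceMatrix, ValidationError

log = logging.getLogger(__name__)

TERMS = ("geo", "env", "pc", "mct")
ALPHA = 0.05


def normalize_fst(fst: float) -> float:
    """Rousset-style linearization FST / (1 - FST); undefined at FST = 1."""
    if not 0.0 <= fst < 1.0:
        raise ValueError(f"normalize_fst needs FST in [0, 1), got {fst}")
    return fst / (1.0 - fst)


def assemble_pairs(
    genomic: DistanceMatrix,
    geo: DistanceMatrix,
    env: DistanceMatrix,
    pc: DistanceMatrix,
    mct: DistanceMatrix,
) -> pd.DataFrame:
    """One observation per unordered station pair with a defined genomic entry.

    Pairs whose genomic FST is missing (no shared SNP) are excluded, never
    imputed; pairs at FST = 1 have no finite normalized distance and are
    dropped with a warning.  Returns columns station_a, station_b, fst, y,
    x_geo, x_env, x_pc, x_mct.
    """
    layers = {"geo": geo, "env": env, "pc": pc, "mct": mct}
    labels = list(genomic.labels)
    for name, m in layers.items():
        if set(m.labels) != set(labels):
            raise ValidationError(f"station labels of {name!r} matrix differ from genomic matrix")
        layers[name] = m.reorder(labels)
    rows = []
    n_fixed = 0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            f = genomic.values[i, j]
            if np.isnan(f):
                continue
            if f >= 1.0:
                n_fixed += 1
                continue
            rows.append(
                {
                    "station_a": labels[i],
                    "station_b": labels[j],
                    "fst": f,
                    "y": normalize_fst(float(f)),
                    **{f"x_{k}": float(m.values[i, j]) for k, m in layers.items()},
                }
            )
    if n_fixed:
        log.warning("%d pair(s) at FST = 1 dropped (normalized distance undefined)", n_fixed)
    obs = pd.DataFrame(rows)
    if len(obs) and not np.isfinite(obs[[f"x_{t}" for t in TERMS]].to_numpy()).all():
        raise ValidationError("non-finite explanatory distances")
    return obs


@dataclass
class RegressionResult:
    """Outcome of the exhaustive-BIC search.

    ``beta`` includes the intercept under key ``'intercept'``;
    ``overall_f_pvalue`` is the F test of the selected model against the
    intercept-only null (NaN when the null itself was selected);
    ``bic_table`` lists all fitted submodels with their BIC.
    """

    selected_terms: tuple[str, ...]
    beta: dict[str, float]
    t_pvalues: dict[str, float]
    overall_f_pvalue: float
    r2_percent: float
    bic_table: pd.DataFrame
    n_obs: int
    significant_terms: tuple[str, ...] = field(default=())

    @property
    def null_selected(self) -> bool:
        return len(self.selected_terms) == 0


def _bic(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood up to constants; guard exact fits
    return n * np.log(max(rss / n, 1e-300)) + k * np.log(n)


def _fit_subset(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ coef) ** 2).sum())
    return coef, rss


def exhaustive_bic_select(
    obs: pd.DataFrame, *, terms: tuple[str, ...] = TERMS
) -> RegressionResult:
    """Fit all covariate subsets and return the BIC-minimizing model.

    Subsets are enumerated smallest first, so a BIC tie resolves to the more
    parsimonious model.  A rank-deficient design drops the offending
    (collinear) term with a warning before fitting.
    """
    if len(obs) < 6:
        raise ValidationError(f"need at least 6 pair observations, got {len(obs)}")
    y = obs["y"].to_numpy(dtype=float)
    n = len(y)
    cols = {t: obs[f"x_{t}"].to_numpy(dtype=float) for t in terms}

    records = []
    best = None
    for size in range(len(terms) + 1):
        for subset in itertools.combinations(terms, size):
            use = list(subset)
            X = np.column_stack([np.ones(n)] + [cols[t] for t in use])
            rank = np.linalg.matrix_rank(X)
            while rank < X.shape[1] and use:
                dropped = use.pop()  # drop the last (collinear) term
                log.warning("dropping collinear term %r from subset %s", dropped, subset)
                X = np.column_stack([np.ones(n)] + [cols[t] for t in use])
                rank = np.linalg.matrix_rank(X)
            _, rss = _fit_subset(y, X)
            bic = _bic(rss, n, X.shape[1])
            records.append({"terms": "+".join(use) or "(intercept)", "k": X.shape[1], "rss": rss, "bic": bic})
            if best is None or bic < best[0]:
                best = (bic, tuple(use))
    bic_table = pd.DataFrame(records)
    return _final_fit(y, cols, best[1], bic_table)


def _final_fit(
    y: np.ndarray,
    cols: dict[str, np.ndarray],
    selected: tuple[str, ...],
    bic_table: pd.DataFrame,
) -> RegressionResult:
    n = len(y)
    X = np.column_stack([np.ones(n)] + [cols[t] for t in selected])
    names = ["intercept"] + list(selected)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, X).fit()
    beta = dict(zip(names, map(float, res.params)))
    t_p = dict(zip(names, map(float, res.pvalues)))
    if selected:
        overall_p = float(res.f_pvalue)  # F test of all slopes = 0, i.e. vs intercept-only
        r2 = float(res.rsquared) * 100.0
    else:
        overall_p = float("nan")
        r2 = 0.0
        log.info("intercept-only model selected; overall F test unavailable")
    significant = tuple(t for t in selected if t_p[t] < ALPHA)
    return RegressionResult(
        selected_terms=tuple(selected),
        beta=beta,
        t_pvalues=t_p,
        overall_f_pvalue=overall_p,
        r2_percent=r2,
        bic_table=bic_table,
        n_obs=n,
        significant_terms=significant,
    )


def fit_terms(obs: pd.DataFrame, terms: tuple[str, ...]) -> RegressionResult:
    """Fit one fixed covariate set (no model selection)."""
    y = obs["y"].to_numpy(dtype=float)
    cols = {t: obs[f"x_{t}"].to_numpy(dtype=float) for t in terms}
    X = np.column_stack([np.ones(len(y))] + [cols[t] for t in terms])
    _, rss = _fit_subset(y, X)
    bic_table = pd.DataFrame(
        [{"terms": "+".join(terms) or "(intercept)", "k": X.shape[1], "rss": rss, "bic": _bic(rss, len(y), X.shape[1])}]
    )
    return _final_fit(y, cols, tuple(terms), bic_table)


def mantel_permutation_pvalue(
    obs: pd.DataFrame,
    term: str,
    *,
    n_permutations: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for one explanatory distance (cross-check only).

    Station labels are permuted jointly on both axes of the response matrix
    (the Mantel scheme), preserving the dependence among pairs that share a
    station; the statistic is the Pearson correlation between y and the
    chosen distance.
    """
    stations = sorted(set(obs["station_a"]) | set(obs["station_b"]))
    idx = {s: i for i, s in enumerate(stations)}
    n = len(stations)
    Y = np.full((n, n), np.nan)
    X = np.full((n, n), np.nan)
    for _, row in obs.iterrows():
        i, j = idx[row["station_a"]], idx[row["station_b"]]
        Y[i, j] = Y[j, i] = row["y"]
        X[i, j] = X[j, i] = row[f"x_{term}"]
    iu = np.triu_indices(n, k=1)

    def corr(perm: np.ndarray) -> float:
        yp = Y[np.ix_(perm, perm)][iu]
        xv = X[iu]
        m = ~np.isnan(yp) & ~np.isnan(xv)
        if m.sum() < 3 or np.std(yp[m]) == 0 or np.std(xv[m]) == 0:
            return 0.0
        return float(np.corrcoef(yp[m], xv[m])[0, 1])

    rng = np.random.default_rng(seed)
    observed = corr(np.arange(n))
    hits = sum(
        abs(corr(rng.permutation(n))) >= abs(observed) for _ in range(n_permutations)
    )
    return (hits + 1) / (n_permutations + 1)


def report(result: RegressionResult) -> tuple[str, pd.DataFrame]:
    """Summary in the shape of a one-row drivers table.

    Columns: overall_p, selected_terms, beta_<term> and p_<term> for each
    selected covariate, r2_percent.  The text rendering mirrors the table.
    """
    row: dict[str, object] = {
        "overall_p": result.overall_f_pvalue,
        "selected_terms": "+".join(result.selected_terms) or "",
        "r2_percent": result.r2_percent if result.selected_terms else np.nan,
    }
    for t in result.selected_terms:
        row[f"beta_{t}"] = result.beta[t]
        row[f"p_{t}"] = result.t_pvalues[t]
    table = pd.DataFrame([row])

    lines = [f"n pairs: {result.n_obs}"]
    if result.null_selected:
        lines.append("selected model: intercept-only (no driver retained)")
    else:
        lines.append(f"overall F test (selected vs null): p = {result.overall_f_pvalue:.4g}")
        for t in result.selected_terms:
            star = " *" if t in result.significant_terms else ""
            lines.append(f"beta_{t} = {result.beta[t]:.4g}  p = {result.t_pvalues[t]:.4g}{star}")
        lines.append(f"R^2 = {result.r2_percent:.2f}%")
    return "\n".join(lines), table
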