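"""Survival screening and meta-analysis of (inferred) lncRNA expression.

Per dataset, each lncRNA's expression is scored by a univariate Cox
proportional-hazards model (Efron tie handling, damped Newton); per-dataset
z = beta / SE are combined across the datasets of one cancer-type family by
weighted Stouffer meta-analysis (weights = dataset sample sizes, as is, or
sqrt(n) optionally), with a robust leave-one-out variant that drops the
single most significant dataset.  Meta p-values are adjusted per family by
Benjamini-Hochberg and Bonferroni.

The Cox solver is implemented in-package so that genome-wide screens can be
fitted for all genes simultaneously (one vectorised Newton iteration per
step rather than one model object per gene).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxFit",
    "MetaResult",
    "fit_univariate_cox",
    "fit_multivariate_cox",
    "cox_screen",
    "stouffer_meta",
    "robust_meta",
    "adjust_pvalues",
    "km_logrank",
    "SurvivalScreen",
    "ScreenResults",
]


@dataclass
class CoxFit:
    beta: float
    se: float
    z: float
    hr: float
    p: float
    n: int
    converged: bool


@dataclass
class MetaResult:
    lncrna: str
    per_dataset_z: dict[str, float]
    meta_z: float
    robust_meta_z: float | None
    meta_p: float
    fdr_bh: float | None
    bonferroni: float | None
    left_out_dataset: str | None


def _validate_survival(time: np.ndarray, event: np.ndarray) -> None:
    if (time <= 0).any():
        raise ValueError("follow-up times must be > 0")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")


# ---------------------------------------------------------------------------
# batched univariate Cox (Efron ties, damped Newton)
# ---------------------------------------------------------------------------

def _group_structure(time: np.ndarray, event: np.ndarray):
    """Ascending-time ordering with tie groups.

    Returns (order, starts, d) where ``starts`` are group start indices in
    the ordered arrays and ``d`` the number of events per group.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    starts = np.flatnonzero(np.concatenate([[True], t[1:] != t[:-1]]))
    grp_of = np.cumsum(np.concatenate([[0], (t[1:] != t[:-1]).astype(int)]))
    d = np.bincount(grp_of, weights=event[order].astype(float),
                    minlength=len(starts))
    return order, starts, grp_of, d


def _cox_batch_score(beta, X, event_o, starts, grp_of, d, max_d):
    """Efron log-likelihood, score and information for all genes at once.

    ``X`` is (G, n) ordered by ascending time; ``beta`` is (G,).
    """
    G, n = X.shape
    K = len(starts)
    eta = np.clip(beta[:, None] * X, -500, 500)
    e = np.exp(eta)
    xe = X * e
    x2e = X * xe

    def suffix_at_starts(a):
        rc = np.cumsum(a[:, ::-1], axis=1)[:, ::-1]
        return rc[:, starts]

    S0 = suffix_at_starts(e)
    S1 = suffix_at_starts(xe)
    S2 = suffix_at_starts(x2e)

    ev = event_o.astype(float)

    def group_event_sum(a):
        return np.add.reduceat(a * ev, starts, axis=1)

    s0d = group_event_sum(e)
    s1d = group_event_sum(xe)
    s2d = group_event_sum(x2e)
    sum_x_events = group_event_sum(X).sum(axis=1)
    sum_eta_events = group_event_sum(eta).sum(axis=1)

    U = sum_x_events.copy()
    I = np.zeros(G)
    ll = sum_eta_events.copy()
    for l in range(max_d):
        active = d > l                      # groups with at least l+1 events
        if not active.any():
            break
        frac = np.where(active, l / np.maximum(d, 1), 0.0)
        a0 = S0 - frac * s0d
        a1 = S1 - frac * s1d
        a2 = S2 - frac * s2d
        with np.errstate(divide="ignore", invalid="ignore"):
            r1 = a1 / a0
            term_i = a2 / a0 - r1**2
            log_a0 = np.log(a0)
        mask = active[None, :]
        U -= np.where(mask, r1, 0.0).sum(axis=1)
        I += np.where(mask, term_i, 0.0).sum(axis=1)
        ll -= np.where(mask, log_a0, 0.0).sum(axis=1)
    return ll, U, I


def cox_screen(
    X: np.ndarray | pd.DataFrame,
    time: Sequence[float],
    event: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Univariate Cox fits for every row of a gene-by-sample matrix.

    Returns a DataFrame with beta, se, z, hr, p, n and a convergence flag per
    gene.  Genes with zero variance get NaN estimates.
    """
    if isinstance(X, pd.DataFrame):
        index = X.index
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.atleast_2d(np.asarray(X, dtype=float))
        index = pd.RangeIndex(Xv.shape[0])
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    _validate_survival(time, event)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    G, n = Xv.shape
    if n != len(time):
        raise ValueError("matrix width must match survival table length")

    order, starts, grp_of, d = _group_structure(time, event)
    max_d = int(d.max())
    Xo = Xv[:, order]
    event_o = event[order]
    # centering leaves the partial likelihood invariant but stabilises exp()
    Xo = Xo - Xo.mean(axis=1, keepdims=True)
    sd = Xo.std(axis=1)
    degenerate = sd == 0

    beta = np.zeros(G)
    converged = np.zeros(G, dtype=bool)
    ll, U, I = _cox_batch_score(beta, Xo, event_o, starts, grp_of, d, max_d)
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(I > 0, U / np.maximum(I, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        step = np.where(converged | degenerate, 0.0, step)
        if np.all(np.abs(step) < tol):
            converged |= ~degenerate
            break
        new_beta = beta + step
        new_ll, new_U, new_I = _cox_batch_score(
            new_beta, Xo, event_o, starts, grp_of, d, max_d
        )
        # damp any gene whose likelihood worsened
        for _ in range(30):
            worse = (new_ll < ll - 1e-12) & ~converged & ~degenerate
            if not worse.any():
                break
            step = np.where(worse, step / 2.0, step)
            new_beta = beta + step
            new_ll, new_U, new_I = _cox_batch_score(
                new_beta, Xo, event_o, starts, grp_of, d, max_d
            )
        just_done = (np.abs(step) < tol) & ~degenerate
        converged |= just_done
        beta, ll, U, I = new_beta, new_ll, new_U, new_I

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(I > 0, 1.0 / np.sqrt(np.maximum(I, 1e-300)), np.nan)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "z": z,
            "hr": np.exp(beta),
            "p": p,
            "n": n,
            "converged": converged,
        },
        index=index,
    )
    out.loc[degenerate, ["beta", "se", "z", "hr", "p"]] = np.nan
    out.loc[degenerate, "converged"] = False
    return out


def fit_univariate_cox(
    x: Sequence[float], surv: pd.DataFrame, tol: float = 1e-8
) -> CoxFit:
    """Univariate Cox PH fit of one expression vector against survival.

    ``surv`` needs ``time`` and ``event`` columns aligned with ``x``.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("x must be finite")
    if np.ptp(x) == 0:
        raise ValueError("constant expression vector: degenerate fit")
    if int(surv["event"].sum()) < 2:
        raise ValueError("need at least 2 events")
    row = cox_screen(x[None, :], surv["time"].to_numpy(),
                     surv["event"].to_numpy(), tol=tol).iloc[0]
    return CoxFit(
        beta=float(row.beta), se=float(row.se), z=float(row.z),
        hr=float(row.hr), p=float(row.p), n=int(row.n),
        converged=bool(row.converged),
    )


# ---------------------------------------------------------------------------
# multivariate Cox
# ---------------------------------------------------------------------------

def _cox_fit_matrix(X, time, event, tol=1e-8, max_iter=50):
    """General Efron Cox fit; X is (n, p).  Returns beta, cov, converged."""
    n, p = X.shape
    order, starts, grp_of, d = _group_structure(time, event)
    Xo = X[order]
    ev = event[order].astype(float)
    Xo = Xo - Xo.mean(axis=0, keepdims=True)
    K = len(starts)
    max_d = int(d.max())

    def score(beta):
        eta = np.clip(Xo @ beta, -500, 500)
        e = np.exp(eta)
        we = e[:, None] * Xo
        ll = float((eta * ev).sum())
        U = (Xo * ev[:, None]).sum(axis=0)
        I = np.zeros((p, p))
        # suffix sums at group starts
        S0 = np.cumsum(e[::-1])[::-1][starts]
        S1 = np.cumsum(we[::-1], axis=0)[::-1][starts]
        outer = Xo[:, :, None] * we[:, None, :]
        S2 = np.cumsum(outer[::-1], axis=0)[::-1][starts]
        s0d = np.add.reduceat(e * ev, starts)
        s1d = np.add.reduceat(we * ev[:, None], starts, axis=0)
        s2d = np.add.reduceat(outer * ev[:, None, None], starts, axis=0)
        for g in range(K):
            dg = int(d[g])
            for l in range(dg):
                frac = l / dg
                a0 = S0[g] - frac * s0d[g]
                a1 = S1[g] - frac * s1d[g]
                a2 = S2[g] - frac * s2d[g]
                ll -= np.log(a0)
                U -= a1 / a0
                I += a2 / a0 - np.outer(a1, a1) / a0**2
        return ll, U, I

    beta = np.zeros(p)
    converged = False
    ll, U, I = score(beta)
    for _ in range(max_iter):
        step = np.linalg.solve(I, U)
        if np.abs(step).max() < tol:
            converged = True
            break
        nb = beta + step
        nll, nU, nI = score(nb)
        for _ in range(30):
            if nll >= ll - 1e-12:
                break
            step = step / 2.0
            nb = beta + step
            nll, nU, nI = score(nb)
        beta, ll, U, I = nb, nll, nU, nI
    cov = np.linalg.inv(I)
    return beta, cov, converged


def fit_multivariate_cox(
    x: Sequence[float],
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame,
    surv: pd.DataFrame,
    tol: float = 1e-8,
) -> CoxFit:
    """Covariate-adjusted Cox fit; returns the CoxFit of the ``x`` coefficient.

    Complete-case: samples with any missing covariate are dropped.  A
    rank-deficient design raises a collinearity error naming the offending
    columns.
    """
    x = np.asarray(x, dtype=float)
    cov_df = pd.DataFrame(covariates)
    cov_df = cov_df.loc[:, cov_df.apply(lambda c: np.ptp(c.to_numpy(float)) > 0
                                        if c.notna().all() else True)]
    design = pd.concat(
        [pd.Series(x, name="__x__", index=cov_df.index), cov_df], axis=1
    )
    keep = design.notna().all(axis=1).to_numpy()
    design = design.loc[keep]
    time = surv["time"].to_numpy(dtype=float)[keep]
    event = surv["event"].to_numpy()[keep]
    _validate_survival(time, event)
    M = design.to_numpy(dtype=float)
    Mc = M - M.mean(axis=0)
    rank = np.linalg.matrix_rank(Mc)
    if rank < M.shape[1]:
        # name columns involved in the deficiency
        bad = []
        cols = list(design.columns)
        for j in range(1, M.shape[1]):
            sub = np.delete(Mc, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(cols[j])
        raise ValueError(f"collinear design; offending columns: {bad}")
    beta, cov, converged = _cox_fit_matrix(M, time, event, tol=tol)
    b = float(beta[0])
    se = float(np.sqrt(cov[0, 0]))
    z = b / se
    p = float(np.clip(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return CoxFit(beta=b, se=se, z=z, hr=float(np.exp(b)), p=p,
                  n=int(M.shape[0]), converged=converged)


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def stouffer_meta(
    zs: Sequence[float], ns: Sequence[float], weight_mode: str = "n"
) -> float:
    """Weighted Stouffer combination: sum(w z) / sqrt(sum(w^2)).

    Weights are the dataset sample sizes (default) or their square roots.
    Invariant to rescaling all weights by a common factor.
    """
    zs = np.asarray(zs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if zs.size == 0 or zs.shape != ns.shape:
        raise ValueError("zs and ns must be nonempty and equal-length")
    if (ns <= 0).any():
        raise ValueError("sample sizes must be positive")
    if weight_mode == "n":
        w = ns
    elif weight_mode == "sqrt_n":
        w = np.sqrt(ns)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    return float((w * zs).sum() / np.sqrt((w**2).sum()))


def robust_meta(
    zs: Sequence[float],
    ns: Sequence[float],
    dataset_ids: Sequence[str] | None = None,
    weight_mode: str = "n",
) -> tuple[float, str]:
    """Leave-one-out Stouffer: drop the most significant dataset (max |z|).

    Ties on |z| break to the first dataset in lexicographic id order.
    Requires at least two datasets.
    """
    zs = np.asarray(zs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if zs.size < 2:
        raise ValueError("robust meta-z needs at least 2 datasets")
    if dataset_ids is None:
        dataset_ids = [str(i) for i in range(zs.size)]
    ids = list(dataset_ids)
    best = max(range(zs.size), key=lambda i: (np.abs(zs[i]), ), default=0)
    # tie-break: among indices achieving max |z|, lexicographically first id
    m = np.abs(zs).max()
    tied = [i for i in range(zs.size) if np.abs(zs[i]) == m]
    best = min(tied, key=lambda i: ids[i])
    mask = np.ones(zs.size, dtype=bool)
    mask[best] = False
    return stouffer_meta(zs[mask], ns[mask], weight_mode), ids[best]


def adjust_pvalues(ps: Sequence[float], method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg (step-up, monotone) or Bonferroni adjustment."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return ps
    if ((ps <= 0) | (ps > 1)).any() or not np.isfinite(ps).all():
        raise ValueError("p-values must lie in (0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(ps, method=key)[1]


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

def km_logrank(
    iexpr: Sequence[float], surv: pd.DataFrame, threshold: float = 0.0
) -> dict:
    """Two-group log-rank test after dichotomising at ``threshold``.

    High group: iexpr > threshold; low group: iexpr <= threshold (exact
    zeros fall in the low group).  Returns the chi-square statistic, p-value,
    group sizes and per-group Kaplan-Meier step tables.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    x = np.asarray(iexpr, dtype=float)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy()
    _validate_survival(time, event)
    high = x > threshold
    if high.all() or (~high).all():
        raise ValueError("one dichotomised group is empty")
    res = logrank_test(time[high], time[~high],
                       event_observed_A=event[high],
                       event_observed_B=event[~high])
    curves = {}
    for label, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=label)
        curves[label] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", label: "survival"}
        )
    return {
        "chi_square": float(res.test_statistic),
        "p": float(res.p_value),
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "curves": curves,
    }


# ---------------------------------------------------------------------------
# screen facade
# ---------------------------------------------------------------------------

class SurvivalScreen:
    """Pan-dataset survival screen of a lncRNA-by-sample expression matrix.

    Parameters
    ----------
    expr : pandas.DataFrame
        lncRNAs in rows; columns are sample ids appearing in ``survival``.
    survival : pandas.DataFrame
        Columns ``sample``, ``time``, ``event``, ``dataset``; every dataset
        forms one stratum of the meta-analysis.
    """

    def __init__(self, expr: pd.DataFrame, survival: pd.DataFrame):
        required = {"sample", "time", "event", "dataset"}
        missing = required - set(survival.columns)
        if missing:
            raise ValueError(f"survival table missing columns: {missing}")
        dup = survival.duplicated(subset=["sample", "dataset"])
        if dup.any():
            raise ValueError("duplicate sample ids within a dataset")
        self.expr = expr
        self.survival = survival

    def fit(self, weight_mode: str = "n") -> "ScreenResults":
        per_rows = []
        z_by_lnc: dict[str, dict[str, float]] = {}
        n_by_ds: dict[str, int] = {}
        for ds, sub in self.survival.groupby("dataset", sort=True):
            samples = [s for s in sub["sample"] if s in self.expr.columns]
            if len(samples) < 3:
                continue
            sub = sub.set_index("sample").loc[samples]
            X = self.expr[samples]
            fits = cox_screen(X, sub["time"].to_numpy(),
                              sub["event"].to_numpy())
            n_by_ds[str(ds)] = len(samples)
            for lnc, row in fits.iterrows():
                if np.isnan(row.z):
                    continue
                z_by_lnc.setdefault(lnc, {})[str(ds)] = float(row.z)
                per_rows.append(
                    {"lncrna": lnc, "dataset": str(ds), "beta": row.beta,
                     "se": row.se, "z": row.z, "hr": row.hr, "p": row.p,
                     "n": int(row.n)}
                )
        per_dataset = pd.DataFrame(per_rows)

        metas: list[MetaResult] = []
        for lnc, zmap in z_by_lnc.items():
            ids = sorted(zmap)
            zs = np.array([zmap[d] for d in ids])
            ns = np.array([n_by_ds[d] for d in ids], dtype=float)
            meta_z = stouffer_meta(zs, ns, weight_mode)
            if len(ids) >= 2:
                robust_z, left_out = robust_meta(zs, ns, ids, weight_mode)
            else:
                robust_z, left_out = None, None
            meta_p = float(np.clip(2 * stats.norm.sf(abs(meta_z)),
                                   np.finfo(float).tiny, 1.0))
            metas.append(MetaResult(
                lncrna=lnc, per_dataset_z=zmap, meta_z=meta_z,
                robust_meta_z=robust_z, meta_p=meta_p,
                fdr_bh=None, bonferroni=None, left_out_dataset=left_out,
            ))
        if metas:
            ps = [m.meta_p for m in metas]
            bh = adjust_pvalues(ps, "BH")
            bf = adjust_pvalues(ps, "bonferroni")
            for m, a, b in zip(metas, bh, bf):
                m.fdr_bh = float(a)
                m.bonferroni = float(b)
        return ScreenResults(self, per_dataset, metas, weight_mode)


class ScreenResults:
    """Per-dataset Cox fits plus the per-lncRNA meta-analysis table."""

    def __init__(self, model, per_dataset, metas, weight_mode):
        self.model = model
        self.per_dataset = per_dataset
        self.metas = metas
        self.weight_mode = weight_mode

    @property
    def meta_table(self) -> pd.DataFrame:
        rows = [
            {
                "lncrna": m.lncrna,
                "meta_z": m.meta_z,
                "robust_meta_z": (np.nan if m.robust_meta_z is None
                                  else m.robust_meta_z),
                "meta_p": m.meta_p,
                "fdr_bh": m.fdr_bh,
                "bonferroni": m.bonferroni,
                "left_out_dataset": m.left_out_dataset or "",
            }
            for m in self.metas
        ]
        return pd.DataFrame(
            rows,
            columns=["lncrna", "meta_z", "robust_meta_z", "meta_p",
                     "fdr_bh", "bonferroni", "left_out_dataset"],
        ).set_index("lncrna")

    def summary(self) -> pd.DataFrame:
        return self.meta_table.sort_values("meta_p")
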