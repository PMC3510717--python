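"""Time-varying-covariate proportional-hazards modelling of relevant posting.

The event of interest is "the user posts a highly relevant photo in the
next 10-day interval".  For every community user, intervals tile the span
from their first photo to the observation end on a 10-day grid; each
interval is an at-risk row (Andersen–Gill counting process, recurrent
events allowed) carrying six covariates computed from data strictly before
the interval start:

* number of relevant photos posted,
* number of views of the user's photos (views are credited at posting time),
* number of views of their relevant photos,
* number of comments received from same-class users,
* number of comments received from other-class users,
* fraction of received comments from same-class users (0 when no comments).

Each covariate exists in a cumulative version (all previous time) and a
recent version (the preceding 30 days).  Covariates are log(1+x)
transformed and, by default, z-scored within the fitting population.  The
partial likelihood is maximised by Newton's method with Breslow tie
handling (the standard cheap choice on a coarse grid with heavy ties);
Efron tie handling is available and delegates to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from edtribes.corpus import Corpus
from edtribes.labels import ClassLabel
from edtribes.synth import HAZARD_COVARIATES

__all__ = [
    "build_hazard_panel",
    "transform_features",
    "fit_hazard_model",
    "HazardFit",
    "HazardFitError",
    "feature_columns",
]

_COMMUNITY = (ClassLabel.PRO_ANA, ClassLabel.PRO_RECOVERY)


class HazardFitError(RuntimeError):
    """Non-convergence or separation, with diagnostics in the message."""


def feature_columns(feature_set: str) -> list[str]:
    """Panel column names of a feature set, in canonical covariate order."""
    if feature_set not in ("cumulative", "recent"):
        raise ValueError("feature_set must be 'cumulative' or 'recent'")
    prefix = "cum_" if feature_set == "cumulative" else "recent_"
    return [prefix + c for c in HAZARD_COVARIATES]


def build_hazard_panel(
    corpus: Corpus,
    labels: dict[str, ClassLabel],
    flags: pd.Series,
    resolution_days: int = 10,
    window_days: int = 30,
    observation_end: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Per-user per-interval covariate/event table on the 10-day grid.

    The grid is anchored at the earliest photo timestamp in the corpus; a
    user's rows run from the interval of their first photo to the interval
    containing the observation end.  Cumulative covariates aggregate data
    strictly before the interval start; recent covariates aggregate the
    window ``[start - window_days, start)``.  Comment class is relative to
    the photo owner's class and only labeled community commenters count.
    The event indicator marks intervals in which the user posted at least
    one relevant photo.
    """
    obs_end = observation_end or corpus.observation_end
    photos = corpus.photos
    comm_users = sorted(u for u, l in labels.items() if l in _COMMUNITY)
    if not comm_users or not len(photos):
        return _empty_panel()
    uidx = {u: i for i, u in enumerate(comm_users)}
    n_u = len(comm_users)

    anchor = photos["posted_at"].min()
    res = pd.Timedelta(days=resolution_days)
    n_iv = int(np.floor((obs_end - anchor) / res)) + 1
    win = max(1, window_days // resolution_days)

    # per-(user, interval) increments of the five count covariates
    inc = np.zeros((5, n_u, n_iv))
    events = np.zeros((n_u, n_iv), dtype=bool)
    first_iv = np.full(n_u, n_iv, dtype=int)

    owner_arr = photos["owner_id"].to_numpy()
    iv_arr = ((photos["posted_at"] - anchor) // res).astype(int).to_numpy()
    views_arr = photos["view_count"].to_numpy(dtype=float)
    rel_arr = photos["photo_id"].map(flags).fillna(False).astype(bool).to_numpy()
    for owner, iv, views, rel in zip(owner_arr, iv_arr, views_arr, rel_arr):
        i = uidx.get(owner)
        if i is None or iv < 0 or iv >= n_iv:
            continue
        first_iv[i] = min(first_iv[i], iv)
        inc[1, i, iv] += views
        if rel:
            inc[0, i, iv] += 1
            inc[2, i, iv] += views
            events[i, iv] = True

    if len(corpus.comments):
        owner_of = photos.set_index("photo_id")["owner_id"]
        c_owner = corpus.comments["photo_id"].map(owner_of)
        c_iv = ((corpus.comments["commented_at"] - anchor) // res).astype(int).to_numpy()
        for owner, commenter, iv in zip(
            c_owner.to_numpy(), corpus.comments["commenter_id"].to_numpy(), c_iv
        ):
            i = uidx.get(owner)
            if i is None or iv < 0 or iv >= n_iv:
                continue
            lab_o, lab_c = labels.get(owner), labels.get(commenter)
            if lab_c not in _COMMUNITY:
                continue
            if lab_c is lab_o:
                inc[3, i, iv] += 1
            else:
                inc[4, i, iv] += 1

    cum_before = np.concatenate(
        [np.zeros((5, n_u, 1)), np.cumsum(inc, axis=2)[:, :, :-1]], axis=2
    )
    recent = cum_before - np.concatenate(
        [np.zeros((5, n_u, win)), cum_before[:, :, :-win]], axis=2
    )[:, :, :n_iv]

    rows = []
    class_col = np.array([labels[u].value for u in comm_users])
    for i, user in enumerate(comm_users):
        if first_iv[i] >= n_iv:
            continue
        ivs = np.arange(first_iv[i], n_iv)
        cb = cum_before[:, i, ivs]
        rc = recent[:, i, ivs]
        cfrac = np.where(cb[3] + cb[4] > 0, cb[3] / np.maximum(cb[3] + cb[4], 1e-300), 0.0)
        rfrac = np.where(rc[3] + rc[4] > 0, rc[3] / np.maximum(rc[3] + rc[4], 1e-300), 0.0)
        block = pd.DataFrame(
            {
                "user_id": user,
                "class": class_col[i],
                "interval": ivs,
                "interval_start": anchor + ivs * res,
                "cum_relevant_photos": cb[0],
                "cum_views": cb[1],
                "cum_views_relevant": cb[2],
                "cum_comments_same": cb[3],
                "cum_comments_other": cb[4],
                "cum_frac_comments_same": cfrac,
                "recent_relevant_photos": rc[0],
                "recent_views": rc[1],
                "recent_views_relevant": rc[2],
                "recent_comments_same": rc[3],
                "recent_comments_other": rc[4],
                "recent_frac_comments_same": rfrac,
                "event": events[i, ivs],
            }
        )
        rows.append(block)
    return pd.concat(rows, ignore_index=True) if rows else _empty_panel()


def _empty_panel() -> pd.DataFrame:
    cols = (
        ["user_id", "class", "interval", "interval_start"]
        + feature_columns("cumulative")
        + feature_columns("recent")
        + ["event"]
    )
    return pd.DataFrame(columns=cols)


@dataclass
class TransformRecord:
    """Parameters of the log1p/z-score transform, for reproducibility."""

    columns: list
    means: dict
    sds: dict
    dropped: list  # zero-variance covariates removed from the design


def transform_features(
    panel: pd.DataFrame,
    feature_set: str,
    standardize: bool = True,
) -> tuple[pd.DataFrame, TransformRecord]:
    """log(1+x)-transform the feature set, optionally z-scoring each column.

    Standardisation uses the mean/SD of the supplied panel (the fitting
    population — call per class for per-class fits).  Zero-variance
    covariates are dropped and recorded.
    """
    cols = feature_columns(feature_set)
    out = panel.copy()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    dropped: list[str] = []
    kept: list[str] = []
    for c in cols:
        x = np.log1p(out[c].to_numpy(dtype=float))
        if standardize:
            m, s = float(x.mean()), float(x.std(ddof=0))
            if s < 1e-12:
                dropped.append(c)
                out = out.drop(columns=[c])
                continue
            means[c], sds[c] = m, s
            x = (x - m) / s
        else:
            if np.ptp(x) < 1e-12:
                dropped.append(c)
                out = out.drop(columns=[c])
                continue
        out[c] = x
        kept.append(c)
    return out, TransformRecord(kept, means, sds, dropped)


@dataclass
class HazardFit:
    """Results of one proportional-hazards fit."""

    class_label: str
    feature_set: str
    ties_method: str
    params: pd.Series
    standard_errors: pd.Series
    pvalues: pd.Series
    n_intervals: int
    n_events: int
    loglik: float
    converged: bool
    transform: TransformRecord
    n_iter: int = 0

    def summary(self) -> pd.DataFrame:
        """Coefficient table: coef, exp(coef), se, z, p."""
        z = self.params / self.standard_errors
        return pd.DataFrame(
            {
                "coef": self.params,
                "exp(coef)": np.exp(self.params),
                "se(coef)": self.standard_errors,
                "z": z,
                "p": self.pvalues,
            }
        )


def fit_hazard_model(
    panel: pd.DataFrame,
    class_label: ClassLabel | str,
    feature_set: str = "cumulative",
    ties_method: str = "breslow",
    standardize: bool = True,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> HazardFit:
    """Fit the proportional-hazards partial likelihood on one class's panel.

    Each interval is an at-risk row (events may recur); rows at risk at an
    event time are exactly the rows of that interval.  ``ties_method`` is
    ``breslow`` (default, fitted by a Newton solver written for this grouped
    structure) or ``efron`` (delegating to lifelines'
    ``CoxTimeVaryingFitter``).  Raises :class:`HazardFitError` on
    separation or non-convergence.
    """
    cls = ClassLabel(class_label).value
    sub = panel[panel["class"] == cls]
    if not len(sub):
        raise ValueError(f"no panel rows for class {cls}")
    if int(sub["event"].sum()) == 0:
        raise HazardFitError(f"no events for class {cls}: partial likelihood undefined")
    transformed, record = transform_features(sub, feature_set, standardize=standardize)
    cols = record.columns
    if not cols:
        raise HazardFitError("all covariates have zero variance")
    X = transformed[cols].to_numpy(dtype=float)
    event = transformed["event"].to_numpy(dtype=bool)
    group = transformed["interval"].to_numpy(dtype=int)

    if ties_method == "breslow":
        beta, se, ll, converged, n_iter = _newton_cox(X, event, group, "breslow", max_iter, tol)
    elif ties_method == "efron":
        beta, se, ll, converged, n_iter = _fit_efron_lifelines(transformed, cols)
    else:
        raise ValueError(f"unknown ties_method: {ties_method}")

    pvals = 2 * stats.norm.sf(np.abs(beta / se))
    return HazardFit(
        class_label=cls,
        feature_set=feature_set,
        ties_method=ties_method,
        params=pd.Series(beta, index=cols),
        standard_errors=pd.Series(se, index=cols),
        pvalues=pd.Series(pvals, index=cols),
        n_intervals=len(sub),
        n_events=int(event.sum()),
        loglik=ll,
        converged=converged,
        transform=record,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Breslow partial-likelihood Newton solver


def _group_sums(group, n_groups, w, X):
    """S0, S1, S2 sums of w, w*x, w*x*x' per interval group."""
    p = X.shape[1]
    S0 = np.zeros(n_groups)
    np.add.at(S0, group, w)
    S1 = np.zeros((n_groups, p))
    np.add.at(S1, group, w[:, None] * X)
    S2 = np.zeros((n_groups, p, p))
    np.add.at(S2, group, w[:, None, None] * (X[:, :, None] * X[:, None, :]))
    return S0, S1, S2


def _breslow_ll_grad_hess(beta, X, event, group, n_groups, d, sum_x_events):
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    S0, S1, S2 = _group_sums(group, n_groups, w, X)
    active = d > 0
    ll = float(sum_x_events @ beta - (d[active] * np.log(S0[active])).sum())
    xbar = S1[active] / S0[active, None]
    grad = sum_x_events - (d[active, None] * xbar).sum(axis=0)
    cov = S2[active] / S0[active, None, None] - xbar[:, :, None] * xbar[:, None, :]
    hess = -(d[active, None, None] * cov).sum(axis=0)
    return ll, grad, hess


def _newton_cox(X, event, group, ties, max_iter, tol):
    groups, group_idx = np.unique(group, return_inverse=True)
    n_groups = len(groups)
    d = np.zeros(n_groups)
    np.add.at(d, group_idx[event], 1.0)
    sum_x_events = X[event].sum(axis=0)

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _breslow_ll_grad_hess(beta, X, event, group_idx, n_groups, d, sum_x_events)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise HazardFitError(f"singular Hessian at iteration {it}") from exc
        # step-halving line search on the log partial likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, hess_new = _breslow_ll_grad_hess(
                cand, X, event, group_idx, n_groups, d, sum_x_events
            )
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        else:  # pragma: no cover - pathological
            raise HazardFitError(f"line search failed at iteration {it}")
        delta = np.abs(cand - beta).max()
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.abs(beta).max() > 50:
            raise HazardFitError(
                f"separation suspected: |beta| diverged ({np.abs(beta).max():.1f}) at iteration {it}"
            )
        if delta < tol or np.abs(grad).max() < 1e-7:
            converged = True
            break
    if not converged:
        raise HazardFitError(
            f"Newton failed to converge in {max_iter} iterations (max |grad| {np.abs(grad).max():.2e})"
        )
    info = -hess
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se, ll, converged, it


def _fit_efron_lifelines(transformed: pd.DataFrame, cols: list[str]):
    from lifelines import CoxTimeVaryingFitter

    df = transformed[cols].copy()
    df["start"] = transformed["interval"].to_numpy(dtype=float)
    df["stop"] = df["start"] + 1.0
    df["event"] = transformed["event"].to_numpy(dtype=bool)
    df["id"] = pd.factorize(transformed["user_id"])[0]
    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    ctv.fit(df, id_col="id", event_col="event", start_col="start", stop_col="stop")
    beta = ctv.params_.reindex(cols).to_numpy()
    se = ctv.standard_errors_.reindex(cols).to_numpy()
    return beta, se, float(ctv.log_likelihood_), True, 0
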