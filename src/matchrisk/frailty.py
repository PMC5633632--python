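"""Proportional-hazards models with nested log-normal frailties.

The model: intervals indexed i carry a gap-time duration (exposure hours),
an event flag, fixed covariates x_i, and cluster memberships (team,
player).  The hazard is

    h_i(t) = h0(t) · exp(x_i' beta + u_team(i) + v_player(i)),

with Gaussian random intercepts u ~ N(0, s2_team), v ~ N(0, s2_player)
(log-normal frailties on the hazard scale).  Estimation:

* inner loop — Newton–Raphson maximizes the penalized partial
  log-likelihood PPL(beta, b) = pl(beta, b) − b' S^-1 b / 2 at fixed
  variance components, with Efron or Breslow handling of tied durations and
  monotone step-halving;
* outer loop — a derivative-free bounded search on the log-variance scale
  maximizes the Laplace-approximate integrated (marginal) log-likelihood

      ILL(s2) = PPL(beta^, b^) − log det(I + S^1/2 K S^1/2) / 2,

  where K is the observed information of the partial likelihood in the
  random-effect block at the mode.

With no random structure the fit reduces exactly to Cox PH; with a single
player effect it is the shared frailty model.  AIC = −2 LL + 2k and
BIC = −2 LL + k ln(n_events), with LL the integrated log-likelihood (the
partial log-likelihood for Cox PH) and k counting fixed effects plus
variance components — not effective degrees of freedom, a documented
simplification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2, norm

Z90 = norm.ppf(0.95)

LOGVAR_LO = -12.0
LOGVAR_HI = 3.0


class FitError(RuntimeError):
    """Non-convergence or an unidentifiable design."""


# ---------------------------------------------------------------------------
# model specification and design assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """One fixed-effect term: a covariate with optional polynomial degree.

    Degree 2 or 3 expands the covariate into a centred, SD-scaled power
    basis z, z^2 (, z^3) to decorrelate the terms; degree-1 columns enter
    as supplied (standardize upstream for 2-SD hazard ratios).  Categorical
    terms (strings, or flagged) expand into treatment dummies against the
    first sorted level.
    """

    name: str
    degree: int = 1
    categorical: bool = False

    def __post_init__(self):
        if not 1 <= self.degree <= 3:
            raise ValueError("polynomial degree must be 1, 2 or 3")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model definition.

    terms: covariate names or :class:`Term` objects.
    interactions: (quartile_column, continuous_column) pairs; each adds the
        quartile main-effect dummies (reference = lowest quartile) and the
        quartile × continuous product terms.
    random: "none" (Cox PH), "player" (shared frailty) or
        "team_player_nested" (nested frailty, requires >= 2 teams).
    ties: "efron" (default) or "breslow".
    """

    terms: tuple = ()
    interactions: tuple = ()
    random: str = "team_player_nested"
    ties: str = "efron"

    def __post_init__(self):
        object.__setattr__(
            self,
            "terms",
            tuple(t if isinstance(t, Term) else Term(t) for t in self.terms),
        )
        object.__setattr__(self, "interactions", tuple(tuple(p) for p in self.interactions))
        if self.random not in ("none", "player", "team_player_nested"):
            raise ValueError(f"unknown random structure {self.random!r}")
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method {self.ties!r}")


@dataclass
class FitControl:
    """Numerical tolerances for the two-level optimization."""

    inner_tol: float = 1e-8  # relative PPL change
    inner_maxiter: int = 50
    outer_xatol: float = 0.02  # log-variance scale
    outer_fatol: float = 1e-5
    outer_maxfev: int = 120
    variance_se: bool = True  # numeric outer Hessian for SE(sigma2)
    logvar_init: float = math.log(0.1)


@dataclass
class DesignInfo:
    """Assembled design: matrix, names, cluster codes, basis metadata."""

    X: np.ndarray
    names: list
    start: np.ndarray  # gap-time risk-window bounds (start, stop]
    stop: np.ndarray
    events: np.ndarray
    n_intervals: int
    team_codes: np.ndarray
    team_levels: list
    player_codes: np.ndarray
    player_levels: list
    poly: dict  # name -> dict(center, scale, degree, cols, lo, hi)
    interactions: dict  # (qcol, ccol) -> dict(levels, dummy_cols, prod_cols, cont_col)


def _expand_term(intervals: pd.DataFrame, term: Term):
    """Columns and names for one term; returns (matrix, names, polyinfo)."""
    x = intervals[term.name]
    if term.categorical or x.dtype == object or str(x.dtype) in ("category", "string"):
        levels = sorted(pd.unique(x.astype(str)))
        ref, rest = levels[0], levels[1:]
        cols = np.column_stack(
            [(x.astype(str) == lv).to_numpy(dtype=float) for lv in rest]
        ) if rest else np.empty((len(x), 0))
        names = [f"{term.name}[{lv}]" for lv in rest]
        return cols, names, None
    xv = x.to_numpy(dtype=float)
    if term.degree == 1:
        return xv[:, None], [term.name], None
    center = float(xv.mean())
    scale = float(xv.std(ddof=1))
    if scale <= 0:
        raise ValueError(f"term {term.name!r}: zero variance")
    z = (xv - center) / scale
    cols = np.column_stack([z**d for d in range(1, term.degree + 1)])
    names = [term.name] + [f"{term.name}^{d}" for d in range(2, term.degree + 1)]
    info = {
        "center": center,
        "scale": scale,
        "degree": term.degree,
        "lo": float(xv.min()),
        "hi": float(xv.max()),
    }
    return cols, names, info


def build_design(intervals: pd.DataFrame, spec: ModelSpec) -> DesignInfo:
    """Assemble the fixed-effect design matrix and cluster codes."""
    blocks, names = [], []
    poly = {}
    for term in spec.terms:
        cols, nms, info = _expand_term(intervals, term)
        blocks.append(cols)
        start = len(names)
        names.extend(nms)
        if info is not None:
            info["cols"] = list(range(start, start + len(nms)))
            poly[term.name] = info

    interactions = {}
    for qcol, ccol in spec.interactions:
        q = intervals[qcol].to_numpy()
        levels = sorted(pd.unique(q))
        if len(levels) < 2:
            raise ValueError(f"interaction {qcol!r}: fewer than 2 levels")
        c = intervals[ccol].to_numpy(dtype=float)
        dummy_cols, prod_cols = [], []
        dmat, pmat = [], []
        for lv in levels[1:]:
            d = (q == lv).astype(float)
            dmat.append(d)
            dummy_cols.append(len(names))
            names.append(f"{qcol}[{lv}]")
        for lv in levels[1:]:
            d = (q == lv).astype(float)
            pmat.append(d * c)
            prod_cols.append(len(names) + len(pmat) - 1)
        # fix prod col indices after dummies were appended
        prod_cols = []
        for k, lv in enumerate(levels[1:]):
            prod_cols.append(len(names))
            names.append(f"{ccol}:{qcol}[{lv}]")
        blocks.append(np.column_stack(dmat + pmat))
        interactions[(qcol, ccol)] = {
            "levels": levels,
            "dummy_cols": dummy_cols,
            "prod_cols": prod_cols,
            "cont_col": names.index(ccol) if ccol in names else None,
        }

    X = np.column_stack(blocks) if blocks else np.empty((len(intervals), 0))
    events = intervals["event"].to_numpy(dtype=bool)
    if "gap_stop_hours" in intervals.columns:
        # counting-process rows: at risk on (gap_start, gap_stop]
        stop = intervals["gap_stop_hours"].to_numpy(dtype=float)
        start = intervals["gap_start_hours"].to_numpy(dtype=float)
    else:
        stop = intervals["duration_hours"].to_numpy(dtype=float)
        start = np.zeros_like(stop)
    if (stop <= start).any():
        raise ValueError("risk windows must have stop > start (positive duration)")
    if "interval_id" in intervals.columns:
        n_intervals = int(intervals["interval_id"].nunique())
    else:
        n_intervals = len(intervals)

    team_levels = sorted(pd.unique(intervals["team_id"].astype(str)))
    player_levels = sorted(pd.unique(intervals["player_id"].astype(str)))
    tmap = {t: i for i, t in enumerate(team_levels)}
    pmap = {p: i for i, p in enumerate(player_levels)}
    team_codes = intervals["team_id"].astype(str).map(tmap).to_numpy(dtype=np.int64)
    player_codes = intervals["player_id"].astype(str).map(pmap).to_numpy(dtype=np.int64)

    if spec.random == "team_player_nested" and len(team_levels) < 2:
        raise ValueError("nested random structure requires >= 2 teams")

    return DesignInfo(
        X=X,
        names=names,
        start=start,
        stop=stop,
        events=events,
        n_intervals=n_intervals,
        team_codes=team_codes,
        team_levels=team_levels,
        player_codes=player_codes,
        player_levels=player_levels,
        poly=poly,
        interactions=interactions,
    )


# ---------------------------------------------------------------------------
# partial-likelihood engine
# ---------------------------------------------------------------------------


class CoxEngine:
    """Cox partial likelihood, gradient and observed information.

    Rows are counting-process records: at risk on the gap-time window
    (start, stop], with an event exactly at stop when flagged.  Plain
    right-censored data are the special case start = 0.  The parameter
    vector is [beta (p), b_1 (q1), b_2 (q2), ...] with cluster-code arrays
    appended as random-intercept coordinates.

    Implementation: with t_1 < ... < t_D the distinct event times, every
    per-row accumulation over the likelihood columns (one per event under
    Efron, one per distinct time weighted by multiplicity under Breslow)
    reduces to prefix-sum differences between the row's start and stop
    positions among the t's.  The observed information assembles as a
    weighted scatter part minus a rank-D outer product U U'.
    """

    def __init__(self, X, stop, events, ties="efron", groups=(), start=None):
        self.ties = ties
        self.X = np.asarray(X, dtype=float)
        self.stop = np.asarray(stop, dtype=float)
        self.start = (
            np.zeros_like(self.stop) if start is None else np.asarray(start, dtype=float)
        )
        self.ev = np.asarray(events, dtype=bool)
        self.n, self.p = self.X.shape
        if np.any(self.stop <= self.start):
            raise ValueError("require stop > start for every record")
        self.groups = [np.asarray(g, dtype=np.int64) for g in groups]
        self.q_sizes = [int(g.max()) + 1 if len(g) else 0 for g in self.groups]
        self.q = int(sum(self.q_sizes))
        self.dim = self.p + self.q
        self.n_events = int(self.ev.sum())
        if self.n_events < 1:
            raise FitError("no events in the interval set")

        self.ev_pos = np.flatnonzero(self.ev)
        t_asc = np.unique(self.stop[self.ev_pos])
        self.t_asc = t_asc
        self.D = len(t_asc)
        # row i is at risk for event time index d (0-based) iff
        # K_start[i] <= d < K_stop[i]
        self.K_stop = np.searchsorted(t_asc, self.stop, side="right")
        self.K_start = np.searchsorted(t_asc, self.start, side="right")
        grp_of_event = np.searchsorted(t_asc, self.stop[self.ev_pos])
        order = np.argsort(grp_of_event, kind="stable")
        self.ev_sorted = self.ev_pos[order]  # event rows grouped by time
        self.grp_m = np.bincount(grp_of_event, minlength=self.D)
        self.grp_ptr = np.concatenate([[0], np.cumsum(self.grp_m)[:-1]])

        if ties == "efron":
            self.col_grp = np.repeat(np.arange(self.D), self.grp_m)
            self.col_l = np.arange(len(self.col_grp)) - self.grp_ptr[self.col_grp]
            self.col_frac = self.col_l / self.grp_m[self.col_grp]
        else:
            self.col_grp = np.arange(self.D)
            self.col_frac = np.zeros(self.D)
        self.col_ptr = (
            self.grp_ptr if ties == "efron" else np.arange(self.D)
        )
        self.n_cols = len(self.col_grp)

        self.group_offsets = []
        off = self.p
        for qs in self.q_sizes:
            self.group_offsets.append(off)
            off += qs

    # -- linear predictor ---------------------------------------------------
    def eta(self, theta):
        theta = np.asarray(theta, dtype=float)
        e = self.X @ theta[: self.p] if self.p else np.zeros(self.n)
        for g, off, qs in zip(self.groups, self.group_offsets, self.q_sizes):
            if qs:
                e = e + theta[off : off + qs][g]
        return e

    def _suffix_bins(self, idx_stop, idx_start, values):
        """sum over rows at risk at each event time, via bin prefix sums."""
        z = np.bincount(idx_stop, weights=values, minlength=self.D + 1)
        z -= np.bincount(idx_start, weights=values, minlength=self.D + 1)
        # S(d) = sum over rows with K_start <= d < K_stop; accumulate bins > d
        return np.cumsum(z[::-1])[::-1][1:]  # length D, entry d uses bins >= d+1

    def _denominators(self, w):
        S0 = self._suffix_bins(self.K_stop, self.K_start, w)
        Wt = np.add.reduceat(w[self.ev_sorted], self.grp_ptr) if self.D else np.empty(0)
        if self.ties == "efron":
            S_col = S0[self.col_grp] - self.col_frac * Wt[self.col_grp]
        else:
            S_col = S0
        return S0, Wt, S_col

    def loglik(self, theta):
        """Cox partial log-likelihood at the full parameter vector."""
        eta = self.eta(theta)
        shift = eta.max()
        w = np.exp(eta - shift)
        _, _, S_col = self._denominators(w)
        if self.ties == "efron":
            return float((eta - shift)[self.ev_pos].sum() - np.log(S_col).sum())
        return float(
            (eta - shift)[self.ev_pos].sum() - (self.grp_m * np.log(S_col)).sum()
        )

    def quantities(self, theta, need_hess=True):
        """(loglik, gradient, observed information) at theta."""
        eta = self.eta(theta)
        shift = eta.max()
        w = np.exp(eta - shift)
        S0, Wt, S_col = self._denominators(w)
        inv_col = 1.0 / S_col

        if self.ties == "efron":
            pl = float((eta - shift)[self.ev_pos].sum() - np.log(S_col).sum())
            col_weight = np.ones(self.n_cols)
        else:
            pl = float(
                (eta - shift)[self.ev_pos].sum() - (self.grp_m * np.log(S_col)).sum()
            )
            col_weight = self.grp_m.astype(float)

        # a_i = sum over columns whose risk set contains i of 1/S_col,
        # minus the Efron own-tied-group adjustment for event rows
        invsum_grp = np.bincount(self.col_grp, weights=col_weight * inv_col, minlength=self.D)
        A = np.concatenate([[0.0], np.cumsum(invsum_grp)])
        a = A[self.K_stop] - A[self.K_start]
        if self.ties == "efron":
            adj_grp = np.bincount(self.col_grp, weights=self.col_frac * inv_col, minlength=self.D)
            a[self.ev_sorted] -= np.repeat(adj_grp, self.grp_m)

        wa = w * a
        resid = self.ev.astype(float) - wa

        grad = np.empty(self.dim)
        if self.p:
            grad[: self.p] = self.X.T @ resid
        for g, off, qs in zip(self.groups, self.group_offsets, self.q_sizes):
            grad[off : off + qs] = np.bincount(g, weights=resid, minlength=qs)

        if not need_hess:
            return pl, grad, None

        # ---- observed information: diagonal-scatter part ----
        info = np.zeros((self.dim, self.dim))
        if self.p:
            info[: self.p, : self.p] = (self.X.T * wa) @ self.X
        for g, off, qs in zip(self.groups, self.group_offsets, self.q_sizes):
            d = np.bincount(g, weights=wa, minlength=qs)
            idx = np.arange(off, off + qs)
            info[idx, idx] += d
            if self.p:
                blk = np.zeros((qs, self.p))
                np.add.at(blk, g, wa[:, None] * self.X)
                info[off : off + qs, : self.p] = blk
                info[: self.p, off : off + qs] = blk.T
        for k1 in range(len(self.groups)):
            for k2 in range(k1 + 1, len(self.groups)):
                g1, g2 = self.groups[k1], self.groups[k2]
                o1, o2 = self.group_offsets[k1], self.group_offsets[k2]
                q1, q2 = self.q_sizes[k1], self.q_sizes[k2]
                acc = np.bincount(g1 * q2 + g2, weights=wa, minlength=q1 * q2).reshape(q1, q2)
                info[o1 : o1 + q1, o2 : o2 + q2] += acc
                info[o2 : o2 + q2, o1 : o1 + q1] += acc.T

        # ---- rank-D correction U U' ----
        # G[:, d] = sum of w_i x_i over rows at risk at event time d
        G = np.empty((self.dim, self.D))
        if self.p:
            for j in range(self.p):
                G[j] = self._suffix_bins(self.K_stop, self.K_start, w * self.X[:, j])
        off_row = 0
        for g, qs in zip(self.groups, self.q_sizes):
            flat = np.bincount(
                g * (self.D + 1) + self.K_stop, weights=w, minlength=qs * (self.D + 1)
            )
            flat -= np.bincount(
                g * (self.D + 1) + self.K_start, weights=w, minlength=qs * (self.D + 1)
            )
            Z = flat.reshape(qs, self.D + 1)
            G[self.p + off_row : self.p + off_row + qs] = np.cumsum(
                Z[:, ::-1], axis=1
            )[:, ::-1][:, 1:]
            off_row += qs

        U = G[:, self.col_grp] * inv_col
        if self.ties == "efron":
            tied = np.flatnonzero(self.grp_m > 1)
            for d in tied:
                members = self.ev_sorted[self.grp_ptr[d] : self.grp_ptr[d] + self.grp_m[d]]
                vec = np.zeros(self.dim)
                if self.p:
                    vec[: self.p] = (w[members, None] * self.X[members]).sum(axis=0)
                for g, off in zip(self.groups, self.group_offsets):
                    np.add.at(vec, off + g[members], w[members])
                cols = np.flatnonzero(self.col_grp == d)
                U[:, cols] -= vec[:, None] * (self.col_frac[cols] * inv_col[cols])
        else:
            U = U * np.sqrt(col_weight)

        info -= U @ U.T
        return pl, grad, info


# ---------------------------------------------------------------------------
# public partial likelihood (oracle-facing)
# ---------------------------------------------------------------------------


def partial_loglik(
    intervals: pd.DataFrame,
    spec: ModelSpec,
    beta=None,
    b_team=None,
    b_player=None,
) -> float:
    """Cox partial log-likelihood at given coefficients and frailty values.

    ``beta`` aligns with the design columns of ``spec`` (zeros when omitted);
    ``b_team`` / ``b_player`` are dicts keyed by team_id / player_id (zero
    for missing keys).  The linear predictor is X beta + b_team + b_player;
    ties are handled by the spec's method.
    """
    design = build_design(intervals, spec)
    groups, offs = [], []
    if spec.random == "player":
        groups = [design.player_codes]
    elif spec.random == "team_player_nested":
        groups = [design.team_codes, design.player_codes]
    engine = CoxEngine(design.X, design.stop, design.events, spec.ties, groups, start=design.start)
    p = design.X.shape[1]
    theta = np.zeros(engine.dim)
    if beta is not None:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (p,):
            raise ValueError(f"beta must have length {p} ({design.names})")
        theta[:p] = beta
    levels = []
    if spec.random == "player":
        levels = [(b_player, design.player_levels)]
    elif spec.random == "team_player_nested":
        levels = [(b_team, design.team_levels), (b_player, design.player_levels)]
    off = p
    for bdict, lvls in levels:
        if bdict:
            for j, lv in enumerate(lvls):
                theta[off + j] = float(bdict.get(lv, 0.0))
        off += len(lvls)
    if not np.all(np.isfinite(engine.eta(theta))):
        raise ValueError("non-finite linear predictor")
    return engine.loglik(theta)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """Estimation output of :func:`fit`."""

    spec: ModelSpec
    names: list
    beta: np.ndarray
    se_beta: np.ndarray
    vcov_beta: np.ndarray
    sigma2_team: float
    sigma2_player: float
    se_sigma2_team: float
    se_sigma2_player: float
    frailty_team: dict
    frailty_player: dict
    loglik: float  # integrated (Laplace) LL; partial LL for Cox PH
    loglik_penalized: float
    aic: float
    bic: float
    k_params: int
    n_events: int
    n_intervals: int
    iterations: int
    grad_norm: float
    converged: bool
    design: DesignInfo = field(repr=False, default=None)

    def coef(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se_beta[i])

    @property
    def n_varcomp(self) -> int:
        return {"none": 0, "player": 1, "team_player_nested": 2}[self.spec.random]

    def summary(self, conf: float = 0.90) -> pd.DataFrame:
        z = norm.ppf(0.5 + conf / 2.0)
        return pd.DataFrame(
            {
                "term": self.names,
                "beta": self.beta,
                "se": self.se_beta,
                "hr": np.exp(self.beta),
                "ci_low": np.exp(self.beta - z * self.se_beta),
                "ci_high": np.exp(self.beta + z * self.se_beta),
                "p": 2 * norm.sf(np.abs(self.beta) / np.where(self.se_beta > 0, self.se_beta, np.nan)),
            }
        )


def _inner_newton(engine, pen_diag, theta0, tol, maxiter):
    """Maximize PPL(theta) = pl − pen·theta²/2 by damped Newton.

    Returns (theta, ppl, pl, grad_pen, info, iterations).  Each accepted
    step does not decrease the PPL (step-halving line search).
    """
    theta = theta0.copy()
    pl, grad, info = engine.quantities(theta)
    f = pl - 0.5 * float(pen_diag @ (theta * theta))
    it = 0
    for it in range(1, maxiter + 1):
        grad_pen = grad - pen_diag * theta
        A = info + np.diag(pen_diag)
        jitter = 0.0
        for _ in range(6):
            try:
                cf = cho_factor(A + (np.eye(len(A)) * jitter if jitter else 0.0), lower=True)
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10.0, 1e-8)
        else:
            raise FitError("penalized information not positive definite (separation?)")
        step = cho_solve(cf, grad_pen)
        # step-halving to keep PPL non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            pl_c = engine.loglik(cand)
            f_c = pl_c - 0.5 * float(pen_diag @ (cand * cand))
            if f_c >= f - 1e-12:
                break
            scale *= 0.5
        else:
            break  # no improving step: treat as converged
        theta = cand
        improved = f_c - f
        f = f_c
        pl, grad, info = engine.quantities(theta)
        if abs(improved) <= tol * (abs(f) + 1.0):
            break
    grad_pen = grad - pen_diag * theta
    return theta, f, pl, grad_pen, info, it


def _laplace_ill(engine, p, pen_diag, theta, ppl, info):
    """Laplace-approximate integrated log-likelihood at the PPL mode."""
    q = engine.dim - p
    if q == 0:
        return ppl
    K = info[p:, p:]
    s = 1.0 / np.sqrt(pen_diag[p:])  # sqrt of variance per coordinate
    M = np.eye(q) + (s[:, None] * K) * s[None, :]
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise FitError("Laplace determinant not positive")
    return ppl - 0.5 * logdet


def fit(
    intervals: pd.DataFrame,
    spec: ModelSpec,
    control: FitControl | None = None,
    fixed_variances: dict | None = None,
) -> FittedModel:
    """Fit the model of ``spec`` to a risk-interval table.

    The table needs event, team_id, player_id, either counting-process
    columns (gap_start_hours, gap_stop_hours) or duration_hours, and every
    covariate the spec references (2-SD standardized upstream where hazard
    ratios per 2 SD are wanted).

    ``fixed_variances`` pins named components ("team", "player") at given
    values instead of estimating them (0 is mapped to a numerically
    negligible floor); remaining components are still profiled.
    """
    control = control or FitControl()
    design = build_design(intervals, spec)
    p = design.X.shape[1]

    if spec.random == "none":
        groups, sizes = [], []
    elif spec.random == "player":
        groups, sizes = [design.player_codes], [len(design.player_levels)]
    else:
        groups = [design.team_codes, design.player_codes]
        sizes = [len(design.team_levels), len(design.player_levels)]
    engine = CoxEngine(design.X, design.stop, design.events, spec.ties, groups, start=design.start)

    warm = {"theta": np.zeros(engine.dim)}
    total_iter = [0]

    def solve_at(logvars, tol=None):
        pen = np.zeros(engine.dim)
        off = p
        for qs, lv in zip(sizes, logvars):
            pen[off : off + qs] = math.exp(-lv)
            off += qs
        theta, ppl, pl, grad_pen, info, it = _inner_newton(
            engine, pen, warm["theta"], tol or control.inner_tol, control.inner_maxiter
        )
        total_iter[0] += it
        warm["theta"] = theta
        ill = _laplace_ill(engine, p, pen, theta, ppl, info)
        # the Gaussian prior normalizer: ppl above omits -q/2 log(2*pi*s2)
        # and the Laplace constant +q/2 log(2*pi); they cancel exactly, and
        # the remaining -0.5*log|S| is inside the logdet(I + S K) form.
        return ill, theta, ppl, pl, grad_pen, info, pen

    n_var = len(sizes)
    level_names = [] if n_var == 0 else (["player"] if n_var == 1 else ["team", "player"])
    fixed_variances = fixed_variances or {}
    fixed_lv = {}
    for nm, v in fixed_variances.items():
        if nm not in level_names:
            raise KeyError(f"fixed variance {nm!r} not in random structure {spec.random!r}")
        # a pinned zero goes far below the search floor so the random
        # effects are numerically exactly zero (penalty ~ 1e13)
        fixed_lv[nm] = math.log(float(v)) if float(v) > 0 else -30.0
    free_names = [nm for nm in level_names if nm not in fixed_lv]

    def full_logvars(free_vals):
        it = iter(free_vals)
        return [fixed_lv[nm] if nm in fixed_lv else float(next(it)) for nm in level_names]

    n_free = len(free_names)
    if n_var == 0:
        logvar_hat = []
        ill, theta, ppl, pl, grad_pen, info, pen = solve_at([])
    elif n_free == 0:
        logvar_hat = full_logvars([])
        ill, theta, ppl, pl, grad_pen, info, pen = solve_at(logvar_hat)
    elif n_free == 1:
        res = optimize.minimize_scalar(
            lambda lv: -solve_at(full_logvars([lv]))[0],
            bounds=(LOGVAR_LO, LOGVAR_HI),
            method="bounded",
            options={"xatol": control.outer_xatol},
        )
        logvar_hat = full_logvars([float(res.x)])
        ill, theta, ppl, pl, grad_pen, info, pen = solve_at(logvar_hat)
    else:
        x0 = np.full(n_free, control.logvar_init)
        res = optimize.minimize(
            lambda lv: -solve_at(full_logvars(lv))[0],
            x0,
            method="Nelder-Mead",
            bounds=[(LOGVAR_LO, LOGVAR_HI)] * n_free,
            options={
                "xatol": control.outer_xatol,
                "fatol": control.outer_fatol,
                "maxfev": control.outer_maxfev,
            },
        )
        logvar_hat = full_logvars([float(v) for v in res.x])
        ill, theta, ppl, pl, grad_pen, info, pen = solve_at(logvar_hat)

    grad_norm = float(np.linalg.norm(grad_pen))
    converged = grad_norm < 1e-3 * (abs(ppl) + 1.0)

    # variance-component point estimates and (optional) SEs for free ones
    sigma2 = {"team": 0.0, "player": 0.0}
    se_sigma2 = {"team": float("nan"), "player": float("nan")}
    for nm, lv in zip(level_names, logvar_hat):
        sigma2[nm] = math.exp(lv)
    free_hat = [lv for nm, lv in zip(level_names, logvar_hat) if nm in free_names]
    if n_free and control.variance_se:
        h = 0.2
        ill0 = ill
        H = np.zeros((n_free, n_free))
        cache = {}

        def f_at(vec):
            key = tuple(round(float(v), 10) for v in vec)
            if key not in cache:
                cache[key] = solve_at(full_logvars(list(vec)))[0]
            return cache[key]

        for i in range(n_free):
            e = np.zeros(n_free)
            e[i] = h
            fp = f_at(np.clip(np.array(free_hat) + e, LOGVAR_LO, LOGVAR_HI))
            fm = f_at(np.clip(np.array(free_hat) - e, LOGVAR_LO, LOGVAR_HI))
            H[i, i] = (fp - 2 * ill0 + fm) / h**2
        for i in range(n_free):
            for j in range(i + 1, n_free):
                ei = np.zeros(n_free)
                ej = np.zeros(n_free)
                ei[i] = h
                ej[j] = h
                fpp = f_at(np.array(free_hat) + ei + ej)
                fpm = f_at(np.array(free_hat) + ei - ej)
                fmp = f_at(np.array(free_hat) - ei + ej)
                fmm = f_at(np.array(free_hat) - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
        try:
            cov_lv = np.linalg.inv(-H)
            for k, nm in enumerate(free_names):
                v = cov_lv[k, k]
                if v > 0:
                    # delta method: SE(s2) = s2 * SE(log s2)
                    se_sigma2[nm] = sigma2[nm] * math.sqrt(v)
        except np.linalg.LinAlgError:
            pass
        # re-solve at the optimum so the returned mode matches it
        ill, theta, ppl, pl, grad_pen, info, pen = solve_at(logvar_hat)

    # fixed-effect covariance from the penalized information at the mode
    A = info + np.diag(pen)
    try:
        vcov_full = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise FitError("singular penalized information at the mode")
    vcov_beta = vcov_full[:p, :p]
    se_beta = np.sqrt(np.maximum(np.diag(vcov_beta), 0.0))

    frailty_team, frailty_player = {}, {}
    off = p
    if spec.random == "team_player_nested":
        frailty_team = {
            lv: float(theta[off + j]) for j, lv in enumerate(design.team_levels)
        }
        off += len(design.team_levels)
    if spec.random in ("player", "team_player_nested"):
        frailty_player = {
            lv: float(theta[off + j]) for j, lv in enumerate(design.player_levels)
        }

    k = p + n_var
    aic = -2.0 * ill + 2.0 * k
    bic = -2.0 * ill + k * math.log(engine.n_events)

    return FittedModel(
        spec=spec,
        names=design.names,
        beta=theta[:p].copy(),
        se_beta=se_beta,
        vcov_beta=vcov_beta,
        sigma2_team=sigma2["team"],
        sigma2_player=sigma2["player"],
        se_sigma2_team=se_sigma2["team"],
        se_sigma2_player=se_sigma2["player"],
        frailty_team=frailty_team,
        frailty_player=frailty_player,
        loglik=float(ill),
        loglik_penalized=float(ppl),
        aic=float(aic),
        bic=float(bic),
        k_params=k,
        n_events=engine.n_events,
        n_intervals=design.n_intervals,
        iterations=total_iter[0],
        grad_norm=grad_norm,
        converged=bool(converged),
        design=design,
    )


# ---------------------------------------------------------------------------
# effect extraction and model comparison
# ---------------------------------------------------------------------------


def hr_per_2sd(model: FittedModel, covariate: str, conf: float = 0.90):
    """Hazard ratio with CI for a (2-SD standardized) model term.

    Returns (hr, ci_low, ci_high).  exp(beta) is the HR per 2-SD increase
    when the column was standardized with :func:`standardize_2sd`.
    """
    if covariate not in model.names:
        raise KeyError(f"covariate {covariate!r} not in model: {model.names}")
    b, se = model.coef(covariate)
    z = norm.ppf(0.5 + conf / 2.0)
    return math.exp(b), math.exp(b - z * se), math.exp(b + z * se)


def polynomial_select(
    intervals: pd.DataFrame,
    covariate: str,
    spec: ModelSpec,
    max_degree: int = 3,
    control: FitControl | None = None,
    aic_margin: float = 2.0,
):
    """Choose the polynomial degree (1..max_degree) for a covariate by AIC.

    Fits the spec with the covariate's degree set to each candidate and
    returns (chosen_degree, table, fits) where the table carries one row per
    degree (degree, loglik, aic, bic, k).

    Selection uses AIC with a parsimony margin: the chosen degree is the
    smallest whose AIC is within ``aic_margin`` of the minimum, mirroring
    the convention that only an AIC difference above 2 counts as
    substantial evidence of a better fit (``aic_margin=0`` recovers plain
    AIC minimization, which accepts a spurious extra degree with the usual
    ~16% chi-square(1) > 2 probability).
    """
    rows, fits = [], {}
    for d in range(1, max_degree + 1):
        terms = tuple(
            Term(t.name, d, t.categorical) if t.name == covariate else t
            for t in spec.terms
        )
        if covariate not in [t.name for t in spec.terms]:
            terms = terms + (Term(covariate, d),)
        m = fit(intervals, replace(spec, terms=terms), control)
        fits[d] = m
        rows.append(
            {"degree": d, "loglik": m.loglik, "aic": m.aic, "bic": m.bic, "k": m.k_params}
        )
    table = pd.DataFrame(rows)
    best = float(table["aic"].min())
    chosen = int(table.loc[table["aic"] <= best + aic_margin, "degree"].min())
    return chosen, table, fits


def hr_curve(
    model: FittedModel,
    covariate: str,
    grid,
    ref: float | None = None,
    conf: float = 0.90,
) -> pd.DataFrame:
    """HR(x) = exp(p(x) − p(ref)) along a grid, with delta-method CI bands.

    ``ref`` defaults to the covariate mean used to centre the polynomial
    basis (HR exactly 1 with zero-width CI there).  Grid points outside the
    observed data range are flagged as extrapolation.
    """
    if covariate in model.design.poly:
        info = model.design.poly[covariate]
        cols = info["cols"]
        center, scale, degree = info["center"], info["scale"], info["degree"]
        lo, hi = info["lo"], info["hi"]
    elif covariate in model.names:
        cols = [model.names.index(covariate)]
        center, scale, degree = 0.0, 1.0, 1
        lo, hi = -math.inf, math.inf
    else:
        raise KeyError(f"covariate {covariate!r} not in model")
    if ref is None:
        ref = center

    def basis(x):
        z = (x - center) / scale
        return np.array([z**d for d in range(1, degree + 1)])

    beta = model.beta[cols]
    V = model.vcov_beta[np.ix_(cols, cols)]
    z_crit = norm.ppf(0.5 + conf / 2.0)
    rows = []
    b_ref = basis(ref)
    for x in np.asarray(grid, dtype=float):
        g = basis(x) - b_ref
        lp = float(g @ beta)
        se = float(np.sqrt(max(g @ V @ g, 0.0)))
        rows.append(
            {
                "x": x,
                "hr": math.exp(lp),
                "ci_low": math.exp(lp - z_crit * se),
                "ci_high": math.exp(lp + z_crit * se),
                "extrapolated": bool(x < lo or x > hi),
            }
        )
    return pd.DataFrame(rows)


def interaction_fit(
    intervals: pd.DataFrame,
    spec: ModelSpec,
    quartile_col: str = "twelve_month_quartile",
    cont_col: str = "one_month_fge_2sd",
    conf: float = 0.90,
    control: FitControl | None = None,
):
    """Per-quartile effects of a continuous covariate (quartile interaction).

    The spec must contain ``cont_col`` as a linear term; the interaction
    pair is added here.  Returns (model, table): the table has one row per
    quartile with the within-reference-quartile HR (lowest quartile) and,
    for the other quartiles, the ratio of their within-quartile effect to
    the reference effect plus the combined within-quartile HR.  A quartile
    stratum with no events is an error.
    """
    z = norm.ppf(0.5 + conf / 2.0)
    ev_per_q = intervals.groupby(quartile_col)["event"].sum()
    if (ev_per_q == 0).any():
        empty = ev_per_q.index[ev_per_q == 0].tolist()
        raise ValueError(f"interaction_fit: no events in quartile stratum {empty}")
    ispec = replace(spec, interactions=spec.interactions + ((quartile_col, cont_col),))
    model = fit(intervals, ispec, control)
    info = model.design.interactions[(quartile_col, cont_col)]
    levels = info["levels"]
    i_cont = model.names.index(cont_col)
    b0 = model.beta[i_cont]
    se0 = model.se_beta[i_cont]
    rows = [
        {
            "quartile": levels[0],
            "kind": "within_reference",
            "hr": math.exp(b0),
            "ci_low": math.exp(b0 - z * se0),
            "ci_high": math.exp(b0 + z * se0),
            "hr_within": math.exp(b0),
        }
    ]
    for lv, ci in zip(levels[1:], info["prod_cols"]):
        bi = model.beta[ci]
        sei = model.se_beta[ci]
        var_sum = (
            model.vcov_beta[i_cont, i_cont]
            + model.vcov_beta[ci, ci]
            + 2 * model.vcov_beta[i_cont, ci]
        )
        rows.append(
            {
                "quartile": lv,
                "kind": "ratio_vs_reference",
                "hr": math.exp(bi),
                "ci_low": math.exp(bi - z * sei),
                "ci_high": math.exp(bi + z * sei),
                "hr_within": math.exp(b0 + bi),
                "hr_within_ci_low": math.exp(b0 + bi - z * math.sqrt(max(var_sum, 0.0))),
                "hr_within_ci_high": math.exp(b0 + bi + z * math.sqrt(max(var_sum, 0.0))),
            }
        )
    return model, pd.DataFrame(rows)


@dataclass
class VarianceTest:
    """Wald and boundary-mixture LR evidence for one variance component."""

    component: str
    sigma2: float
    se: float
    wald_z: float
    wald_p: float
    lr_stat: float | None = None
    lr_p: float | None = None


def _mixture_sf(stat: float, df: int) -> float:
    """P(mixture >= stat) for 50:50 chi2_0:chi2_df boundary mixtures.

    df 1: 0.5 chi2_0 + 0.5 chi2_1; df 2: 0.25 chi2_0 + 0.5 chi2_1 +
    0.25 chi2_2 (two components on the boundary).  The chi2_0 atom
    contributes nothing for stat >= 0, so the value at stat = 0 is 0.5
    (df 1) or 0.75 (df 2).
    """
    stat = max(stat, 0.0)
    if df == 0:
        return 1.0
    if df == 1:
        return 0.5 * float(chi2.sf(stat, 1))
    if df == 2:
        return 0.5 * float(chi2.sf(stat, 1)) + 0.25 * float(chi2.sf(stat, 2))
    raise ValueError("mixture defined for df 0, 1, 2")


def variance_test(
    model: FittedModel,
    component: str,
    reduced_model: FittedModel | None = None,
) -> VarianceTest:
    """Test a frailty variance component against zero.

    Wald: one-sided z = sigma2 / SE(sigma2) (p = 0.5 at the boundary).
    When the fit of the model without the component is supplied, a
    likelihood-ratio statistic 2 ΔLL with the 50:50 chi2_0:chi2_1 boundary
    mixture reference is reported alongside.
    """
    if component not in ("team", "player"):
        raise KeyError("component must be 'team' or 'player'")
    s2 = model.sigma2_team if component == "team" else model.sigma2_player
    se = model.se_sigma2_team if component == "team" else model.se_sigma2_player
    has = {"none": (), "player": ("player",), "team_player_nested": ("team", "player")}[
        model.spec.random
    ]
    if component not in has:
        raise KeyError(f"component {component!r} absent from random structure {model.spec.random!r}")
    if not np.isfinite(se) or se <= 0 or s2 <= 1e-8:
        wald_z, wald_p = 0.0, 0.5
    else:
        wald_z = s2 / se
        wald_p = float(norm.sf(wald_z))
    lr_stat = lr_p = None
    if reduced_model is not None:
        lr_stat = 2.0 * (model.loglik - reduced_model.loglik)
        lr_p = _mixture_sf(lr_stat, 1)
    return VarianceTest(component, s2, se, wald_z, wald_p, lr_stat, lr_p)


def compare_models(fits: dict, alpha: float = 0.10, delta_ic: float = 2.0):
    """LL/AIC/BIC comparison table plus pairwise boundary-mixture LR tests.

    ``fits`` maps model labels to FittedModel objects fitted on the same
    interval set and fixed-effect specification.  Flags: "substantial" when
    |ΔAIC| or |ΔBIC| exceeds ``delta_ic``; "significant" when the LR p-value
    is at or below ``alpha``.
    """
    items = list(fits.items())
    base = items[0][1]
    for _, m in items[1:]:
        if m.n_events != base.n_events or m.n_intervals != base.n_intervals:
            raise ValueError("compare_models: fits are not on the same interval set")
        if m.names != base.names:
            raise ValueError("compare_models: fits differ in fixed-effect specification")
    table = pd.DataFrame(
        {
            "model": [k for k, _ in items],
            "loglik": [m.loglik for _, m in items],
            "aic": [m.aic for _, m in items],
            "bic": [m.bic for _, m in items],
            "k": [m.k_params for _, m in items],
            "n_varcomp": [m.n_varcomp for _, m in items],
        }
    )
    best_aic = table["aic"].min()
    best_bic = table["bic"].min()
    table["delta_aic"] = table["aic"] - best_aic
    table["delta_bic"] = table["bic"] - best_bic

    rows = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (na, ma), (nb, mb) = items[i], items[j]
            if mb.n_varcomp < ma.n_varcomp:
                (na, ma), (nb, mb) = (nb, mb), (na, ma)
            df = mb.n_varcomp - ma.n_varcomp
            stat = 2.0 * (mb.loglik - ma.loglik)
            p = 1.0 if df == 0 else _mixture_sf(stat, df)
            rows.append(
                {
                    "reduced": na,
                    "full": nb,
                    "df": df,
                    "lr_stat": stat,
                    "p": p,
                    "significant": bool(p <= alpha) if df > 0 else False,
                    "substantial_aic": bool(abs(ma.aic - mb.aic) > delta_ic),
                    "substantial_bic": bool(abs(ma.bic - mb.bic) > delta_ic),
                }
            )
    return table, pd.DataFrame(rows)
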