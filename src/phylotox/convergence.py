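"""Convergent adaptive regimes under Ornstein-Uhlenbeck (Hansen) models.

A Hansen model describes a trait evolving by OU dynamics toward
branch-specific adaptive optima: a *regime painting* assigns every branch
one of a set of regimes, each regime ``r`` has an optimum ``theta_r``, and
all regimes share a selection strength ``alpha`` (per My) and diffusion
rate ``sigma^2`` per trait.  Under a painting the tip expectations are a
weighted mix of the optima along each root-to-tip path, ``E[y] = W theta``,
and the covariance depends only on alpha and the tree.

The stepwise search mirrors the SURFACE method: a *forward* phase greedily
adds regime shifts (each a new regime painted on a branch and inherited by
its descendants) while the corrected AIC improves, then a *backward* phase
greedily merges regimes — distant lineages collapsing into one regime is
the signature of convergence.  The summary metrics are

* ``k``  — regime placements (basal + shifts),
* ``k'`` — distinct regimes after collapse,
* ``delta_k = k - k'`` — how much convergence compresses the regime count,
* ``c``  — shifts toward regimes occupied by multiple placements.

Significance of the observed ``c`` (and ``delta_k``) comes from a
parametric bootstrap: traits are re-simulated under the fitted Hansen
model with every shift given its own regime (no true convergence), the
full search is re-run, and an add-one exceedance p-value is reported.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize_scalar

from .trees import Phylogeny, shared_time_matrix

__all__ = [
    "FitError",
    "RegimePainting",
    "ConvergenceMetrics",
    "HansenFit",
    "ForwardResult",
    "SurfaceResult",
    "NullDistribution",
    "ou_vcv",
    "hansen_weights",
    "fit_hansen",
    "aicc",
    "surface_forward",
    "surface_backward",
    "convergence_metrics",
    "simulate_null",
    "exceedance_pvalue",
]


class FitError(RuntimeError):
    """Numerical failure while fitting a Hansen model."""


# --------------------------------------------------------------------------
# paintings


@dataclass(frozen=True)
class RegimePainting:
    """Assignment of an adaptive regime to every branch of a tree.

    The painting is defined by the basal regime (carried by the root) and a
    set of *shift placements*: (node, regime) pairs meaning the branch above
    ``node`` switches to ``regime``, inherited by all descendant branches
    until overridden by a deeper shift.  A shift may target an existing
    regime (that is what convergence looks like after the backward phase),
    including the basal one (a reversion).
    """

    n_nodes: int
    shifts: tuple[tuple[int, int], ...] = ()
    basal: int = 0

    def __post_init__(self) -> None:
        nodes = [s[0] for s in self.shifts]
        if len(set(nodes)) != len(nodes):
            raise ValueError("multiple shifts on one branch")
        if 0 in nodes:
            raise ValueError("the root has no branch to shift on")
        object.__setattr__(self, "shifts", tuple(sorted(self.shifts)))

    @property
    def shift_nodes(self) -> tuple[int, ...]:
        return tuple(s[0] for s in self.shifts)

    @property
    def regime_ids(self) -> tuple[int, ...]:
        return tuple(sorted({self.basal, *(r for _, r in self.shifts)}))

    @property
    def n_distinct(self) -> int:
        return len(self.regime_ids)

    def node_regimes(self, tree: Phylogeny) -> np.ndarray:
        """Regime carried by the branch above each node (basal at the root)."""
        if tree.n_nodes != self.n_nodes:
            raise ValueError("painting does not match tree size")
        shift = dict(self.shifts)
        reg = np.empty(self.n_nodes, dtype=np.int64)
        for i in tree.preorder():
            i = int(i)
            if i == tree.root:
                reg[i] = self.basal
            else:
                reg[i] = shift.get(i, reg[tree.parent[i]])
        return reg

    def with_shift(self, node: int, regime: int) -> "RegimePainting":
        return RegimePainting(self.n_nodes, self.shifts + ((node, regime),), self.basal)

    def merged(self, a: int, b: int) -> "RegimePainting":
        """Collapse regime ``b`` into regime ``a`` everywhere."""
        shifts = tuple((n, a if r == b else r) for n, r in self.shifts)
        basal = a if self.basal == b else self.basal
        return RegimePainting(self.n_nodes, shifts, basal)

    def relabeled(self) -> "RegimePainting":
        """Renumber regimes contiguously from 0 (basal first)."""
        mapping = {self.basal: 0}
        for _, r in self.shifts:
            if r not in mapping:
                mapping[r] = len(mapping)
        shifts = tuple((n, mapping[r]) for n, r in self.shifts)
        return RegimePainting(self.n_nodes, shifts, 0)

    @classmethod
    def single_regime(cls, tree: Phylogeny) -> "RegimePainting":
        return cls(tree.n_nodes)


@dataclass(frozen=True)
class ConvergenceMetrics:
    """SURFACE convergence summary (k, k', delta_k, c)."""

    k: int
    k_prime: int
    delta_k: int
    c: int
    n_convergent_regimes: int


def convergence_metrics(painting: RegimePainting) -> ConvergenceMetrics:
    """Count regime placements, distinct regimes, and convergent shifts.

    The basal regime counts as one placement; a placement is convergent
    (contributes to ``c``) when its regime is reached by at least two
    placements, so a reversion to a shared basal regime is convergent with
    it.
    """
    placements = [painting.basal] + [r for _, r in painting.shifts]
    counts = Counter(placements)
    k = len(placements)
    k_prime = len(counts)
    c = sum(v for v in counts.values() if v >= 2)
    ncr = sum(1 for v in counts.values() if v >= 2)
    return ConvergenceMetrics(k=k, k_prime=k_prime, delta_k=k - k_prime, c=c,
                              n_convergent_regimes=ncr)


# --------------------------------------------------------------------------
# Hansen model likelihood


def _tree_mats(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    """Shared-time and patristic-distance matrices (tip order), cached."""
    if "ou_mats" not in tree._cache:
        Sv = shared_time_matrix(tree).to_numpy()
        d = np.diag(Sv)
        D = d[:, None] + d[None, :] - 2.0 * Sv
        tree._cache["ou_mats"] = (Sv, D)
    return tree._cache["ou_mats"]  # type: ignore[return-value]


def _ou_vcv_raw(tree: Phylogeny, alpha: float, sigma2: float) -> np.ndarray:
    Sv, D = _tree_mats(tree)
    if alpha * tree.height < 1e-8:
        return sigma2 * Sv
    return (sigma2 / (2.0 * alpha)) * np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * Sv))


def ou_vcv(
    tree: Phylogeny, alpha: float, sigma2: float, ultrametric_rtol: float = 1e-6
) -> pd.DataFrame:
    """Stationary OU covariance among tips.

    ``V_ij = sigma^2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha s_ij))``
    with ``d_ij`` the patristic distance and ``s_ij`` the shared
    root-to-MRCA time.  As ``alpha -> 0`` this approaches the Brownian
    covariance ``sigma^2 s_ij`` (evaluated directly when ``alpha * T`` is
    below 1e-8 to avoid cancellation).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if not tree.is_ultrametric(ultrametric_rtol):
        raise ValueError("ou_vcv requires an ultrametric tree")
    labels = tree.tip_labels
    return pd.DataFrame(_ou_vcv_raw(tree, alpha, sigma2), index=labels, columns=labels)


def _segments(tree: Phylogeny, painting: RegimePainting):
    """Per-branch path segments of every root-to-tip path, painting applied.

    Returns arrays (tip row, regime column, segment start, segment end),
    the per-tip depth vector, and the basal column index — everything
    :func:`hansen_weights` needs, with no per-alpha Python looping.
    """
    reg = painting.node_regimes(tree)
    regime_ids = list(painting.regime_ids)
    col = {r: j for j, r in enumerate(regime_ids)}
    depths = tree.depths()
    tips = tree.tip_indices
    rows, cols, t0s, t1s = [], [], [], []
    for k, tip in enumerate(tips):
        node = int(tip)
        while node != tree.root:
            rows.append(k)
            cols.append(col[reg[node]])
            t0s.append(depths[tree.parent[node]])
            t1s.append(depths[node])
            node = int(tree.parent[node])
    return (
        np.array(rows),
        np.array(cols),
        np.array(t0s),
        np.array(t1s),
        depths[tips],
        col[painting.basal],
        regime_ids,
    )


def _weights_raw(segs, alpha: float) -> np.ndarray:
    rows, cols, t0s, t1s, tip_depth, basal_col, regime_ids = segs
    W = np.zeros((tip_depth.size, len(regime_ids)))
    Ti = tip_depth[rows]
    np.add.at(
        W, (rows, cols), np.exp(-alpha * (Ti - t1s)) - np.exp(-alpha * (Ti - t0s))
    )
    W[:, basal_col] += np.exp(-alpha * tip_depth)
    return W


def hansen_weights(
    tree: Phylogeny, painting: RegimePainting, alpha: float
) -> pd.DataFrame:
    """Tip x regime optimum weights of the Hansen model, rows summing to 1.

    For tip ``i`` at depth ``T_i``, a path segment of regime ``r`` running
    from time ``t0`` to ``t1`` contributes
    ``exp(-alpha (T_i - t1)) - exp(-alpha (T_i - t0))`` to column ``r``;
    the basal column additionally receives ``exp(-alpha T_i)`` (the root
    state is absorbed into the basal optimum).
    """
    if alpha <= 0:
        raise ValueError("hansen_weights requires alpha > 0")
    segs = _segments(tree, painting)
    return pd.DataFrame(
        _weights_raw(segs, alpha), index=tree.tip_labels, columns=segs[6]
    )


@dataclass
class HansenFit:
    """Per-trait OU parameters and optima under a regime painting.

    ``alpha`` and ``sigma2`` are fit per trait but shared across regimes;
    ``theta`` is the regime x trait table of optima.  ``loglik`` is the
    joint Gaussian log-likelihood across traits and ``n_params = m * (2 +
    k')`` with ``k'`` the number of distinct regimes in the painting.
    """

    painting: RegimePainting
    alpha: np.ndarray
    sigma2: np.ndarray
    theta: pd.DataFrame
    loglik: float
    n_params: int
    n_obs: int
    aicc: float
    aic: float

    def score(self, criterion: str = "aicc") -> float:
        return self.aicc if criterion == "aicc" else self.aic


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Small-sample corrected AIC: -2 lnL + 2p + 2p(p+1)/(n-p-1)."""
    if n_obs - n_params - 1 <= 0:
        raise ValueError("AICc undefined: need n - p - 1 > 0")
    p = n_params
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n_obs - n_params - 1)


_BIG = 1e10


def _chol_cache(tree: Phylogeny, alpha: float):
    """Cholesky of the unit-rate OU covariance, cached per (tree, alpha)."""
    cache = tree._cache.setdefault("ou_chol", {})
    if alpha not in cache:
        if len(cache) > 512:
            cache.clear()
        try:
            cache[alpha] = np.linalg.cholesky(_ou_vcv_raw(tree, alpha, 1.0))
        except np.linalg.LinAlgError:
            cache[alpha] = None
    return cache[alpha]


def _profile_loglik(y: np.ndarray, tree: Phylogeny, segs, alpha: float):
    """Profile lnL over (theta, sigma2) at fixed alpha for one trait."""
    n = y.size
    L = _chol_cache(tree, alpha)
    if L is None:
        return -_BIG, None, None
    if alpha > 0:
        W = _weights_raw(segs, alpha)
    else:
        W = np.ones((n, 1))
    Wt = solve_triangular(L, W, lower=True, check_finite=False)
    yt = solve_triangular(L, y, lower=True, check_finite=False)
    theta, _, rank, _ = np.linalg.lstsq(Wt, yt, rcond=None)
    if rank < W.shape[1]:
        return -_BIG, None, None
    r = yt - Wt @ theta
    s2 = max(float(r @ r) / n, 1e-12)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * np.log(2.0 * np.pi * s2) + logdetV + n)
    return ll, theta, s2


def fit_hansen(
    traits: pd.DataFrame,
    tree: Phylogeny,
    painting: RegimePainting | None = None,
    fixed_alpha: float | None = None,
    alpha_bounds: tuple[float, float] | None = None,
    criterion: str = "aicc",
) -> HansenFit:
    """Fit a Hansen model: per-trait (alpha, sigma2) and per-regime optima.

    For each trait, alpha is optimized by bounded scalar search on a log
    scale (default bounds 1e-6/T .. 100/T with T the tree height); at each
    alpha the optima come from generalized least squares and sigma2 from
    the profiled residual quadratic form.  ``fixed_alpha`` skips the search
    (useful for evaluating the Brownian limit).
    """
    painting = painting or RegimePainting.single_regime(tree)
    if not tree.is_ultrametric():
        raise FitError("the Hansen machinery requires an ultrametric tree")
    tip_order = tree.tip_labels
    missing = set(tip_order) - set(traits.index)
    if missing:
        raise FitError(f"traits missing for tips: {sorted(missing)}")
    Y = traits.loc[tip_order].to_numpy(dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = Y.shape
    T = tree.height
    lo, hi = alpha_bounds or (1e-6 / T, 100.0 / T)
    segs = _segments(tree, painting)

    regime_ids = list(painting.regime_ids)
    alphas = np.empty(m)
    sig2 = np.empty(m)
    thetas = np.zeros((len(regime_ids), m))
    total_ll = 0.0
    for t in range(m):
        y = Y[:, t]
        if fixed_alpha is not None:
            a_hat = float(fixed_alpha)
        else:
            res = minimize_scalar(
                lambda u: -_profile_loglik(y, tree, segs, float(np.exp(u)))[0],
                bounds=(np.log(lo), np.log(hi)),
                method="bounded",
                options={"xatol": 1e-2},
            )
            if not res.success:  # pragma: no cover - bounded search rarely fails
                raise FitError(f"alpha search failed for trait {t}: {res.message}")
            a_hat = float(np.exp(res.x))
        ll, theta, s2 = _profile_loglik(y, tree, segs, a_hat)
        if theta is None:
            raise FitError(
                f"singular Hansen design for trait {t} (collinear regime weights)"
            )
        alphas[t] = a_hat
        sig2[t] = s2
        if fixed_alpha is not None and fixed_alpha == 0:
            thetas[regime_ids.index(painting.basal), t] = theta[0]
        else:
            thetas[:, t] = theta
        total_ll += ll

    p = m * (2 + len(regime_ids))
    fit_aicc = aicc(total_ll, p, n)
    fit_aic = -2.0 * total_ll + 2.0 * p
    return HansenFit(
        painting=painting,
        alpha=alphas,
        sigma2=sig2,
        theta=pd.DataFrame(thetas, index=regime_ids, columns=list(traits.columns)),
        loglik=total_ll,
        n_params=p,
        n_obs=n,
        aicc=fit_aicc,
        aic=fit_aic,
    )


# --------------------------------------------------------------------------
# stepwise search


@dataclass
class ForwardResult:
    painting: RegimePainting
    fit: HansenFit
    trace: list[dict]  # one entry per accepted step: shift_node, score


@dataclass
class SurfaceResult:
    painting: RegimePainting
    fit: HansenFit
    metrics: ConvergenceMetrics
    forward_trace: list[dict]
    backward_trace: list[dict]
    regime_members: dict[int, tuple[str, ...]]

    def to_dict(self) -> dict:
        return {
            "k": self.metrics.k,
            "k_prime": self.metrics.k_prime,
            "delta_k": self.metrics.delta_k,
            "c": self.metrics.c,
            "n_convergent_regimes": self.metrics.n_convergent_regimes,
            "aicc": self.fit.aicc,
            "loglik": self.fit.loglik,
            "shifts": {int(n): int(r) for n, r in self.painting.shifts},
            "forward_trace": self.forward_trace,
            "backward_trace": self.backward_trace,
            "regime_members": {int(r): list(v) for r, v in self.regime_members.items()},
        }


def _try_fit(traits, tree, painting, criterion) -> HansenFit | None:
    try:
        return fit_hansen(traits, tree, painting, criterion=criterion)
    except (FitError, ValueError):
        return None


def surface_forward(
    traits: pd.DataFrame,
    tree: Phylogeny,
    threshold: float = 0.0,
    criterion: str = "aicc",
    max_steps: int | None = None,
) -> ForwardResult:
    """Greedy forward phase: add regime shifts while the AICc improves.

    Each step evaluates placing a brand-new regime on every branch that is
    not already a shift point (the shift is inherited down the tree until
    overridden), accepts the single best placement if it improves the score
    by more than ``threshold``, and repeats.  Candidates are visited in
    preorder, so ties resolve to the earliest branch deterministically.
    """
    painting = RegimePainting.single_regime(tree)
    fit = fit_hansen(traits, tree, painting, criterion=criterion)
    trace = [{"step": 0, "shift_node": None, "score": fit.score(criterion)}]
    step = 0
    preorder = [int(i) for i in tree.preorder() if int(i) != tree.root]
    while max_steps is None or step < max_steps:
        taken = set(painting.shift_nodes)
        new_regime = max(painting.regime_ids) + 1
        best: tuple[float, int, HansenFit] | None = None
        for node in preorder:
            if node in taken:
                continue
            cand_fit = _try_fit(
                traits, tree, painting.with_shift(node, new_regime), criterion
            )
            if cand_fit is None:
                continue
            s = cand_fit.score(criterion)
            if best is None or s < best[0]:
                best = (s, node, cand_fit)
        if best is None or fit.score(criterion) - best[0] <= threshold:
            break
        fit = best[2]
        painting = fit.painting
        step += 1
        trace.append({"step": step, "shift_node": best[1], "score": best[0]})
    return ForwardResult(painting=painting, fit=fit, trace=trace)


def surface_backward(
    traits: pd.DataFrame,
    tree: Phylogeny,
    painting: RegimePainting | ForwardResult,
    threshold: float = 0.0,
    criterion: str = "aicc",
) -> SurfaceResult:
    """Greedy backward phase: collapse regime pairs while the AICc improves.

    Every unordered pair of distinct regimes is evaluated as a single
    merged regime; the best merge is accepted if it improves the score by
    more than ``threshold``, and the loop repeats.  Regimes that survive
    with multiple placements are the convergent ones.
    """
    forward_trace: list[dict] = []
    if isinstance(painting, ForwardResult):
        forward_trace = painting.trace
        fit = painting.fit
        painting = painting.painting
    else:
        fit = fit_hansen(traits, tree, painting, criterion=criterion)
    trace: list[dict] = [{"merge": None, "score": fit.score(criterion)}]
    while True:
        ids = painting.regime_ids
        best: tuple[float, tuple[int, int], HansenFit] | None = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                cand_fit = _try_fit(
                    traits, tree, painting.merged(ids[ai], ids[bi]), criterion
                )
                if cand_fit is None:
                    continue
                s = cand_fit.score(criterion)
                if best is None or s < best[0]:
                    best = (s, (ids[ai], ids[bi]), cand_fit)
        if best is None or fit.score(criterion) - best[0] <= threshold:
            break
        fit = best[2]
        painting = fit.painting
        trace.append({"merge": best[1], "score": best[0]})

    final = painting.relabeled()
    reg = final.node_regimes(tree)
    members: dict[int, tuple[str, ...]] = {}
    for r in final.regime_ids:
        members[r] = tuple(
            tree.labels[i] for i in tree.tip_indices if reg[i] == r
        )
    # refit on the relabeled painting (identical model, canonical ids)
    fit = fit_hansen(traits, tree, final, criterion=criterion)
    return SurfaceResult(
        painting=final,
        fit=fit,
        metrics=convergence_metrics(final),
        forward_trace=forward_trace,
        backward_trace=trace,
        regime_members=members,
    )


# --------------------------------------------------------------------------
# parametric bootstrap null


@dataclass
class NullDistribution:
    c: np.ndarray
    delta_k: np.ndarray
    observed_c: int | None
    observed_delta_k: int | None
    p_c: float | None
    p_delta_k: float | None

    @property
    def n_sim(self) -> int:
        return self.c.size


def exceedance_pvalue(null_values, observed) -> float:
    """Add-one exceedance p-value: (#{null >= observed} + 1) / (n + 1)."""
    null_values = np.asarray(null_values)
    return float((np.sum(null_values >= observed) + 1) / (null_values.size + 1))


def _simulate_hansen(
    fit: HansenFit,
    tree: Phylogeny,
    rng: np.random.Generator,
    sample_optima: bool = False,
) -> pd.DataFrame:
    """One draw of tip traits under a fitted Hansen model.

    With ``sample_optima`` each regime's optimum is redrawn from a normal
    distribution matching the location and spread of the fitted optima, so
    the simulated landscape keeps the number and placement of shifts but
    its regimes are distinct with probability one — the no-true-convergence
    null of the stepwise search.
    """
    tips = tree.tip_labels
    segs = _segments(tree, fit.painting)
    theta = fit.theta.to_numpy(copy=True)
    if sample_optima:
        mu = theta.mean(axis=0)
        sd = theta.std(axis=0, ddof=1) if theta.shape[0] > 1 else np.ones_like(mu)
        theta = mu + sd * rng.standard_normal(theta.shape)
    cols = {}
    for t, name in enumerate(fit.theta.columns):
        V = fit.sigma2[t] * _ou_vcv_raw(tree, fit.alpha[t], 1.0)
        W = _weights_raw(segs, fit.alpha[t])
        mean = W @ theta[:, t]
        L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / len(tips) * np.eye(len(tips)))
        cols[name] = mean + L @ rng.standard_normal(len(tips))
    return pd.DataFrame(cols, index=tips)


def simulate_null(
    fit: HansenFit,
    tree: Phylogeny,
    n_sim: int = 500,
    seed: int = 0,
    observed: ConvergenceMetrics | SurfaceResult | None = None,
    threshold: float = 0.0,
    criterion: str = "aicc",
) -> NullDistribution:
    """Null distribution of the convergence metrics by parametric bootstrap.

    Traits are simulated under the fitted Hansen model with every shift
    assigned its own unique regime and a freshly sampled optimum (a
    landscape with the same number and placement of shifts but no true
    convergence); the full forward+backward search is re-run on each
    simulated data set.  P-values use the add-one convention, so they are
    never exactly zero.
    """
    if n_sim < 50:
        raise ValueError("need n_sim >= 50 for a usable null")
    # the generator must lack true convergence: every shift its own regime
    ids = [r for _, r in fit.painting.shifts]
    if len(set(ids)) != len(ids) or fit.painting.basal in ids:
        raise FitError(
            "simulate_null needs a fit whose shifts all target unique regimes "
            "(pass the forward-phase fit, whose regimes are new by construction)"
        )
    rng = np.random.default_rng(seed)
    c_vals = np.empty(n_sim, dtype=int)
    dk_vals = np.empty(n_sim, dtype=int)
    for i in range(n_sim):
        ysim = _simulate_hansen(fit, tree, rng, sample_optima=True)
        fwd = surface_forward(ysim, tree, threshold=threshold, criterion=criterion)
        res = surface_backward(ysim, tree, fwd, threshold=threshold, criterion=criterion)
        c_vals[i] = res.metrics.c
        dk_vals[i] = res.metrics.delta_k
    obs_c = obs_dk = p_c = p_dk = None
    if observed is not None:
        met = observed.metrics if isinstance(observed, SurfaceResult) else observed
        obs_c, obs_dk = met.c, met.delta_k
        p_c = exceedance_pvalue(c_vals, obs_c)
        p_dk = exceedance_pvalue(dk_vals, obs_dk)
    return NullDistribution(
        c=c_vals,
        delta_k=dk_vals,
        observed_c=obs_c,
        observed_delta_k=obs_dk,
        p_c=p_c,
        p_delta_k=p_dk,
    )
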