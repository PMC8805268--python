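"""Bayesian semi-parametric gene-gene interaction model with spike-and-slab
selection.

The response is modelled as a sum of ``k`` sparse additive functions,

    Y_i ~ Normal(f(X_i), sigma^2),    f = sum_h f^(h),

where each f^(h) contains natural-spline main terms ``Xt_j beta_j`` for the
genes active in function h and elementwise-product interaction terms
``Xt_j1 * Xt_j2 beta_j1j2`` for every active pair. Gene j enters function h
through a binary indicator zeta_jh; coefficients of function h get a
spike-and-slab prior — a point mass at zero unless all genes of the term are
active, and a zero-mean Gaussian slab with diagonal covariance (empirical
Bayes scale) otherwise. Because a pair interacts only when both genes are
active in a common function, strong heredity holds by construction and the
pairwise Posterior Inclusion Probability can never exceed either marginal
one.

Inclusion indicators are updated by Gibbs sampling with the function's
coefficients integrated out analytically (conjugate Gaussian marginal
likelihood), which mixes far better than joint Metropolis moves; the
coefficients, inclusion probabilities tau_h, residual variance and slab
scale are then refreshed by direct conditional draws.

PIPs are chain-frequency estimates: marginal PIP(j) is the fraction of
retained sweeps where gene j is active in at least one function, and
interaction PIP(j1, j2) the fraction where both are active in a common one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .containers import GeneSummary, PhenotypeVector
from .errors import ParameterError

__all__ = [
    "BasisExpansion",
    "ModelConfig",
    "PosteriorSummary",
    "build_basis",
    "natural_spline_basis",
    "fit",
    "select_effects",
]


# ---------------------------------------------------------------------------
# natural cubic spline basis


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form, no intercept).

    With K knots the returned basis has K-1 columns: the identity and K-2
    curvature terms ``d_k(x) - d_{K-1}(x)`` with

        d_k(x) = [(x - t_k)_+^3 - (x - t_K)_+^3] / (t_K - t_k),

    linear beyond the boundary knots. The spanned space (plus a constant)
    is the standard natural cubic spline space on those knots.
    """
    x = np.asarray(x, float)
    t = np.sort(np.asarray(knots, float))
    K = t.size
    if K < 2:
        raise ParameterError("need at least 2 knots")

    def d(k: int) -> np.ndarray:
        num = np.clip(x - t[k], 0, None) ** 3 - np.clip(x - t[K - 1], 0, None) ** 3
        return num / (t[K - 1] - t[k])

    cols = [x]
    if K > 2:
        dlast = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dlast)
    return np.column_stack(cols)


@dataclass
class BasisExpansion:
    """Basis-evaluated gene summary: the n x d design block for one gene."""

    gene_id: str
    design: np.ndarray
    d: int

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, float)
        if self.design.ndim != 2 or self.design.shape[1] != self.d or self.d < 1:
            raise ValueError("basis design shape mismatch")
        if not np.isfinite(self.design).all():
            raise ValueError("non-finite basis values")


def build_basis(summary: GeneSummary, d: int = 2) -> BasisExpansion:
    """Natural-spline basis of a gene summary's standardized scores.

    ``d = 1`` returns the standardized scores themselves (a linear term);
    ``d >= 2`` evaluates a natural cubic spline with ``d`` basis functions,
    knots at evenly spaced quantiles of the scores (boundary knots at the
    extremes). Columns are standardized so coefficient scales are
    comparable.
    """
    if d < 1:
        raise ParameterError("basis dimension d must be >= 1")
    s = np.asarray(summary.scores, float)
    if s.size <= d:
        raise ParameterError("need more samples than basis functions")
    sd = s.std()
    if sd == 0:
        raise ParameterError(f"gene {summary.gene_id}: constant scores")
    z = (s - s.mean()) / sd
    if d == 1:
        design = z[:, None]
    else:
        knots = np.quantile(z, np.linspace(0, 1, d + 1))
        if np.unique(knots).size != knots.size:
            raise ParameterError(f"gene {summary.gene_id}: degenerate knots")
        design = natural_spline_basis(z, knots)
        design = (design - design.mean(axis=0)) / design.std(axis=0)
    return BasisExpansion(summary.gene_id, design, d)


# ---------------------------------------------------------------------------
# model configuration and posterior summary


@dataclass
class ModelConfig:
    """Sampler settings.

    k: number of additive functions (large enough to hold all effects).
    d: basis functions per gene (1 = linear).
    n_iter / n_burn / thin: Gibbs schedule; retained draws =
        (n_iter - n_burn) / thin.
    tau_a, tau_b: Beta prior on each function's inclusion probability
        tau_h; tau_b = None uses the number of genes p (sparsity scales
        with dimension).
    slab_scale: lower bound on the slab-to-noise variance ratio; the slab
        variance is ``max(slab_scale * sigma2, EB, slab_floor)`` where EB
        is the mean squared active coefficient. Anchoring the slab to
        sigma^2 keeps the Occam penalty of an extra column meaningful
        (with an absolute floor alone the slab can collapse, making
        inclusion prior-driven); the default 0.1 matches the scale of
        standardized coefficients whose terms explain up to ~10% of the
        trait variance, the regime gene-level effects live in.
    slab_floor: absolute lower bound for the slab variance.
    pair_moves: joint Metropolis pair-flip proposals per function per
        sweep. Single-indicator Gibbs moves cannot easily reach a pure
        interaction (either gene alone adds no fit), so pairs of
        indicators are also proposed together.
    heredity: enforce that no function's active set is contained in
        another's (removes redundant functions).
    """

    k: int = 10
    d: int = 2
    n_iter: int = 10000
    n_burn: int = 5000
    thin: int = 5
    seed: int = 0
    tau_a: float = 1.0
    tau_b: float | None = None
    slab_scale: float = 0.1
    slab_floor: float = 1e-6
    pair_moves: int = 10
    sigma_a: float = 1e-3
    sigma_b: float = 1e-3
    heredity: bool = True

    def __post_init__(self) -> None:
        if self.k < 1 or self.d < 1:
            raise ParameterError("k and d must be >= 1")
        if not 0 <= self.n_burn < self.n_iter:
            raise ParameterError("need 0 <= n_burn < n_iter")
        if self.thin < 1:
            raise ParameterError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Marginal and pairwise PIPs plus retained-sample traces."""

    gene_ids: list[str]
    marginal_pip: np.ndarray
    interaction_pip: np.ndarray
    sigma2_trace: np.ndarray
    marginal_trace: np.ndarray      # retained x p bool
    interaction_trace: np.ndarray   # retained x p x p bool
    n_retained: int
    config: ModelConfig
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = len(self.gene_ids)
        if self.marginal_pip.shape != (p,) or self.interaction_pip.shape != (p, p):
            raise ValueError("PIP shape mismatch")
        if (self.marginal_pip < 0).any() or (self.marginal_pip > 1).any():
            raise ValueError("PIPs outside [0, 1]")


# ---------------------------------------------------------------------------
# sampler internals


class _Design:
    """Caches per-gene basis blocks and lazy pairwise product blocks."""

    def __init__(self, bases: list[np.ndarray]):
        self.main = bases
        self.p = len(bases)
        self.n, self.d = bases[0].shape
        self._pairs: dict[tuple[int, int], np.ndarray] = {}
        self._sets: dict[tuple[int, ...], tuple[np.ndarray, np.ndarray]] = {}

    def pair(self, j1: int, j2: int) -> np.ndarray:
        key = (min(j1, j2), max(j1, j2))
        blk = self._pairs.get(key)
        if blk is None:
            a, b = self.main[key[0]], self.main[key[1]]
            blk = np.einsum("ni,nj->nij", a, b).reshape(self.n, self.d * self.d)
            self._pairs[key] = blk
        return blk

    def matrix(self, active: tuple[int, ...]) -> np.ndarray | None:
        if not active:
            return None
        return self.spectral(active)[0]

    def spectral(self, active: tuple[int, ...]):
        """Design D and eigendecomposition of its Gram D^T D, cached.

        The Gram matrix of an active set never changes during a run, so its
        spectrum is computed once; every marginal-likelihood and posterior
        draw then reduces to vectorized spectral arithmetic.
        """
        cached = self._sets.get(active)
        if cached is None:
            blocks = [self.main[j] for j in active]
            blocks += [self.pair(a, b) for a, b in combinations(active, 2)]
            d = np.hstack(blocks)
            lam, q = np.linalg.eigh(d.T @ d)
            lam = np.clip(lam, 0.0, None)
            cached = (d, q, lam)
            if len(self._sets) < 8192:
                self._sets[active] = cached
        return cached


def _log_ml(
    design: "_Design", active: tuple[int, ...], r: np.ndarray, sigma2: float, v: float
) -> float:
    """Log marginal likelihood of r ~ N(0, sigma2 I + v D D^T) for the
    active set's design D, with constant terms shared by all sets dropped."""
    if not active:
        return 0.0
    d, q, lam = design.spectral(active)
    w = q.T @ (d.T @ r)
    c = sigma2 / v
    # log|I + (v/sigma2) G| = sum log((lam + c) / c)
    logdet = float(np.log((lam + c) / c).sum())
    quad = float((w * w / (lam + c)).sum()) / sigma2
    return -0.5 * logdet + 0.5 * quad


def _violates_heredity(sets: list[set], h: int, proposed: set) -> bool:
    """True if replacing sets[h] by ``proposed`` nests one nonempty active
    set inside another (redundant-function exclusion)."""
    for m, other in enumerate(sets):
        if m == h:
            continue
        if proposed and proposed <= other:
            return True
        if other and other <= proposed:
            return True
    return False


def fit(
    summaries: list[GeneSummary], y: PhenotypeVector, cfg: ModelConfig
) -> PosteriorSummary:
    """Run the spike-and-slab Gibbs sampler and summarise inclusion.

    Gene order is canonicalized internally (sorted by gene id) so that the
    chain — and therefore every PIP — depends only on the data, not on the
    order in which summaries are passed; results are reported in the input
    order.
    """
    if len(summaries) < 2:
        raise ParameterError("need at least 2 gene summaries")
    gene_ids = [s.gene_id for s in summaries]
    if len(set(gene_ids)) != len(gene_ids):
        raise ParameterError("duplicate gene ids")
    for s in summaries:
        if s.sample_ids != y.sample_ids:
            raise ParameterError(f"gene {s.gene_id} not aligned with phenotype")

    order = sorted(range(len(gene_ids)), key=lambda i: gene_ids[i])
    inv = np.argsort(order)
    sorted_summaries = [summaries[i] for i in order]

    rng = np.random.default_rng(cfg.seed)
    p = len(sorted_summaries)
    bases = [build_basis(s, cfg.d).design for s in sorted_summaries]
    design = _Design(bases)
    n = design.n
    yv = np.asarray(y.values, float)
    y_center = yv - yv.mean()
    if not np.isfinite(y_center).all():
        raise ParameterError("phenotype contains non-finite values")

    tau_b = float(p) if cfg.tau_b is None else cfg.tau_b
    k = cfg.k
    zeta = np.zeros((k, p), dtype=bool)
    tau = np.full(k, cfg.tau_a / (cfg.tau_a + tau_b))
    sigma2 = float(np.var(y_center)) or 1.0
    slab_v = max(cfg.slab_floor, cfg.slab_scale * sigma2)
    fits = np.zeros((k, n))
    coefs: list[np.ndarray] = [np.empty(0)] * k
    total_fit = np.zeros(n)

    n_ret = (cfg.n_iter - cfg.n_burn + cfg.thin - 1) // cfg.thin
    marg_trace = np.zeros((n_ret, p), dtype=bool)
    pair_trace = np.zeros((n_ret, p, p), dtype=bool)
    sigma2_trace = np.zeros(n_ret)
    ret = 0

    for sweep in range(cfg.n_iter):
        active_sets = [set(np.flatnonzero(zeta[m])) for m in range(k)]
        for h in range(k):
            r = y_center - total_fit + fits[h]
            cur_set = active_sets[h]
            cur_ml = _log_ml(design, tuple(sorted(cur_set)), r, sigma2, slab_v)
            log_tau_odds = math.log(tau[h]) - math.log1p(-tau[h])
            for j in range(p):
                cur = j in cur_set
                alt_set = cur_set - {j} if cur else cur_set | {j}
                if cfg.heredity and _violates_heredity(active_sets, h, alt_set):
                    continue
                alt_ml = _log_ml(design, tuple(sorted(alt_set)), r, sigma2, slab_v)
                ml_incl = cur_ml if cur else alt_ml
                ml_excl = alt_ml if cur else cur_ml
                log_odds = (ml_incl - ml_excl) + log_tau_odds
                p_incl = 1.0 / (1.0 + math.exp(-max(-700.0, min(700.0, log_odds))))
                new = rng.random() < p_incl
                if new != cur:
                    zeta[h, j] = new
                    cur_set = alt_set
                    active_sets[h] = cur_set
                    cur_ml = alt_ml

            # joint pair flips (Metropolis): reach pure interactions
            for _ in range(cfg.pair_moves):
                j1 = int(rng.integers(p))
                j2 = int(rng.integers(p - 1))
                if j2 >= j1:
                    j2 += 1
                prop_set = cur_set ^ {j1, j2}
                if cfg.heredity and _violates_heredity(active_sets, h, prop_set):
                    continue
                delta_s = len(prop_set) - len(cur_set)
                prop_ml = _log_ml(design, tuple(sorted(prop_set)), r, sigma2, slab_v)
                log_acc = (prop_ml - cur_ml) + delta_s * log_tau_odds
                if math.log(rng.random()) < log_acc:
                    for j in (j1, j2):
                        zeta[h, j] = not zeta[h, j]
                    cur_set = prop_set
                    active_sets[h] = cur_set
                    cur_ml = prop_ml

            # refresh coefficients of function h
            active = tuple(np.flatnonzero(zeta[h]))
            if not active:
                fits[h] = 0.0
                coefs[h] = np.empty(0)
            else:
                d_mat, q, lam = design.spectral(active)
                prec_eig = lam / sigma2 + 1.0 / slab_v
                w = q.T @ (d_mat.T @ r) / sigma2
                mean = w / prec_eig
                z = rng.standard_normal(lam.size)
                draw = q @ (mean + z / np.sqrt(prec_eig))
                coefs[h] = draw
                fits[h] = d_mat @ draw
            total_fit = fits.sum(axis=0)

            s_h = int(zeta[h].sum())
            draw = rng.beta(cfg.tau_a + s_h, tau_b + p - s_h)
            tau[h] = min(max(draw, 1e-12), 1.0 - 1e-12)  # keep log-odds finite

        resid = y_center - total_fit
        rss = float(resid @ resid)
        sigma2 = 1.0 / rng.gamma(cfg.sigma_a + n / 2.0, 1.0 / (cfg.sigma_b + rss / 2.0))

        eb = 0.0
        if any(c.size for c in coefs):
            all_coef = np.concatenate([c for c in coefs if c.size])
            eb = float(np.mean(all_coef**2))
        slab_v = max(cfg.slab_floor, cfg.slab_scale * sigma2, eb)

        if sweep >= cfg.n_burn and (sweep - cfg.n_burn) % cfg.thin == 0:
            marg = zeta.any(axis=0)
            marg_trace[ret] = marg
            for h in range(k):
                act = np.flatnonzero(zeta[h])
                for a, b in combinations(act, 2):
                    pair_trace[ret, a, b] = True
                    pair_trace[ret, b, a] = True
            sigma2_trace[ret] = sigma2
            ret += 1

    marg_trace = marg_trace[:ret]
    pair_trace = pair_trace[:ret]
    sigma2_trace = sigma2_trace[:ret]

    marginal_pip = marg_trace.mean(axis=0)
    interaction_pip = pair_trace.mean(axis=0)
    np.fill_diagonal(interaction_pip, 0.0)

    # report in the caller's gene order
    marginal_pip = marginal_pip[inv]
    interaction_pip = interaction_pip[np.ix_(inv, inv)]
    marg_trace = marg_trace[:, inv]
    pair_trace = pair_trace[:, :, inv][:, inv, :]

    diagnostics = {"geweke_sigma2": _geweke(sigma2_trace)}
    return PosteriorSummary(
        gene_ids=gene_ids,
        marginal_pip=marginal_pip,
        interaction_pip=interaction_pip,
        sigma2_trace=sigma2_trace,
        marginal_trace=marg_trace,
        interaction_trace=pair_trace,
        n_retained=ret,
        config=cfg,
        diagnostics=diagnostics,
    )


def _geweke(trace: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score of a scalar trace (nan if too short)."""
    n = trace.size
    if n < 20:
        return float("nan")
    a = trace[: max(2, int(first * n))]
    b = trace[-max(2, int(last * n)):]
    denom = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    return float((a.mean() - b.mean()) / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# effect selection


def select_effects(
    ps: PosteriorSummary,
    threshold: float = 0.0,
    strict: bool = False,
    min_count: int = 2,
) -> tuple[list[tuple[str, float]], list[tuple[str, str, float]]]:
    """Genes and gene pairs with PIP above threshold, sorted by PIP.

    With finite chains, "PIP > 0" means "included in at least one retained
    sample"; ``strict`` instead requires at least ``min_count`` inclusion
    events (PIP >= min_count / n_retained).
    """
    if not 0 <= threshold < 1:
        raise ParameterError("threshold must be in [0, 1)")
    floor = min_count / ps.n_retained if strict else 0.0
    genes = [
        (g, float(pip))
        for g, pip in zip(ps.gene_ids, ps.marginal_pip)
        if pip > threshold and pip >= floor
    ]
    genes.sort(key=lambda t: (-t[1], t[0]))
    pairs = []
    p = len(ps.gene_ids)
    for i in range(p):
        for j in range(i + 1, p):
            pip = float(ps.interaction_pip[i, j])
            if pip > threshold and pip >= floor:
                g1, g2 = sorted((ps.gene_ids[i], ps.gene_ids[j]))
                pairs.append((g1, g2, pip))
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return genes, pairs
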