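"""Variational Bayesian ICA mixture model.

Generative model, per cluster k with weight pi_k:

    x_n | z_n=k  =  mu_k + A_k s_n + e_n,      e_n ~ N(0, diag(1/psi_k))
    s_nl | c_nl=j ~ N(eta_klj, 1/beta_klj),    c_nl ~ Categorical(w_kl)

with conjugate priors: pi ~ Dir(pi0), w_kl ~ Dir(w0), mu_kd ~ N(0, 1/kappa0),
A_kdl ~ N(0, 1/alpha_kl) with ARD precisions alpha_kl ~ Gamma(a0, b0),
psi_kd ~ Gamma(c0, d0), eta_klj ~ N(0, 1/tau0), beta_klj ~ Gamma(e0, f0).

Inference is structured mean-field coordinate ascent over
q(z) q(s|z) q(c|z) q(A) q(mu) q(alpha) q(psi) q(pi) q(w) q(eta) q(beta),
with q(s_n | z_n=k) a full-covariance Gaussian.  Every update is the exact
conditional optimum, so the evidence lower bound (ELBO) is non-decreasing
sweep over sweep; that monotonicity is the package's main self-check.

ARD shrinks irrelevant mixing-matrix columns towards zero, which is how the
number of defect-pattern axes per cluster is discovered (hard pruning lives
in axis_model).  Cluster labels never enter this module: fitting is fully
unsupervised.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

log = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))
_TINY = 1e-300


class VbicaNumericalError(FloatingPointError):
    """Raised when an update step produces non-finite values."""


@dataclass
class VimConfig:
    """Model size, training control and prior hyperparameters."""

    K: int
    L_max: int
    m: int = 3
    n_iterations: int = 500
    convergence_tol: float = 1e-8
    seed: int = 0
    init: str = "kmeans"  # or "random"
    # priors
    pi0: float = 1.0
    w0: float = 1.0
    kappa0: float = 1e-2
    a0: float = 1e-2   # ARD precision shape
    b0: float = 1e-2   # ARD precision rate
    c0: float = 1e-2   # noise precision shape
    d0: float = 1e-2   # noise precision rate
    tau0: float = 1.0  # source component mean precision
    e0: float = 1.0    # source component precision shape
    f0: float = 1.0    # source component precision rate

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.L_max < 1:
            raise ValueError("L_max must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for name in ("pi0", "w0", "kappa0", "a0", "b0", "c0", "d0", "tau0", "e0", "f0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter {name} must be > 0")
        if self.init not in ("kmeans", "random"):
            raise ValueError("init must be 'kmeans' or 'random'")


def standardize(data: np.ndarray) -> tuple[np.ndarray, dict]:
    """Center and scale each column to unit variance; returns (Z, params)."""
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("data must be an N x D matrix with N >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contains missing or non-finite values")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(scale == 0.0)
    if zero.size:
        raise ValueError(f"zero-variance column(s): {zero.tolist()}")
    return (X - center) / scale, {"center": center, "scale": scale}


def destandardize(Z: np.ndarray, params: dict) -> np.ndarray:
    return np.asarray(Z) * params["scale"] + params["center"]


@dataclass
class ClusterState:
    """Variational posterior of one cluster's ICA sub-model.

    Global factors: q(A) row-wise Gaussian (mA, SA), q(mu) diagonal Gaussian,
    q(alpha), q(psi), q(beta) Gamma, q(w) Dirichlet, q(eta) Gaussian.
    Local factors for the training data: q(s|z=k) (ms, Ss) and q(c|z=k) (rho).
    """

    mA: np.ndarray       # (D, L) posterior mean mixing matrix
    SA: np.ndarray       # (D, L, L) posterior row covariances
    m_mu: np.ndarray     # (D,)
    v_mu: np.ndarray     # (D,)
    alpha_a: np.ndarray  # (L,)
    alpha_b: np.ndarray  # (L,)
    psi_c: np.ndarray    # (D,)
    psi_d: np.ndarray    # (D,)
    w: np.ndarray        # (L, m) Dirichlet concentrations
    eta_m: np.ndarray    # (L, m)
    eta_v: np.ndarray    # (L, m)
    beta_e: np.ndarray   # (L, m)
    beta_f: np.ndarray   # (L, m)
    # local posteriors on the training data
    rho: Optional[np.ndarray] = None      # (N, L, m)
    ms: Optional[np.ndarray] = None       # (N, L)
    Ss: Optional[np.ndarray] = None       # (N, L, L)
    logdetS: Optional[np.ndarray] = None  # (N,)

    @property
    def L(self) -> int:
        return self.mA.shape[1]

    @property
    def D(self) -> int:
        return self.mA.shape[0]

    # --- posterior expectations -------------------------------------------
    @property
    def Epsi(self) -> np.ndarray:
        return self.psi_c / self.psi_d

    @property
    def Elogpsi(self) -> np.ndarray:
        return digamma(self.psi_c) - np.log(self.psi_d)

    @property
    def Ealpha(self) -> np.ndarray:
        return self.alpha_a / self.alpha_b

    @property
    def Elogalpha(self) -> np.ndarray:
        return digamma(self.alpha_a) - np.log(self.alpha_b)

    @property
    def Ebeta(self) -> np.ndarray:
        return self.beta_e / self.beta_f

    @property
    def Elogbeta(self) -> np.ndarray:
        return digamma(self.beta_e) - np.log(self.beta_f)

    @property
    def Elogw(self) -> np.ndarray:
        return digamma(self.w) - digamma(self.w.sum(axis=1, keepdims=True))

    def Ess(self) -> np.ndarray:
        """(N, L, L) second moments E[s s^T] under q(s|z=k)."""
        return self.Ss + self.ms[:, :, None] * self.ms[:, None, :]

    def Es2(self) -> np.ndarray:
        return self.ms**2 + np.einsum("nll->nl", self.Ss)


@dataclass
class VimModel:
    """A fitted (or initializing) VB-ICA mixture: K cluster sub-models + weights."""

    config: VimConfig
    D: int
    clusters: list[ClusterState]
    pi_conc: np.ndarray                   # (K,) Dirichlet concentrations of q(pi)
    standardization: Optional[dict] = None
    elbo_trace: list[float] = dc_field(default_factory=list)
    r: Optional[np.ndarray] = None        # (N, K) training responsibilities

    @property
    def K(self) -> int:
        return len(self.clusters)

    @property
    def Elogpi(self) -> np.ndarray:
        return digamma(self.pi_conc) - digamma(self.pi_conc.sum())

    @property
    def pi_mean(self) -> np.ndarray:
        return self.pi_conc / self.pi_conc.sum()

    def axis_counts(self) -> list[int]:
        return [c.L for c in self.clusters]

    def hard_assignments(self) -> np.ndarray:
        """argmax responsibilities; ties broken towards the lowest cluster index."""
        return np.argmax(self.r, axis=1)

    # --- serialization -----------------------------------------------------
    _ARRAYS = ("mA", "SA", "m_mu", "v_mu", "alpha_a", "alpha_b", "psi_c", "psi_d",
               "w", "eta_m", "eta_v", "beta_e", "beta_f")

    def to_dict(self) -> dict:
        return {
            "format": "fdtica-vim/1",
            "config": asdict(self.config),
            "D": self.D,
            "pi_conc": self.pi_conc.tolist(),
            "standardization": None if self.standardization is None else {
                "center": np.asarray(self.standardization["center"]).tolist(),
                "scale": np.asarray(self.standardization["scale"]).tolist(),
            },
            "elbo_trace": list(map(float, self.elbo_trace)),
            "clusters": [
                {name: getattr(c, name).tolist() for name in self._ARRAYS}
                for c in self.clusters
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "VimModel":
        if d.get("format") != "fdtica-vim/1":
            raise ValueError(f"unknown model format {d.get('format')!r}")
        config = VimConfig(**d["config"])
        clusters = [
            ClusterState(**{name: np.asarray(c[name], float) for name in cls._ARRAYS})
            for c in d["clusters"]
        ]
        std = d["standardization"]
        if std is not None:
            std = {"center": np.asarray(std["center"]), "scale": np.asarray(std["scale"])}
        return cls(config=config, D=int(d["D"]), clusters=clusters,
                   pi_conc=np.asarray(d["pi_conc"], float), standardization=std,
                   elbo_trace=list(d["elbo_trace"]))

    @classmethod
    def load(cls, path: str | Path) -> "VimModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FitResult:
    model: VimModel
    converged: bool
    n_sweeps_run: int
    final_elbo: float
    responsibilities: np.ndarray


def _check_finite(step: str, *arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise VbicaNumericalError(f"non-finite values produced in update step {step!r}")


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------

def init_model(Z: np.ndarray, config: VimConfig, rng: np.random.Generator) -> VimModel:
    """Seeded initialization.

    "kmeans" init: cluster means from a seeded k-means partition (plus a
    tiny seed-dependent jitter so distinct seeds give distinct starts),
    mixing matrices from each member set's principal directions scaled by
    their singular values plus random jitter, and source-component means
    spread over standard-normal quantiles to break mixture symmetry.
    "random" init: random data rows as means, small random mixing entries.
    All remaining variational factors start at their priors.
    """
    from scipy import stats as _stats

    Z = np.asarray(Z, float)
    N, D = Z.shape
    K, L, m = config.K, config.L_max, config.m
    if K > N:
        raise ValueError(f"K={K} exceeds the number of observations N={N}")
    if L >= D:
        raise ValueError(f"L_max={L} must be < D={D}")

    if config.init == "kmeans" and K > 1:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=K, n_init=10,
                    random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(Z)
        centers = km.cluster_centers_ + 0.01 * rng.standard_normal((K, D))
    elif K == 1:
        centers = Z.mean(axis=0, keepdims=True) + 0.01 * rng.standard_normal((1, D))
        labels = np.zeros(N, dtype=int)
    else:
        centers = Z[rng.choice(N, size=K, replace=False)].copy()
        labels = np.argmin(((Z[:, None, :] - centers[None]) ** 2).sum(-1), axis=1)

    quantiles = _stats.norm.ppf((np.arange(m) + 0.5) / m) if m > 1 else np.zeros(1)

    clusters = []
    for k in range(K):
        if config.init == "kmeans":
            members = Z[labels == k]
            if members.shape[0] <= L:
                members = Z
            Xc = members - centers[k]
            _, sv, vt = np.linalg.svd(Xc, full_matrices=False)
            scale = sv[:L] / np.sqrt(members.shape[0])
            mA = vt[:L].T * scale[None, :] + 0.05 * rng.standard_normal((D, L))
            eta_m = np.tile(quantiles, (L, 1)) + 0.1 * rng.standard_normal((L, m))
        else:
            mA = 0.05 * rng.standard_normal((D, L))
            eta_m = 0.5 * rng.standard_normal((L, m))
        clusters.append(ClusterState(
            mA=mA,
            SA=np.tile(0.01 * np.eye(L), (D, 1, 1)),
            m_mu=centers[k].copy(),
            v_mu=np.full(D, 1e-2),
            alpha_a=np.full(L, config.a0),
            alpha_b=np.full(L, config.b0),
            psi_c=np.full(D, config.c0),
            psi_d=np.full(D, config.d0),
            w=np.full((L, m), config.w0),
            eta_m=eta_m,
            eta_v=np.full((L, m), 1.0 / config.tau0),
            beta_e=np.full((L, m), config.e0),
            beta_f=np.full((L, m), config.f0),
            rho=np.full((N, L, m), 1.0 / m),
            ms=np.zeros((N, L)),
            Ss=np.tile(np.eye(L), (N, 1, 1)),
            logdetS=np.zeros(N),
        ))
    r0 = np.full((N, K), 0.05 / max(K - 1, 1))
    r0[np.arange(N), labels] = 0.95 if K > 1 else 1.0
    r0 /= r0.sum(axis=1, keepdims=True)
    model = VimModel(config=config, D=D, clusters=clusters,
                     pi_conc=np.full(K, config.pi0), r=r0)
    return model


# --------------------------------------------------------------------------
# local updates (per cluster, conditioned on z = k)
# --------------------------------------------------------------------------

def _update_sources(c: ClusterState, Z: np.ndarray) -> None:
    """Exact update of q(s | z=k): full-covariance Gaussian per observation."""
    N = Z.shape[0]
    L = c.L
    Epsi, Ebeta = c.Epsi, c.Ebeta
    AtPsiA = c.mA.T @ (Epsi[:, None] * c.mA) + np.einsum("d,dij->ij", Epsi, c.SA)
    diag_n = np.einsum("nlm,lm->nl", c.rho, Ebeta)           # (N, L)
    prec = np.broadcast_to(AtPsiA, (N, L, L)).copy()
    prec[:, np.arange(L), np.arange(L)] += diag_n
    c.Ss = np.linalg.inv(prec)
    sign, logdet_prec = np.linalg.slogdet(prec)
    c.logdetS = -logdet_prec
    h = (Z - c.m_mu) @ (Epsi[:, None] * c.mA) \
        + np.einsum("nlm,lm->nl", c.rho, Ebeta * c.eta_m)
    c.ms = np.einsum("nij,nj->ni", c.Ss, h)
    _check_finite("source posterior q(s)", c.ms, c.Ss)


def _source_quad(c: ClusterState) -> np.ndarray:
    """(N, L, m): E[(s_nl - eta_lj)^2] under current q(s), q(eta)."""
    Es2 = c.Es2()
    return (Es2[:, :, None]
            - 2.0 * c.ms[:, :, None] * c.eta_m[None]
            + (c.eta_m**2 + c.eta_v)[None])


def _update_components(c: ClusterState) -> None:
    """Exact update of q(c | z=k): per-source component responsibilities."""
    logrho = (c.Elogw[None] + 0.5 * c.Elogbeta[None]
              - 0.5 * c.Ebeta[None] * _source_quad(c) - 0.5 * LOG2PI)
    logrho -= logrho.max(axis=2, keepdims=True)
    rho = np.exp(logrho)
    c.rho = rho / rho.sum(axis=2, keepdims=True)
    _check_finite("component posterior q(c)", c.rho)


def _expected_quad(c: ClusterState, Z: np.ndarray) -> np.ndarray:
    """(N, D): E[(x_nd - mu_d - a_d . s_n)^2] under q(mu), q(A), q(s)."""
    xc = Z - c.m_mu
    Ess = c.Ess()
    proj = c.ms @ c.mA.T
    t3 = np.einsum("dl,nlk,dk->nd", c.mA, Ess, c.mA, optimize=True)
    t4 = np.einsum("dlk,nlk->nd", c.SA, Ess, optimize=True)
    return xc**2 + c.v_mu[None, :] - 2.0 * xc * proj + t3 + t4


def _cluster_loglik(c: ClusterState, Z: np.ndarray,
                    Equad: Optional[np.ndarray] = None) -> np.ndarray:
    """(N,): E[log p(x, s, c | z=k)] + H[q(s|k)] + H[q(c|k)] per observation."""
    N, D = Z.shape
    if Equad is None:
        Equad = _expected_quad(c, Z)
    ll_x = 0.5 * c.Elogpsi.sum() - 0.5 * D * LOG2PI - 0.5 * (Equad @ c.Epsi)
    sq = _source_quad(c)
    ll_s = np.einsum(
        "nlm->n", c.rho * (0.5 * c.Elogbeta[None] - 0.5 * LOG2PI
                           - 0.5 * c.Ebeta[None] * sq))
    ll_c = np.einsum("nlm,lm->n", c.rho, c.Elogw)
    H_s = 0.5 * (c.L * (1.0 + LOG2PI) + c.logdetS)
    H_c = -np.einsum("nlm->n", c.rho * np.log(c.rho + _TINY))
    return ll_x + ll_s + ll_c + H_s + H_c


def _local_loglik_matrix(model: VimModel, Z: np.ndarray) -> np.ndarray:
    return np.column_stack([_cluster_loglik(c, Z) for c in model.clusters])


def _update_responsibilities(model: VimModel, Z: np.ndarray) -> None:
    logr = model.Elogpi[None, :] + _local_loglik_matrix(model, Z)
    logr -= logsumexp(logr, axis=1, keepdims=True)
    model.r = np.exp(logr)
    _check_finite("cluster responsibilities q(z)", model.r)


# --------------------------------------------------------------------------
# global updates
# --------------------------------------------------------------------------

def _update_globals(model: VimModel, Z: np.ndarray, k: int) -> np.ndarray:
    """Exact coordinate updates of cluster k's global factors, in the fixed
    documented order A, alpha, mu, psi, (w, eta, beta).  Returns the final
    expected quadratic residual (N, D) for reuse in the ELBO."""
    cfg = model.config
    c = model.clusters[k]
    r = model.r[:, k]
    N, D = Z.shape
    L = c.L
    Nk = r.sum()

    Ess_sum = np.einsum("n,nlk->lk", r, c.Ss) + c.ms.T @ (r[:, None] * c.ms)

    # q(A): row-wise Gaussians with shared structure up to the noise precision
    Epsi = c.Epsi
    row_prec = Epsi[:, None, None] * Ess_sum[None] + np.diag(c.Ealpha)[None]
    c.SA = np.linalg.inv(row_prec)
    Cxs = ((r[:, None] * (Z - c.m_mu)).T @ c.ms)                 # (D, L)
    c.mA = np.einsum("dlk,dk->dl", c.SA, Epsi[:, None] * Cxs)
    _check_finite("mixing matrix q(A)", c.mA, c.SA)

    # q(alpha): ARD precisions on the columns of A
    EAsq = (c.mA**2).sum(axis=0) + c.SA[:, np.arange(L), np.arange(L)].sum(axis=0)
    c.alpha_a = np.full(L, cfg.a0 + 0.5 * D)
    c.alpha_b = cfg.b0 + 0.5 * EAsq
    _check_finite("ARD precisions q(alpha)", c.alpha_b)

    # q(mu)
    pred = c.ms @ c.mA.T
    c.v_mu = 1.0 / (cfg.kappa0 + Epsi * Nk)
    c.m_mu = c.v_mu * Epsi * (r @ (Z - pred))
    _check_finite("cluster mean q(mu)", c.m_mu)

    # q(psi): diagonal noise precisions, using the refreshed A and mu
    Equad = _expected_quad(c, Z)
    c.psi_c = np.full(D, cfg.c0 + 0.5 * Nk)
    c.psi_d = cfg.d0 + 0.5 * (r @ Equad)
    _check_finite("noise precisions q(psi)", c.psi_d)

    # q(w), q(eta), q(beta): source mixture parameters
    cnt = np.einsum("n,nlm->lm", r, c.rho)
    c.w = cfg.w0 + cnt
    sx = np.einsum("n,nlm,nl->lm", r, c.rho, c.ms)
    Ebeta = c.Ebeta
    prec_eta = cfg.tau0 + Ebeta * cnt
    c.eta_v = 1.0 / prec_eta
    c.eta_m = c.eta_v * Ebeta * sx
    s2 = np.einsum("n,nlm,nl->lm", r, c.rho, c.Es2())
    quad = s2 - 2.0 * c.eta_m * sx + (c.eta_m**2 + c.eta_v) * cnt
    c.beta_e = cfg.e0 + 0.5 * cnt
    c.beta_f = cfg.f0 + 0.5 * np.maximum(quad, 0.0)
    _check_finite("source mixtures q(w, eta, beta)", c.w, c.eta_m, c.beta_f)

    return Equad


# --------------------------------------------------------------------------
# ELBO
# --------------------------------------------------------------------------

def _kl_gamma(a, b, a0, b0) -> float:
    return float(np.sum((a - a0) * digamma(a) - gammaln(a) + gammaln(a0)
                        + a0 * (np.log(b) - np.log(b0)) + a * (b0 - b) / b))


def _kl_dirichlet(lam: np.ndarray, lam0: float) -> float:
    lam = np.atleast_2d(lam)
    n = lam.shape[1]
    s = lam.sum(axis=1)
    return float(np.sum(
        gammaln(s) - gammaln(lam).sum(axis=1)
        - gammaln(n * lam0) + n * gammaln(lam0)
        + ((lam - lam0) * (digamma(lam) - digamma(s)[:, None])).sum(axis=1)
    ))


def _kl_gauss(m, v, prec0) -> float:
    return float(0.5 * np.sum(prec0 * (np.asarray(m)**2 + v) - 1.0
                              - np.log(prec0 * np.asarray(v))))


def _global_kl(model: VimModel) -> float:
    """Sum of KL(q||p) over all global factors, minus the A-entropy bundle."""
    cfg = model.config
    total = _kl_dirichlet(model.pi_conc[None, :], cfg.pi0)
    for c in model.clusters:
        L, D = c.L, c.D
        total += _kl_gauss(c.m_mu, c.v_mu, cfg.kappa0)
        total += _kl_gamma(c.alpha_a, c.alpha_b, cfg.a0, cfg.b0)
        total += _kl_gamma(c.psi_c, c.psi_d, cfg.c0, cfg.d0)
        total += _kl_dirichlet(c.w, cfg.w0)
        total += _kl_gauss(c.eta_m, c.eta_v, cfg.tau0)
        total += _kl_gamma(c.beta_e, c.beta_f, cfg.e0, cfg.f0)
        # -(E[log p(A|alpha)] + H[q(A)]) term
        EAsq = (c.mA**2).sum(axis=0) + c.SA[:, np.arange(L), np.arange(L)].sum(axis=0)
        _, logdetSA = np.linalg.slogdet(c.SA)
        a_term = 0.5 * (D * c.Elogalpha.sum() - (c.Ealpha * EAsq).sum()
                        + D * L + logdetSA.sum())
        total -= a_term
    return total


def compute_elbo(model: VimModel, Z: np.ndarray,
                 Equads: Optional[list[np.ndarray]] = None) -> float:
    """Evidence lower bound at the model's current variational state."""
    G = np.column_stack([
        _cluster_loglik(c, Z, None if Equads is None else Equads[k])
        for k, c in enumerate(model.clusters)
    ])
    r = model.r
    local = float(np.sum(r * (model.Elogpi[None, :] + G))
                  - np.sum(r * np.log(r + _TINY)))
    return local - _global_kl(model)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def vb_sweep(model: VimModel, Z: np.ndarray) -> tuple[VimModel, float]:
    """One full coordinate-ascent pass; returns (model, ELBO after the pass).

    Update order (fixed for reproducibility): responsibilities; per-cluster
    source posteriors q(s) then q(c); mixing matrices; ARD precisions;
    cluster means; noise precisions; source-mixture parameters; cluster
    proportions.  The returned ELBO can never fall below the previous
    sweep's value beyond numerical round-off.
    """
    Z = np.asarray(Z, float)
    if Z.shape[1] != model.D:
        raise ValueError(f"data dimension {Z.shape[1]} != model dimension {model.D}")
    _update_responsibilities(model, Z)
    Equads = []
    for k, c in enumerate(model.clusters):
        _update_sources(c, Z)
        _update_components(c)
        Equads.append(_update_globals(model, Z, k))
    model.pi_conc = model.config.pi0 + model.r.sum(axis=0)
    elbo = compute_elbo(model, Z, Equads)
    if not np.isfinite(elbo):
        raise VbicaNumericalError("non-finite ELBO after sweep")
    return model, float(elbo)


def _train(model: VimModel, Z: np.ndarray, n_iterations: int,
           convergence_tol: float) -> tuple[bool, int]:
    converged = False
    sweeps = 0
    prev = compute_elbo(model, Z)  # pre-sweep reference for the stopping rule
    for _ in range(n_iterations):
        _, elbo = vb_sweep(model, Z)
        sweeps += 1
        if model.elbo_trace and elbo < prev - 1e-6 * abs(prev) - 1e-9:
            log.warning("ELBO decreased: %.10g -> %.10g", prev, elbo)
        model.elbo_trace.append(elbo)
        if abs(elbo - prev) <= convergence_tol * abs(prev):
            converged = True
            break
        prev = elbo
    return converged, sweeps


def fit_vbica_mm(Z: np.ndarray, config: VimConfig) -> FitResult:
    """Fit by coordinate-ascent VB: up to config.n_iterations sweeps with
    early stopping on relative ELBO change; deterministic given config.seed."""
    Z = np.asarray(Z, float)
    rng = np.random.default_rng(config.seed)
    model = init_model(Z, config, rng)
    converged, sweeps = _train(model, Z, config.n_iterations, config.convergence_tol)
    return FitResult(model=model, converged=converged, n_sweeps_run=sweeps,
                     final_elbo=model.elbo_trace[-1], responsibilities=model.r)


# --------------------------------------------------------------------------
# posterior queries
# --------------------------------------------------------------------------

def refresh_local_posteriors(model: VimModel, Z: np.ndarray,
                             n_inner: int = 5) -> np.ndarray:
    """(Re)compute q(s|k), q(c|k) and responsibilities for data Z in place.

    Used after deserialization or for held-out data; deterministic.  Returns
    the responsibility matrix.
    """
    Z = np.asarray(Z, float)
    if Z.shape[1] != model.D:
        raise ValueError(f"data dimension {Z.shape[1]} != model dimension {model.D}")
    N = Z.shape[0]
    for c in model.clusters:
        c.rho = np.broadcast_to(
            (c.w / c.w.sum(axis=1, keepdims=True))[None], (N, c.L, c.w.shape[1])
        ).copy()
        for _ in range(n_inner):
            _update_sources(c, Z)
            _update_components(c)
    _update_responsibilities(model, Z)
    return model.r


def responsibilities(model: VimModel, Z_new: np.ndarray) -> np.ndarray:
    """Posterior cluster membership probabilities for (held-out) data."""
    import copy

    probe = copy.deepcopy(model)
    return refresh_local_posteriors(probe, Z_new)


def axis_magnitudes(model: VimModel, cluster_index: int) -> np.ndarray:
    """Effective data-space magnitude of each axis of one cluster.

    magnitude_l = ||E[A]_{:,l}||_2 x posterior SD of source l over the
    cluster's members (responsibility-weighted), i.e. how much observed
    spread the axis carries.  ARD-suppressed axes score ~0.
    """
    c = model.clusters[cluster_index]
    if c.ms is None or model.r is None:
        raise ValueError("model has no local posteriors; call refresh_local_posteriors")
    r = model.r[:, cluster_index]
    wsum = r.sum()
    if wsum <= 0:
        return np.zeros(c.L)
    mean_s = (r @ c.ms) / wsum
    second = (r @ c.Es2()) / wsum
    sd = np.sqrt(np.maximum(second - mean_s**2, 0.0))
    return np.linalg.norm(c.mA, axis=0) * sd
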