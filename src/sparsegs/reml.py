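"""REML estimation for mixed models with a Kronecker genetic term.

The engine fits

    y = X b + Z1 u1 + sum_p Zp up + e

by restricted maximum likelihood, where

* ``u1`` is the genetic line-by-environment effect with
  Var(u1) = Go (x) G: ``G`` a fixed genomic relationship matrix over g
  lines and ``Go`` a v x v between-environment genetic covariance under an
  unstructured (US), factor-analytic (FA: Go = Lambda Lambda' + Psi, with
  Lambda constrained lower-trapezoidal for identifiability) or diagonal
  (DIAG) parameterization;
* each ``up`` is an iid nuisance effect, Var(up) = I sigma2_p;
* ``e`` has a heterogeneous diagonal covariance with one residual variance
  per environment.

Estimation iterates expectation-maximization (EM) updates, which never
decrease the restricted likelihood, and from the second iteration attempts
an average-information (AI) Newton step for speed; an AI step that lowers
the likelihood or leaves the feasible region is rejected in favour of the
EM update.  All computations run through Henderson's mixed-model equations
with a dense Cholesky factorization; the identity

    -2 logL_R = (n - p) log 2pi + log|R| + log|Sigma_u| + log|C| + y' P y

(with C the full coefficient matrix) gives the likelihood, and the EM
updates use traces of blocks of C^-1.

Variance components that collapse are pinned at a floor of
``floor_frac`` times the phenotypic variance and flagged; non-convergence
is reported through ``converged=False`` together with the likelihood trace,
never silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp
from scipy.linalg.lapack import dpotri

__all__ = [
    "USCovariance",
    "FACovariance",
    "DiagCovariance",
    "IIDTerm",
    "KroneckerTerm",
    "MixedREML",
    "REMLStatus",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


def _sym(a: np.ndarray) -> np.ndarray:
    return (a + a.T) / 2.0


# ---------------------------------------------------------------------------
# covariance structures for Go


class USCovariance:
    """Unstructured v x v genetic covariance: every element free."""

    name = "US"

    def __init__(self, go: np.ndarray):
        self.go = _sym(np.asarray(go, float))
        self.v = self.go.shape[0]

    @property
    def n_params(self) -> int:
        return self.v * (self.v + 1) // 2

    def param_vector(self) -> np.ndarray:
        i, j = np.triu_indices(self.v)
        return self.go[i, j].copy()

    def set_params(self, theta: np.ndarray) -> bool:
        go = np.zeros((self.v, self.v))
        i, j = np.triu_indices(self.v)
        go[i, j] = theta
        go[j, i] = theta
        w = np.linalg.eigvalsh(go)
        if w[0] <= 1e-8 * max(w[-1], 0.0):  # PD with a sane condition
            return False
        self.go = go
        return True

    def derivative_matrices(self) -> list:
        mats = []
        for i, j in zip(*np.triu_indices(self.v)):
            d = np.zeros((self.v, self.v))
            d[i, j] = d[j, i] = 1.0
            mats.append(d)
        return mats

    def boundary_mask(self, floor: float) -> np.ndarray:
        return np.zeros(self.n_params, dtype=bool)

    def em_update(self, S: np.ndarray, g: int, floor: float) -> None:
        go = _sym(S / g)
        d = np.diag(go).copy()
        low = d < floor
        if low.any():
            scale = np.sqrt(np.where(low, floor / np.maximum(d, 1e-300), 1.0))
            go = go * np.outer(scale, scale)
        # keep invertible for the prior (condition cap ~1e7)
        w, vec = np.linalg.eigh(go)
        w = np.clip(w, 1e-7 * max(w.max(), floor), None)
        self.go = _sym(vec @ np.diag(w) @ vec.T)


class FACovariance:
    """Factor-analytic Go = Lambda Lambda' + Psi with m latent factors.

    Lambda is v x m with zeros above the diagonal (rotation fixed); Psi is
    a non-negative diagonal of environment-specific variances, allowed to
    reach (numerically) zero as in the extended-FA parameterization.
    """

    name = "FA"

    def __init__(self, go_start: np.ndarray, m: int,
                 psi_floor: float | None = None):
        go_start = _sym(np.asarray(go_start, float))
        self.v = go_start.shape[0]
        if not 1 <= m < self.v:
            raise ValueError(f"FA needs 1 <= m < v; got m={m}, v={self.v}")
        self.m = m
        # Psi may approach zero (extended-FA, non-full-rank GxE) but Go
        # enters the equations through its inverse, so keep a relative floor
        if psi_floor is None:
            psi_floor = 1e-6 * float(np.mean(np.diag(go_start)))
        self.psi_floor = psi_floor
        w, vec = np.linalg.eigh(go_start)
        order = np.argsort(w)[::-1]
        w, vec = w[order], vec[:, order]
        lam = vec[:, :m] * np.sqrt(np.clip(w[:m], 1e-8, None))
        self.lam = self._rotate(lam)
        psi = np.diag(go_start) - np.sum(self.lam ** 2, axis=1)
        self.psi = np.clip(psi, 0.05 * np.diag(go_start).mean(), None)

    @property
    def go(self) -> np.ndarray:
        return self.lam @ self.lam.T + np.diag(self.psi)

    def _rotate(self, lam: np.ndarray) -> np.ndarray:
        """Rotate loadings to the lower-trapezoidal identified form."""
        q, r = np.linalg.qr(lam.T)  # lam' = q r, r is m x v upper
        signs = np.sign(np.diag(r[:, :self.m]))
        signs[signs == 0] = 1.0
        return (r * signs[:, None]).T

    def _free_indices(self):
        return [(i, j) for j in range(self.m) for i in range(j, self.v)]

    @property
    def n_params(self) -> int:
        return len(self._free_indices()) + self.v

    def param_vector(self) -> np.ndarray:
        lam_part = [self.lam[i, j] for i, j in self._free_indices()]
        return np.concatenate([lam_part, self.psi])

    def set_params(self, theta: np.ndarray) -> bool:
        idx = self._free_indices()
        lam = np.zeros((self.v, self.m))
        for k, (i, j) in enumerate(idx):
            lam[i, j] = theta[k]
        psi = np.clip(theta[len(idx):], self.psi_floor, None)
        self.lam, self.psi = lam, psi
        return True

    def derivative_matrices(self) -> list:
        mats = []
        for i, j in self._free_indices():
            d = np.zeros((self.v, self.v))
            d[i, :] += self.lam[:, j]
            d[:, i] += self.lam[:, j]
            mats.append(d)
        for vv in range(self.v):
            d = np.zeros((self.v, self.v))
            d[vv, vv] = 1.0
            mats.append(d)
        return mats

    def boundary_mask(self, floor: float) -> np.ndarray:
        mask = np.zeros(self.n_params, dtype=bool)
        n_lam = len(self._free_indices())
        mask[n_lam:] = self.psi <= self.psi_floor * (1.0 + 1e-6)
        return mask

    def em_update(self, S: np.ndarray, g: int, floor: float) -> None:
        """M-step: fit Lambda, Psi to the conditional second moment S/g.

        Inner factor-analysis EM on the v x v matrix; each inner sweep
        increases the implied Wishart likelihood, so the outer REML-EM
        retains its ascent property (ECM).
        """
        target = _sym(S / g)
        lam, psi = self.lam.copy(), np.clip(self.psi, self.psi_floor, None)
        for _ in range(50):
            go = lam @ lam.T + np.diag(psi)
            b = la.solve(go, lam, assume_a="pos")  # Go^-1 Lambda, v x m
            m2 = np.eye(self.m) - lam.T @ b + b.T @ target @ b
            lam_new = target @ b @ np.linalg.inv(_sym(m2))
            psi_new = np.clip(np.diag(target - lam_new @ m2 @ lam_new.T),
                              self.psi_floor, None)
            delta = np.abs(lam_new - lam).max() + np.abs(psi_new - psi).max()
            lam, psi = lam_new, psi_new
            if delta < 1e-10:
                break
        self.lam = self._rotate(lam)
        self.psi = psi


class DiagCovariance:
    """Independent environments: Go diagonal (no borrowing baseline)."""

    name = "DIAG"

    def __init__(self, go_start: np.ndarray):
        go_start = np.asarray(go_start, float)
        self.v = go_start.shape[0]
        self.var = np.diag(go_start).copy()

    @property
    def go(self) -> np.ndarray:
        return np.diag(self.var)

    @property
    def n_params(self) -> int:
        return self.v

    def param_vector(self) -> np.ndarray:
        return self.var.copy()

    def set_params(self, theta: np.ndarray) -> bool:
        if (theta <= 0).any():
            return False
        self.var = np.asarray(theta, float).copy()
        return True

    def derivative_matrices(self) -> list:
        mats = []
        for vv in range(self.v):
            d = np.zeros((self.v, self.v))
            d[vv, vv] = 1.0
            mats.append(d)
        return mats

    def boundary_mask(self, floor: float) -> np.ndarray:
        return self.var <= floor * (1.0 + 1e-6)

    def em_update(self, S: np.ndarray, g: int, floor: float) -> None:
        self.var = np.clip(np.diag(S) / g, floor, None)


# ---------------------------------------------------------------------------
# model terms


@dataclass
class IIDTerm:
    """Random effect with Var = I sigma2."""

    name: str
    Z: sp.csr_matrix
    labels: list = field(default_factory=list)


@dataclass
class KroneckerTerm:
    """Genetic line x environment effect with Var = Go (x) G.

    ``Z`` has one column per (environment, line) pair, environment-major and
    line-minor, matching the Kronecker ordering of Go (x) G.
    """

    Z: sp.csr_matrix
    G: np.ndarray
    structure: object  # USCovariance | FACovariance | DiagCovariance
    name: str = "genetic"


@dataclass
class REMLStatus:
    converged: bool
    n_iterations: int
    loglike_trace: list
    pinned: list
    message: str = ""


class MixedREML:
    """REML fitter; see module docstring for the model and algorithm."""

    def __init__(self, y, X, iid_terms=None, kron_term=None,
                 env_index=None, n_envs=1):
        self.y = np.asarray(y, float)
        n = self.y.shape[0]
        self.X = sp.csr_matrix(X)
        if self.X.shape[0] != n:
            raise ValueError("X rows must match y")
        self.iid_terms = list(iid_terms or [])
        self.kron = kron_term
        self.n_envs = int(n_envs)
        if env_index is None:
            env_index = np.zeros(n, dtype=int)
        self.env_index = np.asarray(env_index, int)

        blocks = [self.X] + [t.Z for t in self.iid_terms]
        if self.kron is not None:
            blocks.append(self.kron.Z)
        self.W = sp.hstack(blocks, format="csr")
        self.n_records = n
        self.n_fixed = self.X.shape[1]
        # column slices of W for each block
        self.slices = {}
        start = self.n_fixed
        for t in self.iid_terms:
            self.slices[t.name] = slice(start, start + t.Z.shape[1])
            start += t.Z.shape[1]
        if self.kron is not None:
            self.slices["genetic"] = slice(start, start + self.kron.Z.shape[1])
            self.g = self.kron.G.shape[0]
            self.v = self.kron.Z.shape[1] // self.g
            if self.kron.Z.shape[1] != self.v * self.g:
                raise ValueError("kron term columns must be v * g")
            cho = la.cho_factor(self.kron.G, lower=True, check_finite=False)
            self.G_inv = la.cho_solve(cho, np.eye(self.g), check_finite=False)
            self.logdet_G = 2.0 * np.sum(np.log(np.diag(cho[0])))

        # per-environment sufficient statistics
        self._env_rows = [np.flatnonzero(self.env_index == e)
                          for e in range(self.n_envs)]
        self._n_env = np.array([len(r) for r in self._env_rows])
        if (self._n_env == 0).any():
            raise ValueError("every environment must have records")
        self._WtW_env, self._Wty_env, self._yty_env = [], [], []
        for rows in self._env_rows:
            Wv = self.W[rows]
            self._WtW_env.append((Wv.T @ Wv).tocoo())
            self._Wty_env.append(np.asarray(Wv.T @ self.y[rows]).ravel())
            self._yty_env.append(float(self.y[rows] @ self.y[rows]))
        self._var_y = float(np.var(self.y)) or 1.0

        # parameter state, set by fit()
        self.resid_var = None
        self.iid_var = None

    # -- parameter bookkeeping ---------------------------------------------

    def _param_vector(self) -> np.ndarray:
        parts = []
        if self.kron is not None:
            parts.append(self.kron.structure.param_vector())
        parts.append(np.array([self.iid_var[t.name] for t in self.iid_terms]))
        parts.append(self.resid_var.copy())
        return np.concatenate(parts) if parts else np.array([])

    def _set_params(self, theta: np.ndarray, floor: float) -> bool:
        pos = 0
        if self.kron is not None:
            k = self.kron.structure.n_params
            if not self.kron.structure.set_params(theta[pos:pos + k]):
                return False
            pos += k
        for t in self.iid_terms:
            val = theta[pos]
            if val < floor:
                val = floor
            self.iid_var[t.name] = val
            pos += 1
        rv = np.asarray(theta[pos:pos + self.n_envs], float)
        self.resid_var = np.clip(rv, floor, None)
        return True

    # -- core linear algebra -----------------------------------------------

    def _assemble(self, need_inverse: bool):
        """Build and factor the MME; return the per-iteration state dict."""
        w_env = 1.0 / self.resid_var
        C = sum(w_env[e] * self._WtW_env[e] for e in range(self.n_envs))
        C = np.asarray(C.todense())
        rhs = sum(w_env[e] * self._Wty_env[e] for e in range(self.n_envs))
        prior_logdet = 0.0
        for t in self.iid_terms:
            sl = self.slices[t.name]
            q = sl.stop - sl.start
            idx = np.arange(sl.start, sl.stop)
            C[idx, idx] += 1.0 / self.iid_var[t.name]
            prior_logdet += q * np.log(self.iid_var[t.name])
        if self.kron is not None:
            go = self.kron.structure.go
            sign, logdet_go = np.linalg.slogdet(go)
            if sign <= 0:
                return None
            go_inv = la.inv(go)
            sl = self.slices["genetic"]
            C[sl, sl] += np.kron(go_inv, self.G_inv)
            prior_logdet += self.g * logdet_go + self.v * self.logdet_G
        try:
            cho = la.cho_factor(C, lower=True, check_finite=False,
                                overwrite_a=True)
        except la.LinAlgError:
            return None
        logdet_C = 2.0 * np.sum(np.log(np.diag(cho[0])))
        sol = la.cho_solve(cho, rhs, check_finite=False)
        yty = sum(w_env[e] * self._yty_env[e] for e in range(self.n_envs))
        yPy = yty - rhs @ sol
        loglike = -0.5 * ((self.n_records - self.n_fixed) * _LOG2PI
                          + float(self._n_env @ np.log(self.resid_var))
                          + prior_logdet + logdet_C + yPy)
        state = {"sol": sol, "loglike": loglike, "go_inv": None, "cho": cho}
        if self.kron is not None:
            state["go_inv"] = go_inv
        if need_inverse:
            self._complete_inverse(state)
            if "C_inv" not in state:
                return None
        return state

    def _complete_inverse(self, state) -> None:
        """Fill state['C_inv'] from the stored Cholesky factor."""
        if "C_inv" in state:
            return
        inv, info = dpotri(state["cho"][0], lower=True)
        if info == 0:
            # dpotri fills only the lower triangle; mirror it
            state["C_inv"] = np.tril(inv) + np.tril(inv, -1).T

    def _residuals(self, sol: np.ndarray) -> np.ndarray:
        return self.y - np.asarray(self.W @ sol).ravel()

    def _genetic_T(self, C_inv: np.ndarray) -> np.ndarray:
        """T[v, w] = tr(G^-1 C^-1_{(v),(w)}) over the genetic block."""
        sl = self.slices["genetic"]
        big = C_inv[sl, sl]
        T = np.empty((self.v, self.v))
        for a in range(self.v):
            for b in range(a, self.v):
                blk = big[a * self.g:(a + 1) * self.g,
                          b * self.g:(b + 1) * self.g]
                T[a, b] = T[b, a] = float(np.sum(self.G_inv * blk))
        return T

    def _resid_trace(self, C_inv: np.ndarray, e: int) -> float:
        """tr(W_e' W_e C^-1) using the sparse per-environment cross-product."""
        S = self._WtW_env[e]
        return float(np.sum(S.data * C_inv[S.row, S.col]))

    # -- fitting -------------------------------------------------------------

    def fit(self, method: str = "ai", tol: float = 1e-6, max_iter: int = 200,
            floor_frac: float = 1e-8, n_em_warmup: int = 2):
        """Iterate EM (optionally AI-accelerated) REML updates.

        Returns ``(state, status)``: the assembled final state (solutions,
        C inverse, restricted log-likelihood) and a :class:`REMLStatus`.
        ``method='em'`` runs pure EM, whose likelihood ascent is exact;
        ``method='ai'`` tries a damped average-information step after
        ``n_em_warmup`` EM iterations and falls back to EM when rejected.
        """
        if method not in ("ai", "em"):
            raise ValueError("method must be 'ai' or 'em'")
        floor = floor_frac * self._var_y
        # starting values
        self.resid_var = np.array([
            0.5 * (np.var(self.y[r]) or self._var_y) for r in self._env_rows])
        self.resid_var = np.clip(self.resid_var, floor, None)
        self.iid_var = {t.name: 0.05 * self._var_y for t in self.iid_terms}

        trace, pinned = [], set()
        self._lm_mu = 0.0
        prev_ll = -np.inf
        converged = False
        message = "max iterations reached"
        it = 0
        pending = None
        for it in range(1, max_iter + 1):
            state = pending if pending is not None else \
                self._assemble(need_inverse=True)
            pending = None
            if state is not None and "C_inv" not in state:
                self._complete_inverse(state)
                if "C_inv" not in state:
                    state = None
            if state is None:
                message = "mixed-model equations not positive definite"
                break
            ll = state["loglike"]
            trace.append(ll)
            if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol:
                converged = True
                message = "converged"
                break
            prev_ll = ll

            em_theta, stats = self._em_proposal(state, floor, pinned)
            if method == "ai" and it > n_em_warmup:
                pending = self._try_ai_step(state, stats, floor, ll)
            if pending is None:
                self._set_params(em_theta, floor)

        status = REMLStatus(converged, it, trace, sorted(pinned), message)
        final = self._assemble(need_inverse=True)
        if final is None:  # pragma: no cover - defensive
            raise la.LinAlgError("final mixed-model equations are singular")
        return final, status

    # EM update; returns the proposed parameter vector plus reusable stats
    def _em_proposal(self, state, floor, pinned):
        C_inv, sol = state["C_inv"], state["sol"]
        resid = self._residuals(sol)
        stats = {"resid": resid}
        parts = []
        if self.kron is not None:
            sl = self.slices["genetic"]
            U = sol[sl].reshape(self.v, self.g).T  # g x v, env-major blocks
            T = self._genetic_T(C_inv)
            S = U.T @ self.G_inv @ U + T
            stats["T"] = T
            struct = self.kron.structure
            keep = struct.param_vector()
            struct.em_update(_sym(S), self.g, floor)
            parts.append(struct.param_vector())
            struct.set_params(keep)  # restore until a proposal is accepted
        iid_part = []
        for t in self.iid_terms:
            sl = self.slices[t.name]
            q = sl.stop - sl.start
            u = sol[sl]
            new = (u @ u + np.trace(C_inv[sl, sl])) / q
            if new < floor:
                new = floor
                pinned.add(t.name)
            iid_part.append(new)
        parts.append(np.array(iid_part))
        resid_part = []
        rtr = []
        for e in range(self.n_envs):
            tr_e = self._resid_trace(C_inv, e)
            rtr.append(tr_e)
            rows = self._env_rows[e]
            new = (resid[rows] @ resid[rows] + tr_e) / self._n_env[e]
            if new < floor:
                new = floor
                pinned.add(f"residual_{e}")
            resid_part.append(new)
        stats["resid_traces"] = rtr
        parts.append(np.array(resid_part))
        return np.concatenate(parts), stats

    def _try_ai_step(self, state, stats, floor, current_ll):
        """Attempt an average-information Newton step.

        Returns the assembled state at the accepted parameters (so the next
        iteration can reuse its factorization), or None if every damped step
        failed, in which case the previous parameters are restored.
        """
        theta0 = self._param_vector()
        score, F = self._score_and_directions(state, stats)
        # active set: variance components sitting at the floor with a score
        # pushing further down stay fixed, otherwise the projected Newton
        # direction is no longer an ascent direction
        free = np.ones(len(theta0), dtype=bool)
        n_gen = self.kron.structure.n_params if self.kron is not None else 0
        boundary = theta0 <= floor * (1.0 + 1e-6)
        if n_gen:
            boundary[:n_gen] = self.kron.structure.boundary_mask(floor)
        free &= ~(boundary & (score <= 0.0))
        if not free.any():
            return None
        w_rec = 1.0 / self.resid_var[self.env_index]
        Ff = F[:, free]
        WtF = np.asarray(self.W.T @ (Ff * w_rec[:, None]))
        # P F = R^-1 F - R^-1 W C^-1 W' R^-1 F ; reuse C^-1 explicitly
        PF = Ff * w_rec[:, None] - (
            np.asarray(self.W @ (state["C_inv"] @ WtF)) * w_rec[:, None])
        AI = _sym(0.5 * (Ff.T @ PF))
        d = np.diag(AI).copy()
        d[d <= 0] = 1.0
        # Levenberg-Marquardt damping: the FA likelihood in particular has
        # ridge-shaped level sets where an undamped Newton step overshoots;
        # damping interpolates toward a scaled gradient-ascent step that is
        # guaranteed uphill for mu large enough
        mu = self._lm_mu
        base_ridge = 1e-8 * max(np.trace(AI), 1.0)
        for _ in range(7):
            try:
                delta_f = la.solve(
                    AI + np.diag(mu * d) + base_ridge * np.eye(AI.shape[0]),
                    score[free], assume_a="pos")
            except la.LinAlgError:
                mu = max(mu * 10.0, 1e-4)
                continue
            delta = np.zeros(len(theta0))
            delta[free] = delta_f
            if self._set_params(theta0 + delta, floor):
                trial = self._assemble(need_inverse=False)
                if trial is not None and \
                        trial["loglike"] >= current_ll - 1e-10:
                    self._lm_mu = mu / 10.0 if mu > 1e-8 else 0.0
                    return trial
            mu = max(mu * 10.0, 1e-4)
        self._lm_mu = mu
        self._set_params(theta0, floor)
        return None

    def _score_and_directions(self, state, stats):
        """REML scores and V-derivative directions f_i = dV_i @ Py."""
        resid = stats["resid"]
        w_rec = 1.0 / self.resid_var[self.env_index]
        Py = resid * w_rec
        scores, cols = [], []
        if self.kron is not None:
            sl = self.slices["genetic"]
            struct = self.kron.structure
            go_inv = state["go_inv"]
            T = stats["T"]
            t1 = np.asarray(self.kron.Z.T @ Py).reshape(self.v, self.g)
            Gt = t1 @ self.kron.G  # v x g
            for dgo in struct.derivative_matrices():
                A = go_inv @ dgo @ go_inv
                tr_PV = (self.g * float(np.trace(dgo @ go_inv))
                         - float(np.sum(A * T)))
                f = np.asarray(self.kron.Z @ (dgo @ Gt).ravel()).ravel()
                scores.append(-0.5 * (tr_PV - Py @ f))
                cols.append(f)
        for t in self.iid_terms:
            sl = self.slices[t.name]
            s2 = self.iid_var[t.name]
            q = sl.stop - sl.start
            tr_PV = q / s2 - np.trace(state["C_inv"][sl, sl]) / s2 ** 2
            f = np.asarray(t.Z @ (t.Z.T @ Py)).ravel()
            scores.append(-0.5 * (tr_PV - Py @ f))
            cols.append(f)
        for e in range(self.n_envs):
            s2 = self.resid_var[e]
            tr_PV = self._n_env[e] / s2 - stats["resid_traces"][e] / s2 ** 2
            f = np.where(self.env_index == e, Py, 0.0)
            scores.append(-0.5 * (tr_PV - Py @ f))
            cols.append(f)
        return np.array(scores), np.column_stack(cols)
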