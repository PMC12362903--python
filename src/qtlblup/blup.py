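"""Multi-component GBLUP: AI-REML variance components and GEBV prediction.

The model is a linear mixed model with an overall mean and one or more
genomic random effects,

    y = 1 mu + sum_k Z u_k + e,   u_k ~ N(0, G_k sigma2_k),  e ~ N(0, I sigma2_e),

where each G_k is a genomic relationship matrix over all genotyped animals
and Z selects the phenotyped (training) rows.  Variance components are
estimated by average-information REML with EM fallback steps, and breeding
values for all animals (phenotyped or not) are obtained from the conditional
expectation

    u_hat_k = sigma2_k G_k[:, train] V^{-1} (y - 1 mu_hat),
    V = sum_k G_k[train, train] sigma2_k + I sigma2_e,

which is identical to solving the mixed-model equations with unphenotyped
animals included.

A single genomic component with G built from all markers is plain GBLUP;
two components (QTL-based and SNP-based G) give 2GBLUP, and building the QTL
component with variance weights gives weighted 2GBLUP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg

from .grm import GRM, allele_frequencies

__all__ = [
    "GenomicMixedModel",
    "GenomicREMLResults",
    "backsolve_snp_effects",
    "SnpBacksolve",
]

_FLOOR_FRAC = 1e-8  # variance floor as a fraction of Var(y)
_JITTER_FRAC = 1e-8  # diagonal jitter as a fraction of mean(diag(V))


def _as_matrix(g) -> np.ndarray:
    m = g.matrix if isinstance(g, GRM) else np.asarray(g, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("GRM must be square")
    if not np.allclose(m, m.T, atol=1e-8 * (1 + np.abs(m).max())):
        raise ValueError("GRM must be symmetric")
    return m


class GenomicMixedModel:
    """Mixed model for genomic prediction with one or more GRM components.

    Parameters
    ----------
    y : phenotypes of the training animals, length n.
    components : mapping of component name to GRM (or square array) over all
        genotyped animals (training and test), each of size N x N.
    train_index : integer positions of the training animals within the GRMs.
    animal_ids : optional identifiers of the N genotyped animals.
    """

    def __init__(self, y, components: Mapping[str, GRM | np.ndarray], train_index,
                 animal_ids=None):
        self.y = np.asarray(y, dtype=np.float64).ravel()
        if len(components) == 0:
            raise ValueError("at least one genomic component is required")
        self.names = list(components)
        self.G_full = [_as_matrix(components[k]) for k in self.names]
        N = self.G_full[0].shape[0]
        if any(g.shape[0] != N for g in self.G_full):
            raise ValueError("all GRMs must have the same dimension")
        self.train_index = np.asarray(train_index, dtype=np.intp)
        if len(self.train_index) != len(self.y):
            raise ValueError("train_index length must match y")
        if self.train_index.max() >= N:
            raise ValueError("train_index outside GRM dimension")
        self.animal_ids = (
            np.arange(N) if animal_ids is None else np.asarray(animal_ids)
        )
        if len(self.animal_ids) != N:
            raise ValueError("animal_ids length must match GRM dimension")
        self.A = [g[np.ix_(self.train_index, self.train_index)] for g in self.G_full]
        self.n = len(self.y)
        k = len(self.names) + 1
        if self.n < k + 1:
            raise ValueError("more variance parameters than informative records")

    # -- restricted likelihood machinery ------------------------------------

    def _eval(self, theta: np.ndarray) -> dict:
        """Likelihood, projection and AI/score ingredients at ``theta``.

        ``theta`` holds the genomic variances followed by the residual.
        """
        n = self.n
        V = theta[-1] * np.eye(n)
        for s, A in zip(theta[:-1], self.A):
            V += s * A
        jitter = 0.0
        for attempt in range(4):
            try:
                c, low = linalg.cho_factor(V, lower=True)
                break
            except linalg.LinAlgError:
                jitter = _JITTER_FRAC * 10**attempt * np.mean(np.diag(V))
                V[np.diag_indices_from(V)] += jitter
        else:
            raise linalg.LinAlgError(
                "V is not positive definite beyond jitter; check that the GRMs "
                "are positive semidefinite"
            )
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv = linalg.cho_solve((c, low), np.eye(n))
        ViX = Vinv.sum(axis=1)  # fixed design is the intercept only
        xtvix = ViX.sum()
        P = Vinv - np.outer(ViX, ViX) / xtvix
        Py = P @ self.y
        loglik = -0.5 * (logdet_v + np.log(xtvix) + self.y @ Py)
        mats = self.A + [None]  # None marks the identity (residual)
        traces, t_vecs, quads = [], [], []
        for A in mats:
            if A is None:
                traces.append(np.trace(P))
                t = Py
            else:
                traces.append(np.vdot(P, A))  # tr(P A), both symmetric
                t = A @ Py
            t_vecs.append(t)
            quads.append(float(Py @ t))  # y' P A_k P y
        k = len(mats)
        AI = np.empty((k, k))
        Pt = [P @ t for t in t_vecs]
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * t_vecs[i] @ Pt[j]
        score = np.array([-0.5 * (tr - q) for tr, q in zip(traces, quads)])
        return dict(
            loglik=float(loglik), P=P, Py=Py, score=score, AI=AI,
            Vinv=Vinv, ViX=ViX, xtvix=float(xtvix), jitter=jitter,
        )

    def loglik(self, sigma_u, sigma_e: float) -> float:
        """Restricted log-likelihood at fixed variance components."""
        theta = np.append(np.atleast_1d(np.asarray(sigma_u, float)), sigma_e)
        return self._eval(theta)["loglik"]

    # -- fitting -------------------------------------------------------------

    def fit(self, init=None, tol: float = 1e-6, maxiter: int = 100,
            method: str = "ai") -> "GenomicREMLResults":
        """Estimate variance components.

        method : "ai" (average information with EM fallback), "em" (pure EM),
            or "fixed" (no iteration; use ``init`` as the final components).
        init : optional starting values (genomic variances..., residual);
            default puts 75% of Var(y) on the residual and splits the rest.
        """
        vy = self.y.var(ddof=1)
        floor = _FLOOR_FRAC * vy
        k = len(self.names)
        if init is None:
            theta = np.array([0.25 * vy / k] * k + [0.75 * vy])
        else:
            theta = np.asarray(init, dtype=np.float64).copy()
            if theta.shape != (k + 1,):
                raise ValueError("init must have one value per component plus residual")
        theta = np.maximum(theta, floor)
        state = self._eval(theta)
        history = [state["loglik"]]
        converged = method == "fixed"
        n_iter = 0
        if method not in ("ai", "em", "fixed"):
            raise ValueError("method must be 'ai', 'em' or 'fixed'")
        if method != "fixed":
            for n_iter in range(1, maxiter + 1):
                new, new_state = self._step(theta, state, floor, method)
                dl = new_state["loglik"] - state["loglik"]
                # relative change, guarded so parameters pinned near the
                # floor cannot stall convergence
                dp = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), 1e-3 * vy))
                theta, state = new, new_state
                history.append(state["loglik"])
                if dp < tol and abs(dl) < tol * (1.0 + abs(state["loglik"])):
                    converged = True
                    break
        se = self._se(state)
        return GenomicREMLResults(
            model=self, sigma_u=theta[:-1].copy(), sigma_e=float(theta[-1]),
            se=se, loglik=state["loglik"], n_iter=n_iter, converged=converged,
            loglik_path=history, jitter=state["jitter"], _state=state,
        )

    def _em_update(self, theta, state, floor):
        n = self.n
        new = theta + theta**2 * (state["score"] * 2.0) / n
        return np.maximum(new, floor)

    def _step(self, theta, state, floor, method):
        if method == "em":
            new = self._em_update(theta, state, floor)
            return new, self._eval(new)
        # AI step with EM safeguard
        def _solve(AI, score):
            try:
                return np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                return np.linalg.lstsq(AI, score, rcond=None)[0]

        new = theta + _solve(state["AI"], state["score"])
        # active-set handling: hold variances pushed below the floor there and
        # re-solve the AI system for the free parameters
        pinned = new < floor
        if pinned.any() and not pinned.all():
            free = ~pinned
            new = np.full_like(theta, floor)
            new[free] = theta[free] + _solve(
                state["AI"][np.ix_(free, free)], state["score"][free]
            )
        new = np.maximum(new, floor)
        new_state = self._eval(new)
        if new_state["loglik"] >= state["loglik"] - 1e-10:
            return new, new_state
        new = self._em_update(theta, state, floor)
        new_state = self._eval(new)
        for _ in range(5):  # step-halve toward the current point if needed
            if new_state["loglik"] >= state["loglik"] - 1e-10:
                break
            new = np.maximum(0.5 * (new + theta), floor)
            new_state = self._eval(new)
        return new, new_state

    def _se(self, state) -> np.ndarray:
        """Asymptotic standard errors from the inverse average information."""
        try:
            cov = np.linalg.inv(state["AI"])
            d = np.diag(cov)
            return np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            return np.full(len(self.names) + 1, np.nan)


@dataclass
class GenomicREMLResults:
    """REML estimates, diagnostics and BLUP predictions."""

    model: GenomicMixedModel
    sigma_u: np.ndarray
    sigma_e: float
    se: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: list
    jitter: float
    _state: dict

    @property
    def params(self) -> dict:
        out = dict(zip(self.model.names, self.sigma_u))
        out["residual"] = self.sigma_e
        return out

    @property
    def sigma_g2(self) -> float:
        """Total additive genetic variance (sum over genomic components)."""
        return float(self.sigma_u.sum())

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e)

    @property
    def mu(self) -> float:
        """GLS estimate of the overall mean."""
        st = self._state
        return float(st["ViX"] @ self.model.y / st["xtvix"])

    def predict(self) -> pd.DataFrame:
        """GEBV per component and in total, for every genotyped animal."""
        if not hasattr(self, "_gebv"):
            Py = self._state["Py"]  # equals V^{-1}(y - 1 mu_hat)
            cols = {}
            for name, s, G in zip(self.model.names, self.sigma_u, self.model.G_full):
                cols[name] = s * (G[:, self.model.train_index] @ Py)
            df = pd.DataFrame(cols, index=pd.Index(self.model.animal_ids, name="animal"))
            df["total"] = df.sum(axis=1)
            self._gebv = df
        return self._gebv

    @property
    def gebv(self) -> np.ndarray:
        """Total GEBV aligned to the genotyped-animal order."""
        return self.predict()["total"].to_numpy()

    def backsolve(self, component: str, X: np.ndarray, p=None) -> "SnpBacksolve":
        """Marker effects behind one genomic component (see module function)."""
        u = self.predict()[component].to_numpy()
        return backsolve_snp_effects(u, X, p)

    def summary(self) -> str:
        lines = [
            "Genomic mixed model (REML)",
            "=" * 46,
            f"n obs: {self.model.n:>6d}    components: {len(self.model.names)}",
            f"log-likelihood (restricted): {self.loglik:.4f}",
            f"iterations: {self.n_iter}    converged: {self.converged}",
        ]
        if self.jitter:
            lines.append(f"diagonal jitter applied to V: {self.jitter:.3e}")
        lines.append("-" * 46)
        lines.append(f"{'component':<16s}{'variance':>12s}{'std err':>12s}")
        for name, s, e in zip(self.model.names, self.sigma_u, self.se[:-1]):
            lines.append(f"{name:<16s}{s:>12.5f}{e:>12.5f}")
        lines.append(f"{'residual':<16s}{self.sigma_e:>12.5f}{self.se[-1]:>12.5f}")
        lines.append("-" * 46)
        lines.append(f"total genetic: {self.sigma_g2:.5f}    h2: {self.h2:.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Variance components as a tidy table."""
        names = self.model.names + ["residual"]
        vals = np.append(self.sigma_u, self.sigma_e)
        return pd.DataFrame({"component": names, "variance": vals, "se": self.se})


@dataclass
class SnpBacksolve:
    """Per-locus effects and normalised variance contributions."""

    effects: np.ndarray
    variances: np.ndarray  # 2 p q a_hat^2, scaled to sum to one


def backsolve_snp_effects(u: np.ndarray, X: np.ndarray, p=None) -> SnpBacksolve:
    """Back-solve marker effects from genomic breeding values.

    With G = W W' / s built from the centered dosages W of the same animals,
    the marker-effect BLUP behind u is a_hat = W' G^{-1} u / s (pseudo-inverse
    when G is singular).  Per-locus variances 2 p q a_hat^2 are normalised to
    sum to one.
    """
    X = np.asarray(X, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64).ravel()
    if X.shape[0] != len(u):
        raise ValueError("u must have one entry per genotyped animal in X")
    p = allele_frequencies(X) if p is None else np.asarray(p, dtype=np.float64)
    scale = 2.0 * np.sum(p * (1.0 - p))
    if scale <= 0:
        raise ValueError("all loci fixed: zero scale")
    W = X - 2.0 * p
    G = (W @ W.T) / scale
    try:
        gu = linalg.solve(G + 1e-10 * np.mean(np.diag(G)) * np.eye(len(u)), u,
                          assume_a="pos")
    except linalg.LinAlgError:
        gu = np.linalg.pinv(G) @ u
    a = W.T @ gu / scale
    var = 2.0 * p * (1.0 - p) * a**2
    total = var.sum()
    if total > 0:
        var = var / total
    return SnpBacksolve(a, var)
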