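"""Single-hidden-layer feed-forward networks with classic batch trainers.

Three trainers are provided, matching the toolbox lineage commonly used in
radiotherapy ML studies:

* Levenberg-Marquardt (LM) on the sum of squared errors, damping mu
  multiplied by 10 on rejected steps and divided by 10 on accepted ones
  (initial mu 0.001);
* Bayesian regularization (BR): LM on the regularized objective
  beta * Ed + alpha * Ew with Ed = 0.5*SSE, Ew = 0.5*||theta||^2 and the
  evidence-framework re-estimation of (alpha, beta) from the effective
  number of parameters gamma after every accepted step (initial mu 0.005);
* Moller's scaled conjugate gradient (SCG) with initial lambda 5e-7.

The network is tanh-hidden / linear-output; training is deterministic
given the initialization seed.  Inputs and targets are expected already
standardized by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_MU_MAX = 1e10
_TINY = 1e-12


@dataclass
class MLPState:
    """Flat-parameter single-hidden-layer network h = tanh, linear output."""

    n_inputs: int
    hidden_nodes: int
    theta: np.ndarray = field(default=None)  # type: ignore[assignment]
    sse_history: list[float] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        h, p = self.hidden_nodes, self.n_inputs
        return h * p + h + h + 1

    def init(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        h, p = self.hidden_nodes, self.n_inputs
        # small-scale random init keeps tanh units in their linear regime
        w1 = rng.normal(0.0, 1.0 / np.sqrt(max(p, 1)), size=h * p)
        b1 = rng.normal(0.0, 0.1, size=h)
        w2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=h)
        b2 = np.zeros(1)
        self.theta = np.concatenate([w1, b1, w2, b2])

    def _unpack(self, theta: np.ndarray):
        h, p = self.hidden_nodes, self.n_inputs
        w1 = theta[: h * p].reshape(h, p)
        b1 = theta[h * p: h * p + h]
        w2 = theta[h * p + h: h * p + 2 * h]
        b2 = theta[-1]
        return w1, b1, w2, b2

    def forward(self, X: np.ndarray, theta: np.ndarray | None = None) -> np.ndarray:
        w1, b1, w2, b2 = self._unpack(self.theta if theta is None else theta)
        z = np.tanh(X @ w1.T + b1)
        return z @ w2 + b2

    def jacobian(self, X: np.ndarray, theta: np.ndarray | None = None) -> np.ndarray:
        """d(output)/d(theta), one row per sample."""
        w1, b1, w2, b2 = self._unpack(self.theta if theta is None else theta)
        z = np.tanh(X @ w1.T + b1)          # (n, h)
        d = (1.0 - z * z) * w2              # (n, h)
        n = X.shape[0]
        j_w1 = (d[:, :, None] * X[:, None, :]).reshape(n, -1)
        return np.hstack([j_w1, d, z, np.ones((n, 1))])

    def gradient_sse(self, X: np.ndarray, y: np.ndarray,
                     theta: np.ndarray | None = None) -> np.ndarray:
        """Gradient of 0.5 * SSE."""
        th = self.theta if theta is None else theta
        e = y - self.forward(X, th)
        return -self.jacobian(X, th).T @ e


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training data must be finite")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    return X, y


def fit_lm(X: np.ndarray, y: np.ndarray, hidden_nodes: int, seed: int,
           mu0: float = 0.001, max_epochs: int = 1000,
           gtol: float = 1e-7) -> MLPState:
    """Levenberg-Marquardt backpropagation on sum-of-squared error."""
    X, y = _check_xy(X, y)
    net = MLPState(X.shape[1], hidden_nodes)
    net.init(seed)
    eye = np.eye(net.n_params)
    mu = mu0
    e = y - net.forward(X)
    sse = float(e @ e)
    net.sse_history.append(sse)
    for _ in range(max_epochs):
        J = net.jacobian(X)
        Jte = J.T @ e
        if np.max(np.abs(2.0 * Jte)) < gtol:
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= _MU_MAX:
            step = np.linalg.solve(JtJ + mu * eye, Jte)
            cand = net.theta + step
            e_new = y - net.forward(X, cand)
            sse_new = float(e_new @ e_new)
            if sse_new < sse:
                net.theta, e, sse = cand, e_new, sse_new
                mu = max(mu / 10.0, 1e-20)
                accepted = True
                break
            mu *= 10.0
        net.sse_history.append(sse)
        if not accepted:
            break
    return net


def fit_br(X: np.ndarray, y: np.ndarray, hidden_nodes: int, seed: int,
           mu0: float = 0.005, max_epochs: int = 1000,
           gtol: float = 1e-7) -> MLPState:
    """Bayesian regularization implemented within the LM optimization.

    alpha (weight-decay) and beta (noise precision) are re-estimated every
    accepted epoch from gamma, the effective number of parameters; both
    stay strictly positive throughout.
    """
    X, y = _check_xy(X, y)
    net = MLPState(X.shape[1], hidden_nodes)
    net.init(seed)
    m = net.n_params
    n = X.shape[0]
    eye = np.eye(m)
    alpha, beta = 0.01, 1.0
    net.alpha_beta_history = []  # type: ignore[attr-defined]
    mu = mu0

    def objective(theta: np.ndarray) -> tuple[float, float, float]:
        e_ = y - net.forward(X, theta)
        ed = 0.5 * float(e_ @ e_)
        ew = 0.5 * float(theta @ theta)
        return beta * ed + alpha * ew, ed, ew

    f_cur, ed, ew = objective(net.theta)
    for _ in range(max_epochs):
        J = net.jacobian(X)
        e = y - net.forward(X)
        grad = beta * (J.T @ e) - alpha * net.theta
        if np.max(np.abs(2.0 * grad)) < gtol:
            break
        H = beta * (J.T @ J) + alpha * eye
        accepted = False
        while mu <= _MU_MAX:
            step = np.linalg.solve(H + mu * eye, grad)
            cand = net.theta + step
            f_new, ed_new, ew_new = objective(cand)
            if f_new < f_cur:
                net.theta = cand
                f_cur, ed, ew = f_new, ed_new, ew_new
                mu = max(mu / 10.0, 1e-20)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            break
        # evidence update of the hyperparameters
        J = net.jacobian(X)
        H = beta * (J.T @ J) + alpha * eye
        gamma = m - alpha * float(np.trace(np.linalg.inv(H)))
        gamma = min(max(gamma, _TINY), m - _TINY)
        alpha = max(gamma / (2.0 * max(ew, _TINY)), _TINY)
        beta = max((n - gamma) / (2.0 * max(ed, _TINY)), _TINY)
        net.alpha_beta_history.append((alpha, beta))  # type: ignore[attr-defined]
        f_cur, ed, ew = objective(net.theta)
        net.sse_history.append(2.0 * ed)
    return net


def fit_scg(X: np.ndarray, y: np.ndarray, hidden_nodes: int, seed: int,
            lambda0: float = 5.0e-7, sigma0: float = 5.0e-5,
            max_epochs: int = 1000, gtol: float = 1e-7) -> MLPState:
    """Moller's scaled conjugate gradient on E(theta) = 0.5 * SSE."""
    X, y = _check_xy(X, y)
    net = MLPState(X.shape[1], hidden_nodes)
    net.init(seed)
    m = net.n_params

    def energy(theta: np.ndarray) -> float:
        e_ = y - net.forward(X, theta)
        return 0.5 * float(e_ @ e_)

    theta = net.theta
    lam, lam_bar = lambda0, 0.0
    r = -net.gradient_sse(X, y, theta)
    p = r.copy()
    success = True
    E = energy(theta)
    net.sse_history.append(2.0 * E)
    delta = 0.0
    for k in range(1, max_epochs + 1):
        if np.max(np.abs(r)) < gtol:
            break
        p_norm2 = float(p @ p)
        if p_norm2 < _TINY:
            break
        if success:
            sigma = sigma0 / np.sqrt(p_norm2)
            s = (net.gradient_sse(X, y, theta + sigma * p)
                 - net.gradient_sse(X, y, theta)) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu_ = float(p @ r)
        alpha_ = mu_ / delta
        cand = theta + alpha_ * p
        E_new = energy(cand)
        Delta = 2.0 * delta * (E - E_new) / (mu_ * mu_) if mu_ != 0 else -1.0
        if Delta >= 0:
            theta, E = cand, E_new
            r_new = -net.gradient_sse(X, y, theta)
            lam_bar = 0.0
            success = True
            if k % m == 0:
                p = r_new.copy()  # periodic restart along steepest descent
            else:
                beta_ = (float(r_new @ r_new) - float(r_new @ r)) / mu_
                p = r_new + beta_ * p
            r = r_new
            if Delta >= 0.75:
                lam = max(lam / 4.0, _TINY)
            net.sse_history.append(2.0 * E)
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam += delta * (1.0 - Delta) / p_norm2
        if lam > 1e15:
            break
    net.theta = theta
    return net
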