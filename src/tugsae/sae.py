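"""Sparse autoencoders, greedy stacking and the softmax classification head.

One autoencoder layer maps an input x in [0,1]^K through a logistic-sigmoid
encoder z = h(W1 x + b1) and decoder x_hat = h(W2 z + b2), trained by
minimising

    E = (1/N) sum_n sum_k (x_nk - x_hat_nk)^2
        + lambda * Omega_weights + beta * Omega_sparsity,

where Omega_weights = 1/2 sum w^2 over the layer's encoder and decoder
weights (biases excluded), and Omega_sparsity is the Kullback-Leibler
divergence between the target sparsity proportion rho and each hidden
neuron's mean activation rho_hat_i = (1/N) sum_j z_i(x_j). Gradients are
analytic (backpropagation including the sparsity term's dependence on
rho_hat) and training is deterministic full-batch L-BFGS.

A two-layer stack is trained greedily (AE1 on the images, AE2 on the AE1
codes), the decoders are dropped, a two-class softmax head is attached and
trained, and finally the whole encoder + head is fine-tuned on the
cross-entropy (fine-tuning can be disabled for ablation). The neuron-count
grid search trains the two-layer stack repeatedly per (n1, n2) cell and
averages the stacked reconstruction error x -> z1 -> z2 -> z1_hat -> x_hat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "AutoencoderLayer",
    "TrainConfig",
    "SAEHyperparams",
    "SAEClassifier",
    "GridSearchResult",
    "encode",
    "decode",
    "mean_activation",
    "sparsity_penalty",
    "l2_penalty",
    "ae_cost",
    "train_autoencoder",
    "build_and_train_sae",
    "grid_search",
]

_RHO_EPS = 1e-6  # clip for mean activations inside the KL term


def _sigmoid(a: np.ndarray) -> np.ndarray:
    # clip at |a| = 40: sigmoid saturates beyond double precision there,
    # and the clip keeps exp() overflow-free in one vectorised pass
    return 1.0 / (1.0 + np.exp(-np.clip(a, -40.0, 40.0)))


@dataclass
class AutoencoderLayer:
    """One sparse autoencoder: logistic-sigmoid encoder and decoder."""

    W1: np.ndarray  # (d_hidden, d_in)
    b1: np.ndarray  # (d_hidden,)
    W2: np.ndarray  # (d_in, d_hidden)
    b2: np.ndarray  # (d_in,)
    lambda_: float = 0.0  # L2 coefficient
    beta: float = 0.0  # sparsity coefficient
    rho: float = 0.05  # target sparsity proportion

    def __post_init__(self) -> None:
        h, d = self.W1.shape
        if self.W2.shape != (d, h) or self.b1.shape != (h,) or self.b2.shape != (d,):
            raise ValueError("inconsistent layer shapes")
        if self.lambda_ < 0 or self.beta < 0 or not (0 < self.rho < 1):
            raise ValueError("need lambda, beta >= 0 and rho in (0, 1)")

    @property
    def d_in(self) -> int:
        return self.W1.shape[1]

    @property
    def d_hidden(self) -> int:
        return self.W1.shape[0]


def _as_batch(x: np.ndarray, d: int, what: str) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.ndim != 2 or X.shape[1] != d:
        raise ValueError(f"{what}: expected {d} features, got shape {x.shape}")
    return X, single


def encode(layer: AutoencoderLayer, x: np.ndarray) -> np.ndarray:
    """z = sigmoid(W1 x + b1); accepts one vector or an (n, d_in) batch."""
    X, single = _as_batch(x, layer.d_in, "encode")
    Z = _sigmoid(X @ layer.W1.T + layer.b1)
    return Z[0] if single else Z


def decode(layer: AutoencoderLayer, z: np.ndarray) -> np.ndarray:
    """x_hat = sigmoid(W2 z + b2); accepts one vector or an (n, d_hidden) batch."""
    Z, single = _as_batch(z, layer.d_hidden, "decode")
    Xh = _sigmoid(Z @ layer.W2.T + layer.b2)
    return Xh[0] if single else Xh


def mean_activation(layer: AutoencoderLayer, inputs: np.ndarray) -> np.ndarray:
    """Per-neuron mean activation rho_hat_i over a set of examples."""
    X, _ = _as_batch(inputs, layer.d_in, "mean_activation")
    if X.shape[0] < 1:
        raise ValueError("need at least one example")
    return encode(layer, X).mean(axis=0)


def sparsity_penalty(p_hat: np.ndarray, rho: float) -> float:
    """KL-divergence sparsity penalty: sum_i KL(rho || p_hat_i).

    Zero iff every neuron's mean activation equals the target rho.
    Mean activations are clipped to [1e-6, 1 - 1e-6] against sigmoid
    saturation in finite precision.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    if np.any(p_hat <= 0) or np.any(p_hat >= 1):
        raise ValueError("mean activations must lie strictly in (0, 1)")
    if not (0 < rho < 1):
        raise ValueError("rho must lie in (0, 1)")
    p = np.clip(p_hat, _RHO_EPS, 1 - _RHO_EPS)
    return float(np.sum(rho * np.log(rho / p) + (1 - rho) * np.log((1 - rho) / (1 - p))))


def l2_penalty(weight_matrices) -> float:
    """Half the sum of squares over all given weight matrices (biases excluded)."""
    return 0.5 * float(sum(np.sum(np.square(W)) for W in weight_matrices))


@dataclass(frozen=True)
class TrainConfig:
    """Deterministic full-batch training settings."""

    max_iterations: int = 400  # unsupervised phase, per layer
    supervised_iterations: int = 100  # softmax head and fine-tuning, each
    optimizer: str = "L-BFGS-B"
    convergence_tol: float = 1e-7  # gradient-norm tolerance
    seed: int = 0
    fine_tune: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1 or self.supervised_iterations < 1:
            raise ValueError("iteration counts must be >= 1")


# --- cost and gradients -----------------------------------------------------


def _opt_options(optimizer: str, maxiter: int, gtol: float) -> dict:
    # convergence_tol is a gradient-norm tolerance; for L-BFGS-B the
    # function-decrease test is disabled so flat plateaus (e.g. a collapsed
    # sparse code at the start of fine-tuning) do not end the minimisation
    # prematurely.
    opts = {"maxiter": maxiter, "gtol": gtol}
    if optimizer == "L-BFGS-B":
        opts["ftol"] = 1e-16
    return opts


def _pack(*arrays: np.ndarray) -> np.ndarray:
    return np.concatenate([a.ravel() for a in arrays])


def _unpack_ae(theta: np.ndarray, d_in: int, d_hidden: int):
    i = 0
    W1 = theta[i : i + d_hidden * d_in].reshape(d_hidden, d_in); i += d_hidden * d_in
    b1 = theta[i : i + d_hidden]; i += d_hidden
    W2 = theta[i : i + d_in * d_hidden].reshape(d_in, d_hidden); i += d_in * d_hidden
    b2 = theta[i : i + d_in]
    return W1, b1, W2, b2


def _ae_cost_grad(theta, X, d_in, d_hidden, lam, beta, rho):
    W1, b1, W2, b2 = _unpack_ae(theta, d_in, d_hidden)
    N = X.shape[0]
    Z = _sigmoid(X @ W1.T + b1)
    Xh = _sigmoid(Z @ W2.T + b2)
    R = Xh - X

    rho_hat = np.clip(Z.mean(axis=0), _RHO_EPS, 1 - _RHO_EPS)
    cost = (
        np.sum(R * R) / N
        + lam * 0.5 * (np.sum(W1 * W1) + np.sum(W2 * W2))
        + beta * np.sum(rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat)))
    )
    if not np.isfinite(cost):
        raise FloatingPointError("autoencoder cost is not finite; inspect inputs/hyperparameters")

    d2 = (2.0 / N) * R * Xh * (1 - Xh)  # (N, d_in)
    gW2 = d2.T @ Z + lam * W2
    gb2 = d2.sum(axis=0)
    # The sparsity term reaches every example through rho_hat.
    kl_grad = beta / N * (-(rho / rho_hat) + (1 - rho) / (1 - rho_hat))  # (d_hidden,)
    d1 = (d2 @ W2 + kl_grad) * Z * (1 - Z)  # (N, d_hidden)
    gW1 = d1.T @ X + lam * W1
    gb1 = d1.sum(axis=0)
    return cost, _pack(gW1, gb1, gW2, gb2)


def ae_cost(layer: AutoencoderLayer, inputs: np.ndarray) -> tuple[float, dict]:
    """Training cost of Omega-regularised reconstruction, with gradients.

    Returns ``(cost, grads)`` where ``grads`` maps ``"W1","b1","W2","b2"``
    to arrays of matching shapes. The reconstruction term is the per-example
    mean of the summed squared pixel error.
    """
    X, _ = _as_batch(inputs, layer.d_in, "ae_cost")
    theta = _pack(layer.W1, layer.b1, layer.W2, layer.b2)
    cost, g = _ae_cost_grad(theta, X, layer.d_in, layer.d_hidden, layer.lambda_, layer.beta, layer.rho)
    gW1, gb1, gW2, gb2 = _unpack_ae(g, layer.d_in, layer.d_hidden)
    return float(cost), {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


def _init_layer(d_in: int, d_hidden: int, rng: np.random.Generator) -> np.ndarray:
    # Symmetric uniform scaled by fan sizes; biases start at zero.
    r = np.sqrt(6.0 / (d_in + d_hidden + 1))
    W1 = rng.uniform(-r, r, size=(d_hidden, d_in))
    W2 = rng.uniform(-r, r, size=(d_in, d_hidden))
    return _pack(W1, np.zeros(d_hidden), W2, np.zeros(d_in))


def train_autoencoder(
    inputs: np.ndarray,
    d_hidden: int,
    lambda_: float,
    beta: float,
    rho: float,
    config: TrainConfig,
) -> AutoencoderLayer:
    """Train one sparse autoencoder by full-batch L-BFGS; seeded and deterministic."""
    X = np.asarray(inputs, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D input array with at least 2 examples")
    d_in = X.shape[1]
    rng = np.random.default_rng(config.seed)
    theta0 = _init_layer(d_in, d_hidden, rng)
    res = minimize(
        _ae_cost_grad,
        theta0,
        args=(X, d_in, d_hidden, lambda_, beta, rho),
        jac=True,
        method=config.optimizer,
        options=_opt_options(config.optimizer, config.max_iterations, config.convergence_tol),
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"autoencoder training diverged: {res.message}")
    W1, b1, W2, b2 = _unpack_ae(res.x, d_in, d_hidden)
    return AutoencoderLayer(W1=W1, b1=b1, W2=W2, b2=b2, lambda_=lambda_, beta=beta, rho=rho)


# --- stacked classifier -----------------------------------------------------


@dataclass(frozen=True)
class SAEHyperparams:
    """Per-layer hyperparameters of the two-layer stack."""

    n1: int = 300
    n2: int = 30
    lambda1: float = 0.004
    lambda2: float = 0.002
    beta: float = 4.0
    rho1: float = 0.015
    rho2: float = 0.01


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _head_cost_grad(theta, Z, Y, trace=None):
    n2 = Z.shape[1]
    W = theta[: 2 * n2].reshape(2, n2)
    b = theta[2 * n2 :]
    P = _softmax(Z @ W.T + b)
    N = Z.shape[0]
    cost = -np.sum(Y * np.log(np.clip(P, 1e-12, None))) / N
    if trace is not None:
        trace.append(float(cost))
    D = (P - Y) / N
    return cost, _pack(D.T @ Z, D.sum(axis=0))


def _finetune_cost_grad(theta, X, Y, d_in, n1, n2, trace=None):
    i = 0
    W1 = theta[i : i + n1 * d_in].reshape(n1, d_in); i += n1 * d_in
    b1 = theta[i : i + n1]; i += n1
    W2 = theta[i : i + n2 * n1].reshape(n2, n1); i += n2 * n1
    b2 = theta[i : i + n2]; i += n2
    Ws = theta[i : i + 2 * n2].reshape(2, n2); i += 2 * n2
    bs = theta[i :]
    Z1 = _sigmoid(X @ W1.T + b1)
    Z2 = _sigmoid(Z1 @ W2.T + b2)
    P = _softmax(Z2 @ Ws.T + bs)
    N = X.shape[0]
    cost = -np.sum(Y * np.log(np.clip(P, 1e-12, None))) / N
    if trace is not None:
        trace.append(float(cost))
    Dl = (P - Y) / N
    gWs, gbs = Dl.T @ Z2, Dl.sum(axis=0)
    D2 = (Dl @ Ws) * Z2 * (1 - Z2)
    gW2, gb2 = D2.T @ Z1, D2.sum(axis=0)
    D1 = (D2 @ W2) * Z1 * (1 - Z1)
    gW1, gb1 = D1.T @ X, D1.sum(axis=0)
    return cost, _pack(gW1, gb1, gW2, gb2, gWs, gbs)


@dataclass
class SAEClassifier:
    """Two-layer stacked autoencoder with a two-class softmax head.

    Follows the scikit-learn estimator convention: construct with
    hyperparameters, then ``fit(images, labels)`` (labels 0 = no risk,
    1 = at risk), then ``predict``/``predict_proba``. Training is greedy
    layer-wise pretraining followed by supervised head training and, by
    default, full fine-tuning; the supervised loss trace is kept in
    ``supervised_loss_``.
    """

    hyper: SAEHyperparams = field(default_factory=SAEHyperparams)
    config: TrainConfig = field(default_factory=TrainConfig)

    encoder1: AutoencoderLayer | None = None
    encoder2: AutoencoderLayer | None = None
    softmax_W: np.ndarray | None = None
    softmax_b: np.ndarray | None = None
    supervised_loss_: list = field(default_factory=list)

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "SAEClassifier":
        X = np.asarray(images, dtype=float)
        y = np.asarray(labels).astype(int)
        if X.ndim != 2 or X.shape[0] < 4:
            raise ValueError("need a 2-D image array with at least 4 examples")
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("both classes (0 and 1) must be present")
        h, cfg = self.hyper, self.config
        ss = np.random.SeedSequence(cfg.seed)
        s1, s2, s3 = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))

        self.encoder1 = train_autoencoder(
            X, h.n1, h.lambda1, h.beta, h.rho1, replace(cfg, seed=s1)
        )
        Z1 = encode(self.encoder1, X)
        self.encoder2 = train_autoencoder(
            Z1, h.n2, h.lambda2, h.beta, h.rho2, replace(cfg, seed=s2)
        )
        Z2 = encode(self.encoder2, Z1)

        Y = np.zeros((X.shape[0], 2))
        Y[np.arange(X.shape[0]), y] = 1.0

        # Loss trace records every cost evaluation of the supervised phase
        # (head training then fine-tuning), line-search probes included.
        trace: list[float] = []

        # Small seeded random head init: with heavily sparsified (nearly
        # constant) codes and balanced classes, a zero-initialised head sits
        # on an exact saddle of the cross-entropy.
        head_rng = np.random.default_rng(s3)
        r = np.sqrt(6.0 / (h.n2 + 3))
        theta0 = _pack(head_rng.uniform(-r, r, size=(2, h.n2)), np.zeros(2))
        res = minimize(
            _head_cost_grad, theta0, args=(Z2, Y, trace), jac=True, method=cfg.optimizer,
            options=_opt_options(cfg.optimizer, cfg.supervised_iterations, cfg.convergence_tol),
        )
        self.softmax_W = res.x[: 2 * h.n2].reshape(2, h.n2)
        self.softmax_b = res.x[2 * h.n2 :]

        if cfg.fine_tune:
            d_in = X.shape[1]
            theta0 = _pack(
                self.encoder1.W1, self.encoder1.b1,
                self.encoder2.W1, self.encoder2.b1,
                self.softmax_W, self.softmax_b,
            )
            res = minimize(
                _finetune_cost_grad, theta0, args=(X, Y, d_in, h.n1, h.n2, trace), jac=True,
                method=cfg.optimizer,
                options=_opt_options(cfg.optimizer, cfg.supervised_iterations, cfg.convergence_tol),
            )
            i = 0
            W1 = res.x[i : i + h.n1 * d_in].reshape(h.n1, d_in); i += h.n1 * d_in
            b1 = res.x[i : i + h.n1]; i += h.n1
            W2 = res.x[i : i + h.n2 * h.n1].reshape(h.n2, h.n1); i += h.n2 * h.n1
            b2 = res.x[i : i + h.n2]; i += h.n2
            self.encoder1 = replace(self.encoder1, W1=W1, b1=b1)
            self.encoder2 = replace(self.encoder2, W1=W2, b1=b2)
            self.softmax_W = res.x[i : i + 2 * h.n2].reshape(2, h.n2)
            self.softmax_b = res.x[i + 2 * h.n2 :]
        self.supervised_loss_ = trace
        return self

    def _check_fitted(self):
        if self.encoder1 is None:
            raise RuntimeError("classifier is not fitted")

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X, single = _as_batch(images, self.encoder1.d_in, "predict_proba")
        Z2 = encode(self.encoder2, encode(self.encoder1, X))
        P = _softmax(Z2 @ self.softmax_W.T + self.softmax_b)
        return P[0] if single else P

    def predict(self, images: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(self.predict_proba(images))
        return P.argmax(axis=1)


def build_and_train_sae(
    images: np.ndarray,
    labels: np.ndarray,
    hyper: SAEHyperparams | None = None,
    config: TrainConfig | None = None,
) -> SAEClassifier:
    """Greedy pretraining + softmax head + fine-tuning; returns the fitted classifier."""
    clf = SAEClassifier(hyper=hyper or SAEHyperparams(), config=config or TrainConfig())
    return clf.fit(images, labels)


# --- neuron-count grid search ----------------------------------------------


@dataclass(frozen=True)
class GridSearchResult:
    """Mean stacked-reconstruction MSE per (n1, n2) cell, averaged over runs."""

    n1_values: tuple[int, ...]
    n2_values: tuple[int, ...]
    mse_table: np.ndarray  # (len(n1_values), len(n2_values))
    best_pair: tuple[int, int]
    runs: int


def _stacked_mse(X: np.ndarray, ae1: AutoencoderLayer, ae2: AutoencoderLayer) -> float:
    Z1 = encode(ae1, X)
    Z1_hat = decode(ae2, encode(ae2, Z1))
    X_hat = decode(ae1, Z1_hat)
    # Eq-8 convention: summed squared pixel error, averaged over examples.
    return float(np.sum((X - X_hat) ** 2) / X.shape[0])


def grid_search(
    images: np.ndarray,
    n1_values=(100, 200, 300, 400, 500),
    n2_values=(10, 15, 20, 25, 30),
    runs: int = 10,
    hyper: SAEHyperparams | None = None,
    config: TrainConfig | None = None,
) -> GridSearchResult:
    """Average stacked reconstruction MSE over `runs` seeded trainings per cell.

    The reconstruction path is x -> z1 -> z2 -> z1_hat -> x_hat through the
    greedily trained two-layer stack. Ties break toward smaller n1, then
    smaller n2. Bit-reproducible for a fixed master seed (``config.seed``).
    """
    X = np.asarray(images, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D image array with at least 2 examples")
    h = hyper or SAEHyperparams()
    cfg = config or TrainConfig()
    ss = np.random.SeedSequence(cfg.seed)
    children = iter(ss.spawn(len(n1_values) * len(n2_values) * runs * 2))
    table = np.empty((len(n1_values), len(n2_values)))
    for i, n1 in enumerate(n1_values):
        for j, n2 in enumerate(n2_values):
            mses = []
            for _ in range(runs):
                s1 = int(next(children).generate_state(1)[0] % 2**31)
                s2 = int(next(children).generate_state(1)[0] % 2**31)
                ae1 = train_autoencoder(X, n1, h.lambda1, h.beta, h.rho1, replace(cfg, seed=s1))
                Z1 = encode(ae1, X)
                ae2 = train_autoencoder(Z1, n2, h.lambda2, h.beta, h.rho2, replace(cfg, seed=s2))
                mses.append(_stacked_mse(X, ae1, ae2))
            table[i, j] = np.mean(mses)
    best = (int(n1_values[0]), int(n2_values[0]))
    best_val = table[0, 0]
    for i, n1 in enumerate(n1_values):
        for j, n2 in enumerate(n2_values):
            if table[i, j] < best_val:
                best_val = table[i, j]
                best = (int(n1), int(n2))
    return GridSearchResult(
        n1_values=tuple(int(v) for v in n1_values),
        n2_values=tuple(int(v) for v in n2_values),
        mse_table=table,
        best_pair=best,
        runs=runs,
    )
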