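"""Graph-convolutional autoencoder for spatially-aware spot embeddings.

The encoder stacks graph-convolution layers ``H^(l+1) = act(A_hat H^(l) W^(l))``
down to the latent width ``d_ST``; a mirrored decoder maps back to gene width
and the whole stack is trained full-batch against the mean-squared
reconstruction error of the normalized expression matrix.  The network is
small and the batch is the whole tissue, so training is implemented directly
in numpy with hand-derived gradients and an Adam update; every random draw
(weight initialization) flows from ``EncoderConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .types import ExpressionMatrix, SpotEmbedding, ValidationError


# ---------------------------------------------------------------------------
# expression normalization
# ---------------------------------------------------------------------------

def normalize_expression(expr: ExpressionMatrix, n_hvg: int = 3000) -> ExpressionMatrix:
    """Library-size normalization, log1p, and highly-variable-gene selection.

    Each spot is scaled to the median library size, values are log1p
    transformed, and the top ``n_hvg`` genes by dispersion (variance/mean of
    the scaled counts) are retained; all genes are kept when ``m <= n_hvg``.
    Already-normalized matrices are returned unchanged — normalization is
    applied at most once.
    """
    if n_hvg < 2:
        raise ValidationError(f"n_hvg must be >= 2, got {n_hvg}")
    if expr.is_normalized:
        return expr
    X = expr.values
    libs = X.sum(axis=1)
    if (libs == 0).any():
        import logging
        logging.getLogger(__name__).warning(
            "%d spots have zero total expression; their rows stay zero",
            int((libs == 0).sum()),
        )
    target = float(np.median(libs[libs > 0])) if (libs > 0).any() else 1.0
    scale = np.divide(target, libs, out=np.zeros_like(libs, dtype=float), where=libs > 0)
    S = X * scale[:, None]

    if expr.n_genes > n_hvg:
        mu = S.mean(axis=0)
        var = S.var(axis=0)
        disp = np.divide(var, mu, out=np.zeros_like(mu), where=mu > 0)
        # stable selection: sort by (-dispersion, column index)
        order = np.lexsort((np.arange(disp.size), -disp))
        keep = np.sort(order[:n_hvg])
    else:
        keep = np.arange(expr.n_genes)

    return ExpressionMatrix(
        values=np.log1p(S[:, keep]),
        spot_ids=list(expr.spot_ids),
        gene_symbols=[expr.gene_symbols[i] for i in keep],
        is_normalized=True,
    )


# ---------------------------------------------------------------------------
# graph convolution
# ---------------------------------------------------------------------------

_ACTIVATIONS = ("relu", "elu", "identity")


def _act(Z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(Z, 0.0)
    if kind == "elu":
        return np.where(Z > 0, Z, np.expm1(np.minimum(Z, 0.0)))
    if kind == "identity":
        return Z
    raise ValidationError(f"unknown activation {kind!r}; expected one of {_ACTIVATIONS}")


def _act_grad(Z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (Z > 0).astype(float)
    if kind == "elu":
        return np.where(Z > 0, 1.0, np.exp(np.minimum(Z, 0.0)))
    if kind == "identity":
        return np.ones_like(Z)
    raise ValidationError(f"unknown activation {kind!r}")


def gcn_layer(H: np.ndarray, A_hat, W: np.ndarray, activation: str = "identity") -> np.ndarray:
    """One graph-convolution layer: ``act(A_hat @ H @ W)``."""
    H = np.asarray(H, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    n = A_hat.shape[0]
    if A_hat.shape[1] != n or H.shape[0] != n or H.shape[1] != W.shape[0]:
        raise ValidationError(
            f"shape mismatch: A_hat {A_hat.shape}, H {H.shape}, W {W.shape}"
        )
    return _act(np.asarray(A_hat @ H) @ W, activation)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    """Architecture and optimization settings for the autoencoder.

    Defaults: 2 graph-convolution layers per half (gene width -> ``d_hidden``
    -> ``d_ST``), ELU on hidden layers, Adam at ``learning_rate`` for
    ``epochs`` full-batch steps.
    """

    d_hidden: int = 128
    d_ST: int = 32
    n_layers: int = 2
    activation: str = "elu"
    epochs: int = 500
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_ST < 2:
            raise ValidationError(f"d_ST must be >= 2, got {self.d_ST}")
        if self.epochs < 1:
            raise ValidationError(f"epochs must be >= 1, got {self.epochs}")
        if self.n_layers < 1:
            raise ValidationError(f"n_layers must be >= 1, got {self.n_layers}")
        if self.activation not in _ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")


@dataclass
class TrainingTrace:
    """Per-epoch reconstruction loss values."""

    losses: list[float] = field(default_factory=list)


def _layer_widths(m: int, cfg: EncoderConfig) -> list[int]:
    """Encoder widths m -> hidden... -> d_ST (decoder mirrors the reverse)."""
    if cfg.n_layers == 1:
        return [m, cfg.d_ST]
    widths = [m] + [cfg.d_hidden] * (cfg.n_layers - 1) + [cfg.d_ST]
    return widths


def _glorot(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out))


def train_spatial_encoder(
    X_norm: ExpressionMatrix, A_hat: sparse.spmatrix, config: EncoderConfig | None = None
) -> tuple[SpotEmbedding, TrainingTrace]:
    """Train the GCN autoencoder; return latent embeddings and the loss trace.

    The latent embedding is the final encoder output after training (one
    forward pass with the converged weights).  Bit-reproducible for a fixed
    ``config.seed`` on one machine.
    """
    config = config or EncoderConfig()
    X = X_norm.values
    n, m = X.shape
    if A_hat.shape != (n, n):
        raise ValidationError(f"A_hat shape {A_hat.shape} does not match {n} spots")
    A_hat = sparse.csr_matrix(A_hat, dtype=np.float64)

    widths = _layer_widths(m, config)
    enc_dims = list(zip(widths[:-1], widths[1:]))
    dec_dims = [(b, a) for a, b in reversed(enc_dims)]
    dims = enc_dims + dec_dims
    n_enc = len(enc_dims)

    rng = np.random.default_rng(config.seed)
    Ws = [_glorot(rng, a, b) for a, b in dims]
    # hidden layers use config.activation; the latent layer and the output
    # reconstruction layer are linear
    acts = []
    for li in range(len(dims)):
        is_latent = li == n_enc - 1
        is_output = li == len(dims) - 1
        acts.append("identity" if (is_latent or is_output) else config.activation)

    mom = [np.zeros_like(W) for W in Ws]
    vel = [np.zeros_like(W) for W in Ws]
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr, wd = config.learning_rate, config.weight_decay

    trace = TrainingTrace()
    for epoch in range(config.epochs):
        # forward
        H = X
        caches = []  # (S = A_hat H, Z = S W) per layer
        for W, act in zip(Ws, acts):
            S = np.asarray(A_hat @ H)
            Z = S @ W
            caches.append((S, Z))
            H = _act(Z, act)
        recon = H
        diff = recon - X
        loss = float(np.mean(diff ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite reconstruction loss at epoch {epoch}; "
                "try a lower learning_rate"
            )
        trace.losses.append(loss)

        # backward
        G = (2.0 / diff.size) * diff
        grads: list[np.ndarray] = [None] * len(Ws)  # type: ignore[list-item]
        for li in range(len(Ws) - 1, -1, -1):
            S, Z = caches[li]
            dZ = G * _act_grad(Z, acts[li])
            grads[li] = S.T @ dZ
            if li > 0:
                G = np.asarray(A_hat @ (dZ @ Ws[li].T))

        # Adam
        t = epoch + 1
        for li, (W, g) in enumerate(zip(Ws, grads)):
            if wd:
                g = g + wd * W
            mom[li] = b1 * mom[li] + (1 - b1) * g
            vel[li] = b2 * vel[li] + (1 - b2) * g * g
            m_hat = mom[li] / (1 - b1 ** t)
            v_hat = vel[li] / (1 - b2 ** t)
            Ws[li] = W - lr * m_hat / (np.sqrt(v_hat) + eps)

    # final encoder forward with converged weights
    H = X
    for li in range(n_enc):
        H = gcn_layer(H, A_hat, Ws[li], acts[li])
    return SpotEmbedding(matrix=H, stream="spatial"), trace
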