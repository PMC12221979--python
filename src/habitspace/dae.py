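"""Disentangling autoencoder (DAE) over cubic voxel grids.

The model is a 3-D convolutional autoencoder whose encoder output passes
through an *exactly orthogonal* learned linear map before becoming the
latent vector.  The orthogonal map is parameterized as a product of Givens
(plane) rotations over all d(d-1)/2 latent index pairs — an Euler-angle
style factorization of SO(d) — so orthogonality holds by construction at
every training step and gradients flow through the rotation angles.  The
constraint keeps the latent dimensions linearly independent, which is what
lets individual dimensions align with independent factors of shape
variation (aspect ratios, in practice).

Architecture (side 32, default): a stack of stride-2 kernel-2 3-D
convolutions 32 -> 16 -> 8 -> 4 -> 2 with channel widths ``conv_channels``
and ReLU activations, a linear head to the latent dimension, the Givens
orthogonal map, then a mirrored transposed-convolution decoder with a
sigmoid output in [0, 1].  A stride-2 kernel-2 convolution partitions the
grid into disjoint 2x2x2 blocks and applies one linear map per block, so
every layer is an exact blockwise matrix product — the whole network runs
on BLAS without a deep-learning framework.  Training uses Adam on a
per-voxel binary cross-entropy (or squared-error) objective.

Reconstruction quality is measured with 3-D SSIM and normalized
cross-correlation (NCC), both in [-1, 1] with 1 meaning identity.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity

from .voxelize import VoxelGrid


@dataclasses.dataclass
class DAEConfig:
    """Hyperparameters of the DAE.

    ``conv_channels`` sets both the depth (one stride-2 stage per entry)
    and the widths; the grid side must be divisible by 2**len(conv_channels).
    """

    grid_side: int = 32
    latent_dim: int = 6
    conv_channels: tuple[int, ...] = (8, 16, 32, 64)
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    loss: str = "bce"  # "bce" or "mse"

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.loss not in ("bce", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        for name in ("grid_side", "epochs", "batch_size", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        depth = len(self.conv_channels)
        if self.grid_side % (2**depth):
            raise ValueError(
                f"grid side {self.grid_side} not divisible by 2**{depth}"
            )

    @property
    def final_side(self) -> int:
        return self.grid_side // (2 ** len(self.conv_channels))

    @property
    def flat_dim(self) -> int:
        return self.final_side**3 * self.conv_channels[-1]

    @property
    def n_angles(self) -> int:
        return self.latent_dim * (self.latent_dim - 1) // 2


# ---------------------------------------------------------------------------
# Euler/Givens orthogonal map


def givens_pairs(d: int) -> list[tuple[int, int]]:
    """The fixed (i, j) plane order of the rotation factorization."""
    return [(i, j) for i in range(d) for j in range(i + 1, d)]


def euler_orthogonal_map(angles: np.ndarray, d: int | None = None) -> np.ndarray:
    """Orthogonal d x d matrix as an ordered product of Givens rotations.

    ``angles`` must have length d(d-1)/2; the all-zero vector gives the
    identity.  The result satisfies R^T R = I up to floating round-off.
    """
    angles = np.asarray(angles, dtype=float)
    if d is None:
        d = int(round((1 + np.sqrt(1 + 8 * len(angles))) / 2))
    pairs = givens_pairs(d)
    if len(angles) != len(pairs):
        raise ValueError(
            f"need {len(pairs)} angles for dimension {d}, got {len(angles)}"
        )
    R = np.eye(d)
    for (i, j), th in zip(pairs, angles):
        G = np.eye(d)
        c, s = np.cos(th), np.sin(th)
        G[i, i] = c
        G[j, j] = c
        G[i, j] = -s
        G[j, i] = s
        R = R @ G
    return R


def _givens_factors(angles: np.ndarray, d: int) -> list[np.ndarray]:
    mats = []
    for (i, j), th in zip(givens_pairs(d), angles):
        G = np.eye(d)
        c, s = np.cos(th), np.sin(th)
        G[i, i] = c
        G[j, j] = c
        G[i, j] = -s
        G[j, i] = s
        mats.append(G)
    return mats


def _angle_gradient(
    angles: np.ndarray, d: int, M: np.ndarray
) -> np.ndarray:
    """Gradient of sum_b dz_b . (R z0_b) w.r.t. the angles.

    ``M`` is the d x d accumulation Z0^T dZ; the gradient of angle k is
    trace(P_left dG_k P_right M) with P_left/P_right the partial products
    around factor k.
    """
    pairs = givens_pairs(d)
    factors = _givens_factors(angles, d)
    K = len(factors)
    prefix = [np.eye(d)]
    for G in factors:
        prefix.append(prefix[-1] @ G)
    suffix = [np.eye(d)] * (K + 1)
    for k in range(K - 1, -1, -1):
        suffix[k] = factors[k] @ suffix[k + 1]
    grad = np.zeros(K)
    for k, ((i, j), th) in enumerate(zip(pairs, angles)):
        c, s = np.cos(th), np.sin(th)
        Q = suffix[k + 1] @ M @ prefix[k]  # trace(dG Q) below
        grad[k] = -s * Q[i, i] - s * Q[j, j] - c * Q[j, i] + c * Q[i, j]
    return grad


# ---------------------------------------------------------------------------
# Blockwise conv primitives (stride-2, kernel-2 <=> disjoint 2x2x2 blocks)


def _to_blocks(x: np.ndarray) -> np.ndarray:
    """(B, D, D, D, C) -> (B, D/2, D/2, D/2, 8C) gathering 2x2x2 blocks."""
    b, d, _, _, c = x.shape
    n = d // 2
    x = x.reshape(b, n, 2, n, 2, n, 2, c)
    x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    return x.reshape(b, n, n, n, 8 * c)


def _from_blocks(x: np.ndarray, c: int) -> np.ndarray:
    """Inverse of :func:`_to_blocks`."""
    b, n, _, _, _ = x.shape
    x = x.reshape(b, n, n, n, 2, 2, 2, c)
    x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7)
    return x.reshape(b, 2 * n, 2 * n, 2 * n, c)


def _matmul_last(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    shp = x.shape
    return (x.reshape(-1, shp[-1]) @ W).reshape(*shp[:-1], W.shape[1])


class DisentanglingAutoencoder:
    """A trained or trainable DAE; see the module docstring for the design."""

    def __init__(self, config: DAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cc = config.conv_channels
        enc_in = [1] + list(cc[:-1])
        self.params: dict[str, np.ndarray] = {}

        def he(fan_in: int, shape) -> np.ndarray:
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float64)

        for k, (ci, co) in enumerate(zip(enc_in, cc)):
            self.params[f"We{k}"] = he(8 * ci, (8 * ci, co))
            self.params[f"be{k}"] = np.zeros(co)
        self.params["Wz"] = he(config.flat_dim, (config.flat_dim, config.latent_dim))
        self.params["bz"] = np.zeros(config.latent_dim)
        self.params["angles"] = rng.uniform(-0.1, 0.1, config.n_angles)
        self.params["Wd"] = he(config.latent_dim, (config.latent_dim, config.flat_dim))
        self.params["bd"] = np.zeros(config.flat_dim)
        dec_out = list(reversed(enc_in))  # ... -> 1 channel
        dec_in = list(reversed(cc))
        for k, (ci, co) in enumerate(zip(dec_in, dec_out)):
            self.params[f"Wu{k}"] = he(ci, (ci, 8 * co))
            self.params[f"bu{k}"] = np.zeros(co)
        self._n_dec = len(dec_in)

    # -- forward -----------------------------------------------------------

    def orthogonal_matrix(self) -> np.ndarray:
        return euler_orthogonal_map(self.params["angles"], self.config.latent_dim)

    def gram_deviation(self) -> float:
        R = self.orthogonal_matrix()
        return float(np.abs(R.T @ R - np.eye(self.config.latent_dim)).max())

    def _encode_forward(self, x: np.ndarray, cache: list | None = None):
        cc = self.config.conv_channels
        h = x[..., None]
        for k in range(len(cc)):
            blocks = _to_blocks(h)
            pre = _matmul_last(blocks, self.params[f"We{k}"]) + self.params[f"be{k}"]
            h = np.maximum(pre, 0.0)
            if cache is not None:
                cache.append(("conv", k, blocks, pre))
        flat = h.reshape(h.shape[0], -1)
        z0 = flat @ self.params["Wz"] + self.params["bz"]
        R = self.orthogonal_matrix()
        z = z0 @ R.T
        if cache is not None:
            cache.append(("head", flat, z0, R))
        return z

    def _decode_forward(self, z: np.ndarray, cache: list | None = None):
        cfg = self.config
        pre_h = z @ self.params["Wd"] + self.params["bd"]
        h = np.maximum(pre_h, 0.0)
        fs = cfg.final_side
        x = h.reshape(-1, fs, fs, fs, cfg.conv_channels[-1])
        if cache is not None:
            cache.append(("dense_dec", z, pre_h, h.shape))
        for k in range(self._n_dec):
            W = self.params[f"Wu{k}"]
            co = W.shape[1] // 8
            pre = _matmul_last(x, W)
            up = _from_blocks(pre, co) + self.params[f"bu{k}"]
            last = k == self._n_dec - 1
            out = up if last else np.maximum(up, 0.0)
            if cache is not None:
                cache.append(("deconv", k, x, up, co))
            x = out
        return x[..., 0]  # logits, (B, D, D, D)

    def encode(self, grids: np.ndarray | VoxelGrid) -> np.ndarray:
        """Latent vectors for a (B, D, D, D) batch or a single grid."""
        x, single = self._as_batch(grids)
        z = self._encode_forward(x)
        return z[0] if single else z

    def decode(self, z: np.ndarray) -> np.ndarray | VoxelGrid:
        """Decoded volumes in [0, 1] for latent vectors (B, d) or (d,)."""
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        logits = self._decode_forward(np.atleast_2d(z))
        probs = _sigmoid(logits)
        if single:
            return VoxelGrid(np.clip(probs[0], 0.0, 1.0), binary=False)
        return probs

    def reconstruct(self, grids: np.ndarray | VoxelGrid) -> np.ndarray | VoxelGrid:
        x, single = self._as_batch(grids)
        probs = _sigmoid(self._decode_forward(self._encode_forward(x)))
        if single:
            return VoxelGrid(np.clip(probs[0], 0.0, 1.0), binary=False)
        return probs

    def _as_batch(self, grids) -> tuple[np.ndarray, bool]:
        if isinstance(grids, VoxelGrid):
            arr, single = grids.values[None], True
        else:
            arr = np.asarray(grids, dtype=float)
            single = arr.ndim == 3
            if single:
                arr = arr[None]
        if arr.shape[1] != self.config.grid_side:
            raise ValueError(
                f"model expects side {self.config.grid_side}, got {arr.shape[1]}"
            )
        return arr.astype(np.float64), single

    # -- backward ----------------------------------------------------------

    def _loss_and_grads(self, x: np.ndarray):
        cfg = self.config
        enc_cache: list = []
        dec_cache: list = []
        z = self._encode_forward(x, enc_cache)
        logits = self._decode_forward(z, dec_cache)
        n = logits.size
        if cfg.loss == "bce":
            loss = float(
                np.mean(
                    np.maximum(logits, 0.0)
                    - logits * x
                    + np.log1p(np.exp(-np.abs(logits)))
                )
            )
            dlogits = (_sigmoid(logits) - x) / n
        else:
            p = _sigmoid(logits)
            loss = float(np.mean((p - x) ** 2))
            dlogits = 2.0 * (p - x) * p * (1.0 - p) / n
        grads: dict[str, np.ndarray] = {}

        # decoder backward
        dx = dlogits[..., None]
        for k in range(self._n_dec - 1, -1, -1):
            _, _, x_in, up, co = dec_cache[1 + k]
            if k != self._n_dec - 1:
                dx = dx * (up > 0)
            grads[f"bu{k}"] = dx.sum(axis=(0, 1, 2, 3))
            dpre = _to_blocks(dx)
            W = self.params[f"Wu{k}"]
            grads[f"Wu{k}"] = (
                x_in.reshape(-1, W.shape[0]).T @ dpre.reshape(-1, W.shape[1])
            )
            dx = _matmul_last(dpre, W.T)
        _, z_in, pre_h, h_shape = dec_cache[0]
        dh = dx.reshape(dx.shape[0], -1)
        dh = dh * (pre_h > 0)
        grads["Wd"] = z_in.T @ dh
        grads["bd"] = dh.sum(axis=0)
        dz = dh @ self.params["Wd"].T

        # orthogonal map backward
        _, flat, z0, R = enc_cache[-1]
        grads["angles"] = _angle_gradient(
            self.params["angles"], cfg.latent_dim, z0.T @ dz
        )
        dz0 = dz @ R
        grads["Wz"] = flat.T @ dz0
        grads["bz"] = dz0.sum(axis=0)
        dflat = dz0 @ self.params["Wz"].T

        # encoder conv backward
        fs = cfg.final_side
        dx = dflat.reshape(-1, fs, fs, fs, cfg.conv_channels[-1])
        for k in range(len(cfg.conv_channels) - 1, -1, -1):
            _, _, blocks, pre = enc_cache[k]
            dx = dx * (pre > 0)
            grads[f"be{k}"] = dx.sum(axis=(0, 1, 2, 3))
            W = self.params[f"We{k}"]
            grads[f"We{k}"] = (
                blocks.reshape(-1, W.shape[0]).T @ dx.reshape(-1, W.shape[1])
            )
            dblocks = _matmul_last(dx, W.T)
            dx = _from_blocks(dblocks, dblocks.shape[-1] // 8)
        return loss, grads

    # -- training ----------------------------------------------------------

    def train(
        self,
        data: np.ndarray,
        epochs: int | None = None,
        verbose: bool = False,
    ) -> dict[str, list[float]]:
        """Adam training; returns per-epoch loss and per-step Gram deviation.

        ``data`` is a (N, D, D, D) array of [0, 1] voxel grids.  The loss
        history has one entry per epoch; ``gram_dev`` records the maximum
        deviation of R^T R from the identity after every optimizer step.
        Raises on an empty dataset or a non-finite loss.
        """
        cfg = self.config
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 4 or data.shape[0] == 0:
            raise ValueError("training data must be a non-empty (N, D, D, D) array")
        epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed + 1)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(vv) for k, vv in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        history: dict[str, list[float]] = {"loss": [], "gram_dev": []}
        n = data.shape[0]
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                batch = data[order[start : start + cfg.batch_size]]
                loss, grads = self._loss_and_grads(batch)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, step {t}"
                    )
                t += 1
                for key, g in grads.items():
                    m[key] = beta1 * m[key] + (1 - beta1) * g
                    v[key] = beta2 * v[key] + (1 - beta2) * g * g
                    mhat = m[key] / (1 - beta1**t)
                    vhat = v[key] / (1 - beta2**t)
                    self.params[key] = self.params[key] - cfg.learning_rate * mhat / (
                        np.sqrt(vhat) + eps
                    )
                epoch_losses.append(loss)
                history["gram_dev"].append(self.gram_deviation())
            history["loss"].append(float(np.mean(epoch_losses)))
            if verbose:
                print(
                    f"epoch {epoch + 1}/{epochs}  loss {history['loss'][-1]:.5f}  "
                    f"gram {history['gram_dev'][-1]:.2e}"
                )
        return history

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        cfg = dataclasses.asdict(self.config)
        cfg["conv_channels"] = list(cfg["conv_channels"])
        np.savez(path, __config__=json.dumps(cfg), **self.params)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "DisentanglingAutoencoder":
        with np.load(path, allow_pickle=False) as blob:
            cfg = json.loads(str(blob["__config__"]))
            cfg["conv_channels"] = tuple(cfg["conv_channels"])
            model = cls(DAEConfig(**cfg))
            for key in model.params:
                model.params[key] = blob[key]
        return model

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def build_model(config: DAEConfig) -> DisentanglingAutoencoder:
    """Construct a DAE with seeded initial parameters."""
    return DisentanglingAutoencoder(config)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Reconstruction metrics


def _values(a: np.ndarray | VoxelGrid) -> np.ndarray:
    return a.values if isinstance(a, VoxelGrid) else np.asarray(a, dtype=float)


def ssim3d(
    a: np.ndarray | VoxelGrid, b: np.ndarray | VoxelGrid, win_size: int = 7
) -> float:
    """Mean local structural similarity over 3-D volumes, in [-1, 1].

    Uniform ``win_size``-cubed windows, stabilization constants
    (0.01 * range)^2 and (0.03 * range)^2 with range fixed at 1 (the voxel
    value range).  Symmetric in its arguments; 1.0 iff the volumes agree.
    """
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch: {va.shape} vs {vb.shape}")
    return float(
        structural_similarity(
            va, vb, win_size=win_size, data_range=1.0, gaussian_weights=False
        )
    )


def ncc(a: np.ndarray | VoxelGrid, b: np.ndarray | VoxelGrid) -> float:
    """Normalized cross-correlation: Pearson r of the flattened volumes."""
    va, vb = _values(a).ravel(), _values(b).ravel()
    if va.shape != vb.shape:
        raise ValueError("shape mismatch")
    va = va - va.mean()
    vb = vb - vb.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("NCC is undefined for constant volumes")
    return float(np.clip(va @ vb / (na * nb), -1.0, 1.0))
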