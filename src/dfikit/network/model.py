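"""Autoencoder--autoregression estimator of the latent order parameter.

A denoising autoencoder compresses the 12 scaled CBC features to a
4-dimensional bottleneck ``y = phi(x)``; a linear projector ``A`` maps the
bottleneck to the scalar dynamic frailty indicator (dFI); a linear
autoregression ``z_{n+1} = r z_n + z'`` ties same-animal visits separated by
the sampling interval; a lift ``B`` returns the propagated scalar to the
bottleneck for decoding.  ``A`` and ``B`` are softly constrained to be left
and right eigenvectors of the latent dynamics (``A B = 1``, ``|B| = 1``).

The total training loss is

    L = a1 (L_AE + L_pred) + a2 L_AR + a3 L_C + a4 ||W||^2

with ``a1, a3, a4 = 1, 100, 0.01`` and ``a2`` ramped from 0 to 1.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .autodiff import Adam, Tensor, leaky_relu

__all__ = ["NetworkConfig", "AEARModel", "build_model", "compute_losses", "train"]


@dataclass
class NetworkConfig:
    input_dim: int = 12
    latent_dim: int = 4
    hidden_width: int = 64
    n_resnet_blocks: int = 2
    leaky_slope: float = 0.2
    alpha1: float = 1.0
    alpha2_max: float = 1.0
    alpha2_ramp_epochs: int = 300
    alpha3: float = 100.0
    alpha4: float = 0.01
    epochs: int = 600
    lr_initial: float = 1e-3
    lr_final: float = 1e-4
    lr_switch_epoch: int = 400
    batch_size: int = 256
    pair_interval: float = 26.0
    pair_tolerance: float = 4.0
    age_window: tuple = (26.0, 104.0)
    corruption_sd: float = 0.0  # denoising corruption in scaled units; off by default
    grad_clip: float = 10.0
    #: per-epoch exact (least-squares) refresh of the AR coefficients; the
    #: AR loss is quadratic in (r, z'), so this is block-coordinate descent
    #: on the same objective and removes their slow gradient crawl
    ar_exact_refresh: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim >= self.input_dim:
            raise ValueError("latent_dim must be smaller than input_dim")
        if self.latent_dim != 4:
            warnings.warn(
                "latent_dim != 4 deviates from the reference configuration",
                RuntimeWarning,
                stacklevel=2,
            )


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        s = scale if scale is not None else math.sqrt(2.0 / n_in)
        self.W = Tensor(rng.standard_normal((n_in, n_out)) * s, requires_grad=True)
        self.b = Tensor(np.zeros((1, n_out)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.data + self.b.data

    def params(self):
        return [self.W, self.b]


class ResBlock:
    """Two dense layers with leaky-ReLU activations and a skip connection.

    With all inner weights and biases zero the block is the identity map.
    """

    def __init__(self, width: int, slope: float, rng: np.random.Generator):
        self.d1 = Dense(width, width, rng)
        self.d2 = Dense(width, width, rng, scale=math.sqrt(2.0 / width) * 0.1)
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        h = leaky_relu(self.d1(x), self.slope)
        h = leaky_relu(self.d2(h), self.slope)
        return x + h

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        def lrelu(a):
            return np.where(a > 0, a, self.slope * a)

        h = lrelu(self.d1.forward_np(x))
        h = lrelu(self.d2.forward_np(h))
        return x + h

    def params(self):
        return self.d1.params() + self.d2.params()


class AEARModel:
    """Encoder/decoder stacks plus projector, lift and AR coefficients."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.Generator(np.random.Philox(config.seed))
        c = config
        self.encoder = (
            [Dense(c.input_dim, c.hidden_width, rng)]
            + [ResBlock(c.hidden_width, c.leaky_slope, rng)
               for _ in range(c.n_resnet_blocks)]
            + [Dense(c.hidden_width, c.latent_dim, rng)]
        )
        self.decoder = (
            [Dense(c.latent_dim, c.hidden_width, rng)]
            + [ResBlock(c.hidden_width, c.leaky_slope, rng)
               for _ in range(c.n_resnet_blocks)]
            + [Dense(c.hidden_width, c.input_dim, rng)]
        )
        # projector A (1 x latent) stored column-wise; lift B (latent x 1)
        # stored row-wise, matching row-major batches.
        a0 = rng.standard_normal((c.latent_dim, 1)) / math.sqrt(c.latent_dim)
        self.A = Tensor(a0, requires_grad=True)
        self.B = Tensor(a0.T.copy(), requires_grad=True)
        self.r = Tensor(np.array([[1.0]]), requires_grad=True)
        self.shift = Tensor(np.array([[0.0]]), requires_grad=True)
        self.sign = 1.0
        self.scaler_mean: Optional[np.ndarray] = None
        self.scaler_scale: Optional[np.ndarray] = None
        self.history: list[dict] = []

    # -- parameter access ------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for layer in self.encoder + self.decoder:
            ps += layer.params()
        ps += [self.A, self.B, self.r, self.shift]
        return ps

    def weight_matrices(self) -> list[Tensor]:
        return [
            layer.params()[i]
            for layer in self.encoder + self.decoder
            for i in range(0, len(layer.params()), 2)
        ]

    # -- scaling ---------------------------------------------------------
    def fit_scaler(self, X: np.ndarray) -> None:
        self.scaler_mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.scaler_scale = np.where(sd > 0, sd, 1.0)

    def scale(self, X: np.ndarray) -> np.ndarray:
        if self.scaler_mean is None:
            raise RuntimeError("scaler not fitted")
        return (X - self.scaler_mean) / self.scaler_scale

    def unscale(self, X: np.ndarray) -> np.ndarray:
        return X * self.scaler_scale + self.scaler_mean

    # -- graph forward ---------------------------------------------------
    def encode_t(self, x: Tensor) -> Tensor:
        for layer in self.encoder:
            x = layer(x)
        return x

    def decode_t(self, y: Tensor) -> Tensor:
        for layer in self.decoder:
            y = layer(y)
        return y

    # -- numpy forward (inference) ---------------------------------------
    def encode(self, X_scaled: np.ndarray) -> np.ndarray:
        x = np.asarray(X_scaled, dtype=float)
        for layer in self.encoder:
            x = layer.forward_np(x)
        return x

    def decode(self, Y: np.ndarray) -> np.ndarray:
        y = np.asarray(Y, dtype=float)
        for layer in self.decoder:
            y = layer.forward_np(y)
        return y

    def dfi_scaledX(self, X_scaled: np.ndarray) -> np.ndarray:
        return self.sign * (self.encode(X_scaled) @ self.A.data).ravel()

    def dfi(self, X_raw: np.ndarray) -> np.ndarray:
        return self.dfi_scaledX(self.scale(np.asarray(X_raw, dtype=float)))

    def reconstruct(self, X_raw: np.ndarray) -> np.ndarray:
        Xs = self.scale(np.asarray(X_raw, dtype=float))
        return self.unscale(self.decode(self.encode(Xs)))

    @property
    def ar_r(self) -> float:
        return self.r.data.item()

    @property
    def ar_shift(self) -> float:
        return self.shift.data.item()

    def constraint_residuals(self) -> tuple[float, float]:
        ab = (self.B.data @ self.A.data).item()
        bn = float(np.sqrt((self.B.data**2).sum()))
        return abs(ab - 1.0), abs(bn - 1.0)

    # -- persistence ------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": asdict(self.config),
            "sign": self.sign,
            "scaler_mean": None if self.scaler_mean is None else self.scaler_mean.tolist(),
            "scaler_scale": None if self.scaler_scale is None else self.scaler_scale.tolist(),
            "A": self.A.data.tolist(),
            "B": self.B.data.tolist(),
            "r": self.ar_r,
            "shift": self.ar_shift,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        arrays = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"p{i}"] = p.data
        np.savez(out / "weights.npz", **arrays)

    @classmethod
    def load(cls, in_dir: str | Path) -> "AEARModel":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        cfg = manifest["config"]
        cfg["age_window"] = tuple(cfg["age_window"])
        model = cls(NetworkConfig(**cfg))
        with np.load(src / "weights.npz") as arrays:
            for i, p in enumerate(model.parameters()):
                p.data = arrays[f"p{i}"].copy()
        model.sign = manifest["sign"]
        if manifest["scaler_mean"] is not None:
            model.scaler_mean = np.asarray(manifest["scaler_mean"])
            model.scaler_scale = np.asarray(manifest["scaler_scale"])
        return model


def build_model(config: NetworkConfig) -> AEARModel:
    """Construct an untrained model; identical seeds give identical weights."""
    return AEARModel(config)


def compute_losses(
    model: AEARModel,
    cross_batch: np.ndarray,
    pair_batch: Optional[tuple[np.ndarray, np.ndarray]] = None,
    corruption_rng: Optional[np.random.Generator] = None,
) -> dict[str, Tensor]:
    """Loss components on pre-scaled batches.

    Returns a dict with Tensors ``L_AE, L_pred, L_AR, L_C, L2`` (prediction
    and AR terms are zero Tensors when no pair batch is given).
    """
    x = Tensor(cross_batch)
    x_in = x
    if corruption_rng is not None and model.config.corruption_sd > 0:
        x_in = x + Tensor(
            corruption_rng.standard_normal(cross_batch.shape)
            * model.config.corruption_sd
        )
    recon = model.decode_t(model.encode_t(x_in))
    l_ae = (x - recon).square().mean()

    if pair_batch is not None:
        xn = Tensor(pair_batch[0])
        xn1 = Tensor(pair_batch[1])
        yn = model.encode_t(xn)
        yn1 = model.encode_t(xn1)
        zn = yn @ model.A
        zn1 = yn1 @ model.A
        z_next = model.r * zn + model.shift
        l_ar = (zn1 - z_next).square().mean()
        x_pred = model.decode_t(z_next @ model.B)
        l_pred = (xn1 - x_pred).square().mean()
    else:
        l_ar = Tensor(0.0)
        l_pred = Tensor(0.0)

    ab = model.B @ model.A
    l_c = (ab - 1.0).square().sum() + (model.B.square().sum() - 1.0).square()

    l2 = Tensor(0.0)
    for w in model.weight_matrices():
        l2 = l2 + w.square().sum()

    for name, t in (("L_AE", l_ae), ("L_pred", l_pred), ("L_AR", l_ar),
                    ("L_C", l_c), ("L2", l2)):
        if not np.isfinite(t.data).all():
            raise FloatingPointError(f"non-finite loss component {name}")
    return {"L_AE": l_ae, "L_pred": l_pred, "L_AR": l_ar, "L_C": l_c, "L2": l2}


def train(
    model: AEARModel,
    cross_data: np.ndarray,
    pairs: tuple[np.ndarray, np.ndarray],
    ages_cross: Optional[np.ndarray] = None,
    config: Optional[NetworkConfig] = None,
) -> AEARModel:
    """Optimise the joint loss on raw-unit inputs.

    ``cross_data`` is (n, 12) in original units; ``pairs`` is a tuple of two
    aligned (m, 12) arrays (present and future same-animal records).  The
    per-feature scaler is fitted on the cross-sectional data.  ``ages_cross``
    (when given) fixes the dFI sign so it correlates non-negatively with age.
    """
    cfg = config or model.config
    cross_data = np.asarray(cross_data, dtype=float)
    if cross_data.size == 0:
        raise ValueError("cross_data must be non-empty")
    xn_raw, xn1_raw = pairs
    xn_raw = np.asarray(xn_raw, dtype=float)
    xn1_raw = np.asarray(xn1_raw, dtype=float)
    if xn_raw.shape[0] < 1:
        raise ValueError("at least one longitudinal pair is required")

    model.fit_scaler(cross_data)
    Xc = model.scale(cross_data)
    Xn = model.scale(xn_raw)
    Xn1 = model.scale(xn1_raw)

    rng = np.random.Generator(np.random.Philox([cfg.seed, 0xAEA2]))
    params = model.parameters()
    opt = Adam(params, lr=cfg.lr_initial, clip_norm=cfg.grad_clip)

    n_cross, n_pair = Xc.shape[0], Xn.shape[0]
    bs = cfg.batch_size
    steps = max(1, int(np.ceil(n_cross / bs)))
    initial_total = None

    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_initial if epoch < cfg.lr_switch_epoch else cfg.lr_final
        ramp = min(1.0, epoch / max(cfg.alpha2_ramp_epochs, 1))
        a2 = cfg.alpha2_max * ramp
        ep_losses = np.zeros(5)
        for _ in range(steps):
            ci = rng.integers(0, n_cross, size=min(bs, n_cross))
            pi = rng.integers(0, n_pair, size=min(bs, n_pair))
            losses = compute_losses(
                model, Xc[ci], (Xn[pi], Xn1[pi]),
                corruption_rng=rng if cfg.corruption_sd > 0 else None,
            )
            total = (
                cfg.alpha1 * (losses["L_AE"] + losses["L_pred"])
                + a2 * losses["L_AR"]
                + cfg.alpha3 * losses["L_C"]
                + cfg.alpha4 * losses["L2"]
            )
            if initial_total is None:
                initial_total = total.item()
            if total.item() > 10.0 * max(initial_total, 1e-12) and epoch > 10:
                raise RuntimeError(
                    f"training diverged (loss {total.item():.3g} vs initial "
                    f"{initial_total:.3g}); seed={cfg.seed}, config={cfg}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_losses += [losses[k].item() for k in
                          ("L_AE", "L_pred", "L_AR", "L_C", "L2")]
        if cfg.ar_exact_refresh and a2 > 0:
            zn = (model.encode(Xn) @ model.A.data).ravel()
            zn1 = (model.encode(Xn1) @ model.A.data).ravel()
            var = zn.var()
            if var > 1e-12:
                r_opt = np.cov(zn, zn1)[0, 1] / var
                model.r.data[...] = r_opt
                model.shift.data[...] = zn1.mean() - r_opt * zn.mean()
        ep_losses /= steps
        model.history.append(
            {"epoch": epoch, "lr": opt.lr, "alpha2": a2,
             "L_AE": ep_losses[0], "L_pred": ep_losses[1],
             "L_AR": ep_losses[2], "L_C": ep_losses[3], "L2": ep_losses[4]}
        )

    if ages_cross is not None:
        dfi = model.dfi_scaledX(Xc)
        if np.std(dfi) > 0 and np.std(ages_cross) > 0:
            c = np.corrcoef(dfi, np.asarray(ages_cross, float))[0, 1]
            model.sign = -1.0 if c < 0 else 1.0
    return model
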