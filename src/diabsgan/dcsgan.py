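"""Semi-supervised GAN classifier for tabular data.

The model couples a standard GAN with an auxiliary classifier:

* a **generator** G maps latent noise z to a feature vector x̂;
* a **discriminator** with a shared trunk and two heads: an adversarial
  head D(x) ∈ (0, 1) scoring real-vs-generated, and a classification head
  C(x) producing class probabilities over the real classes.

Training alternates two updates per minibatch.  The discriminator step
pushes D(x) toward 1 on real samples and D(G(z)) toward 0 on generated
ones, while simultaneously minimizing λ-weighted categorical cross-entropy
of C on the *real, labeled* samples — generated samples carry no class
label and influence C only through the shared trunk.  The generator step
uses the non-saturating objective, maximizing E[log D(G(z))], the standard
remedy for vanishing gradients early in training.

The value function being contested is

    V(D, G, C) = E[log D(x)] + E[log(1 − D(G(z)))] + λ·L_C(C(x), y)

with L_C the mean categorical cross-entropy (−1/N Σ Σ y log p).  The
adversarial game shapes the trunk's representation of the data manifold;
the classification head rides on that representation, which is where the
semi-supervised benefit comes from.

Everything is plain NumPy with hand-written backpropagation: the networks
are small multilayer perceptrons (leaky-ReLU hidden units, slope 0.2) and
the optimizer is Adam with β1 = 0.5, the usual choice for GAN stability.
Features are standardized (zero mean, unit variance, fit on the training
data) before entering either network; the generator emits values in
standardized space and samples are mapped back on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_config import TabularDataset

__all__ = [
    "DCSGANConfig",
    "TrainedDCSGAN",
    "classifier_loss",
    "adversarial_value",
    "combined_objective",
    "train_dcsgan",
    "predict",
    "generate_samples",
]

EPS = 1e-7  # probability clamp inside logs


# ------------------------------------------------------------------- losses

def classifier_loss(class_probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy −1/N Σ log p(true class).

    Probabilities are clamped to [EPS, 1] inside the log so a zero
    probability at the true class yields a large finite loss, never inf.
    """
    class_probs = np.asarray(class_probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = class_probs.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels length must match class_probs rows")
    if labels.min() < 0 or labels.max() >= class_probs.shape[1]:
        raise ValueError("label out of range")
    p_true = class_probs[np.arange(n), labels]
    return float(-np.mean(np.log(np.clip(p_true, EPS, 1.0))))


def adversarial_value(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """GAN value E[log D(x)] + E[log(1 − D(G(z)))] with sample means."""
    d_real = np.asarray(d_real, dtype=float)
    d_fake = np.asarray(d_fake, dtype=float)
    if ((d_real <= 0) | (d_real >= 1)).any() or ((d_fake <= 0) | (d_fake >= 1)).any():
        raise ValueError("discriminator outputs must lie strictly in (0, 1)")
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


def combined_objective(
    d_real: np.ndarray,
    d_fake: np.ndarray,
    class_probs: np.ndarray,
    labels: np.ndarray,
    lambda_c: float,
) -> tuple[float, float]:
    """Adversarial value plus λ-weighted classification loss on real samples.

    Returns ``(value_V, loss_C)``; with λ = 0 the value reduces exactly to
    the plain GAN objective.
    """
    loss_c = classifier_loss(class_probs, labels)
    value = adversarial_value(d_real, d_fake) + lambda_c * loss_c
    return value, loss_c


# ------------------------------------------------------------ configuration

@dataclass
class DCSGANConfig:
    latent_dim: int = 64
    gen_hidden: tuple[int, ...] = (128, 128)
    disc_hidden: tuple[int, ...] = (128, 64)
    lambda_c: float = 1.0
    learning_rate: float = 2e-4
    epochs: int = 300
    batch_size: int = 64
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.gen_hidden = tuple(int(w) for w in self.gen_hidden)
        self.disc_hidden = tuple(int(w) for w in self.disc_hidden)
        if any(w < 1 for w in self.gen_hidden + self.disc_hidden):
            raise ValueError("all layer widths must be >= 1")
        if self.latent_dim < 1 or self.n_classes < 2:
            raise ValueError("latent_dim >= 1 and n_classes >= 2 required")
        if not np.isfinite(self.lambda_c) or self.lambda_c < 0:
            raise ValueError("lambda_c must be finite and >= 0")


# ----------------------------------------------------- network building blocks

LEAK = 0.2


def _leaky(a: np.ndarray) -> np.ndarray:
    return np.where(a > 0, a, LEAK * a)


def _leaky_grad(a: np.ndarray) -> np.ndarray:
    return np.where(a > 0, 1.0, LEAK)


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int) -> list[np.ndarray]:
    scale = np.sqrt(2.0 / fan_in)
    return [rng.normal(0.0, scale, size=(fan_in, fan_out)), np.zeros(fan_out)]


class _MLPTrunk:
    """Hidden stack with leaky-ReLU activations and manual backprop."""

    def __init__(self, rng: np.random.Generator, in_dim: int, hidden: tuple[int, ...]):
        self.params: list[list[np.ndarray]] = []
        d = in_dim
        for h in hidden:
            self.params.append(_init_linear(rng, d, h))
            d = h
        self.out_dim = d

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        cache = []
        h = x
        for W, b in self.params:
            a = h @ W + b
            cache.append((h, a))
            h = _leaky(a)
        return h, cache

    def backward(self, grad_h: np.ndarray, cache: list) -> tuple[list, np.ndarray]:
        """Return per-layer [dW, db] plus the gradient w.r.t. the input."""
        grads: list[list[np.ndarray]] = [None] * len(self.params)  # type: ignore
        g = grad_h
        for i in range(len(self.params) - 1, -1, -1):
            h_in, a = cache[i]
            W, _ = self.params[i]
            ga = g * _leaky_grad(a)
            grads[i] = [h_in.T @ ga, ga.sum(axis=0)]
            g = ga @ W.T
        return grads, g


class _Adam:
    """Adam with β1 tuned for adversarial training."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class _Generator:
    def __init__(self, rng: np.random.Generator, cfg: DCSGANConfig, p: int):
        self.trunk = _MLPTrunk(rng, cfg.latent_dim, cfg.gen_hidden)
        self.out = _init_linear(rng, self.trunk.out_dim, p)

    def forward(self, z: np.ndarray) -> tuple[np.ndarray, tuple]:
        h, cache = self.trunk.forward(z)
        W, b = self.out
        return h @ W + b, (h, cache)

    def backward(self, grad_x: np.ndarray, cache: tuple) -> list[np.ndarray]:
        h, trunk_cache = cache
        W, _ = self.out
        g_out = [h.T @ grad_x, grad_x.sum(axis=0)]
        trunk_grads, _ = self.trunk.backward(grad_x @ W.T, trunk_cache)
        return self.flatten_like(trunk_grads, g_out)

    def flatten_like(self, trunk_grads, out_grad) -> list[np.ndarray]:
        flat = [g for layer in trunk_grads for g in layer]
        return flat + out_grad

    @property
    def flat_params(self) -> list[np.ndarray]:
        return [p for layer in self.trunk.params for p in layer] + self.out


class _Discriminator:
    """Shared trunk with a sigmoid adversarial head and a softmax class head."""

    def __init__(self, rng: np.random.Generator, cfg: DCSGANConfig, p: int):
        self.trunk = _MLPTrunk(rng, p, cfg.disc_hidden)
        self.adv = _init_linear(rng, self.trunk.out_dim, 1)
        self.cls = _init_linear(rng, self.trunk.out_dim, cfg.n_classes)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple]:
        h, cache = self.trunk.forward(x)
        Wa, ba = self.adv
        s = (h @ Wa + ba).ravel()
        d = 1.0 / (1.0 + np.exp(-s))
        Wc, bc = self.cls
        logits = h @ Wc + bc
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return d, probs, (h, cache)

    def backward(
        self,
        grad_s: np.ndarray | None,
        grad_logits: np.ndarray | None,
        cache: tuple,
    ) -> tuple[list[np.ndarray], np.ndarray]:
        """Backprop from head pre-activations; returns flat grads + input grad."""
        h, trunk_cache = cache
        grad_h = np.zeros_like(h)
        if grad_s is not None:
            Wa, _ = self.adv
            g_adv = [h.T @ grad_s[:, None], np.array([grad_s.sum()])]
            grad_h += grad_s[:, None] @ Wa.T
        else:
            g_adv = [np.zeros_like(self.adv[0]), np.zeros_like(self.adv[1])]
        if grad_logits is not None:
            Wc, _ = self.cls
            g_cls = [h.T @ grad_logits, grad_logits.sum(axis=0)]
            grad_h += grad_logits @ Wc.T
        else:
            g_cls = [np.zeros_like(self.cls[0]), np.zeros_like(self.cls[1])]
        trunk_grads, grad_x = self.trunk.backward(grad_h, trunk_cache)
        flat = [g for layer in trunk_grads for g in layer] + g_adv + g_cls
        return flat, grad_x

    @property
    def flat_params(self) -> list[np.ndarray]:
        return [p for layer in self.trunk.params for p in layer] + self.adv + self.cls


# ------------------------------------------------------------- trained model

@dataclass
class TrainedDCSGAN:
    config: DCSGANConfig
    generator: _Generator
    discriminator: _Discriminator
    mean: np.ndarray
    scale: np.ndarray
    classes: np.ndarray  # original label codes, sorted
    history: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        """Serialize parameters, config and standardizer to one .npz file."""
        arrays: dict[str, np.ndarray] = {
            "mean": self.mean, "scale": self.scale, "classes": self.classes,
        }
        for i, p in enumerate(self.generator.flat_params):
            arrays[f"g{i}"] = p
        for i, p in enumerate(self.discriminator.flat_params):
            arrays[f"d{i}"] = p
        cfg = self.config
        arrays["cfg"] = np.array([
            cfg.latent_dim, cfg.lambda_c, cfg.learning_rate, cfg.epochs,
            cfg.batch_size, cfg.n_classes, cfg.seed,
        ])
        arrays["gen_hidden"] = np.array(cfg.gen_hidden)
        arrays["disc_hidden"] = np.array(cfg.disc_hidden)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedDCSGAN":
        data = np.load(path)
        c = data["cfg"]
        cfg = DCSGANConfig(
            latent_dim=int(c[0]), gen_hidden=tuple(data["gen_hidden"]),
            disc_hidden=tuple(data["disc_hidden"]), lambda_c=float(c[1]),
            learning_rate=float(c[2]), epochs=int(c[3]), batch_size=int(c[4]),
            n_classes=int(c[5]), seed=int(c[6]),
        )
        p = data["mean"].shape[0]
        rng = np.random.default_rng(0)
        model = cls(
            config=cfg,
            generator=_Generator(rng, cfg, p),
            discriminator=_Discriminator(rng, cfg, p),
            mean=data["mean"], scale=data["scale"], classes=data["classes"],
        )
        for i, pm in enumerate(model.generator.flat_params):
            pm[...] = data[f"g{i}"]
        for i, pm in enumerate(model.discriminator.flat_params):
            pm[...] = data[f"d{i}"]
        return model

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


# ----------------------------------------------------------------- training

def train_dcsgan(dataset: TabularDataset, config: DCSGANConfig | None = None) -> TrainedDCSGAN:
    """Adversarially train generator and two-headed discriminator.

    Per minibatch: (1) a discriminator/classifier step decreasing
    −E[log D(x)] − E[log(1 − D(G(z)))] + λ·CE(C(x), y); (2) a generator step
    decreasing −E[log D(G(z))] (non-saturating).  History records per-epoch
    mean losses and training accuracy.  Identical seeds yield identical
    histories and parameters.
    """
    if dataset.labels is None:
        raise ValueError("training requires a labeled dataset")
    config = config or DCSGANConfig()
    x_raw = dataset.features
    n, p = x_raw.shape
    if config.epochs > 0 and n < config.batch_size:
        raise ValueError("n_samples must be >= batch_size")

    classes = np.unique(dataset.labels)
    if classes.size > config.n_classes:
        raise ValueError(
            f"{classes.size} classes in data exceed n_classes={config.n_classes}"
        )
    y = np.searchsorted(classes, dataset.labels)

    mean = x_raw.mean(axis=0)
    scale = x_raw.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    x = (x_raw - mean) / scale

    rng = np.random.default_rng(config.seed)
    gen = _Generator(rng, config, p)
    disc = _Discriminator(rng, config, p)
    opt_g = _Adam(gen.flat_params, config.learning_rate)
    opt_d = _Adam(disc.flat_params, config.learning_rate)

    model = TrainedDCSGAN(
        config=config, generator=gen, discriminator=disc,
        mean=mean, scale=scale, classes=classes,
    )

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_d, ep_g, ep_c, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            m = len(idx)

            # --- discriminator/classifier step
            z = rng.standard_normal((m, config.latent_dim))
            x_fake, _ = gen.forward(z)
            d_real, probs, cache_r = disc.forward(xb)
            d_fake, _, cache_f = disc.forward(x_fake)

            d_real_c = np.clip(d_real, EPS, 1 - EPS)
            d_fake_c = np.clip(d_fake, EPS, 1 - EPS)
            loss_adv = float(-np.mean(np.log(d_real_c)) - np.mean(np.log(1 - d_fake_c)))
            onehot = np.zeros_like(probs)
            onehot[np.arange(m), yb] = 1.0
            loss_cls = classifier_loss(probs, yb)

            # d(-log σ(s))/ds = σ(s) − 1 ; d(-log(1−σ(s)))/ds = σ(s)
            grad_s_real = (d_real - 1.0) / m
            grad_logits = config.lambda_c * (probs - onehot) / m
            g_real, _ = disc.backward(grad_s_real, grad_logits, cache_r)
            grad_s_fake = d_fake / m
            g_fake, _ = disc.backward(grad_s_fake, None, cache_f)
            opt_d.step([a + b for a, b in zip(g_real, g_fake)])

            # --- generator step (non-saturating)
            z = rng.standard_normal((m, config.latent_dim))
            x_fake, cache_g = gen.forward(z)
            d_fake, _, cache_f = disc.forward(x_fake)
            d_fake_c = np.clip(d_fake, EPS, 1 - EPS)
            loss_g = float(-np.mean(np.log(d_fake_c)))
            grad_s = (d_fake - 1.0) / m
            _, grad_x = disc.backward(grad_s, None, cache_f)
            opt_g.step(gen.backward(grad_x, cache_g))

            if not (np.isfinite(loss_adv) and np.isfinite(loss_g) and np.isfinite(loss_cls)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"D={loss_adv} G={loss_g} C={loss_cls}"
                )
            ep_d += loss_adv
            ep_g += loss_g
            ep_c += loss_cls
            n_batches += 1

        _, probs_all, _ = disc.forward(x)
        acc = float(np.mean(probs_all.argmax(axis=1) == y))
        model.history.append({
            "epoch": epoch,
            "loss_D": ep_d / n_batches,
            "loss_G": ep_g / n_batches,
            "loss_C": ep_c / n_batches,
            "train_accuracy": acc,
        })
    return model


# ---------------------------------------------------------------- inference

def predict(model: TrainedDCSGAN, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class predictions and probabilities from the classification head.

    Ties in the probability row break toward the lowest class code.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"expected {model.mean.shape[0]} features, got shape {features.shape}"
        )
    x = (features - model.mean) / model.scale
    _, probs, _ = model.discriminator.forward(x)
    probs = probs[:, : len(model.classes)]
    probs = probs / probs.sum(axis=1, keepdims=True)
    labels = model.classes[probs.argmax(axis=1)]
    return labels, probs


def generate_samples(model: TrainedDCSGAN, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` synthetic rows from the generator, in original feature scale."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.config.latent_dim))
    x_std, _ = model.generator.forward(z)
    return x_std * model.scale + model.mean
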