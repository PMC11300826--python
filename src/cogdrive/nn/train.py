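"""Training loop, inference helpers and checkpointing for the variational
recurrent encoder."""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np

from cogdrive.data import CognitiveProfile, TrajectorySnippet
from cogdrive.nn.autodiff import Tensor
from cogdrive.nn.layers import Decoder, Encoder, LatentEncoding
from cogdrive.nn.losses import (
    contrastive_loss,
    kl_regularizer,
    reconstruction_loss,
    total_loss,
)

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "train_encoder",
    "encode",
    "encode_batch",
    "sample_latent",
    "decode_action",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainingConfig:
    alpha1: float = 1.0
    alpha2: float = 1.0
    alpha3: float = 0.1
    epsilon: float = 1.0
    latent_dim: int = 2
    hidden_size: int = 64
    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 200
    seed: int = 0
    distance_measure: str = "euclidean"
    decoder_hidden: int = 32

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.alpha3) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


class _Adam:
    def __init__(self, params: list[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedModel:
    """Encoder + decoder parameters plus the config they were trained with."""

    encoder: Encoder
    decoder: Decoder
    config: TrainingConfig
    factor_names: list[str] = field(default_factory=list)
    loss_history: list[dict] = field(default_factory=list)


def _stack_batches(snippets: list[TrajectorySnippet],
                   profiles: dict[str, CognitiveProfile],
                   factor_names: list[str]):
    X = np.stack([s.channels for s in snippets])
    A = np.stack([s.action for s in snippets])
    Y = np.stack([profiles[s.subject_id].z_vector(factor_names) for s in snippets])
    return X, A, Y


def train_encoder(
    snippets: list[TrajectorySnippet],
    profiles: list[CognitiveProfile] | dict[str, CognitiveProfile],
    config: TrainingConfig,
    factor_names: list[str] | None = None,
) -> TrainedModel:
    """Train the encoder/decoder pair on labeled trajectory snippets.

    Each snippet is tagged with its subject's standardized cognitive-measure
    vector (the contrastive target) and its next-step action (the
    reconstruction target).  Fully seeded; aborts on non-finite loss.
    """
    if isinstance(profiles, list):
        profiles = {p.subject_id: p for p in profiles}
    subjects = {s.subject_id for s in snippets}
    if len(subjects) < 2:
        raise ValueError("training requires snippets from at least 2 subjects")
    missing = subjects - set(profiles)
    if missing:
        raise ValueError(f"snippets reference unknown subjects: {sorted(missing)}")
    if factor_names is None:
        factor_names = sorted(next(iter(profiles.values())).standardized)

    rng = np.random.default_rng(config.seed)
    n_channels = snippets[0].channels.shape[1]
    encoder = Encoder(n_channels, config.hidden_size, config.latent_dim, rng)
    decoder = Decoder(config.latent_dim, config.decoder_hidden, 2, rng)
    params = encoder.parameters() + decoder.parameters()
    opt = _Adam(params, config.learning_rate)

    X, A, Y = _stack_batches(snippets, profiles, factor_names)
    n = len(snippets)
    bs = min(config.batch_size, n)
    history: list[dict] = []

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep = {"total": 0.0, "recon": 0.0, "contrastive": 0.0, "kl": 0.0}
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start: start + bs]
            if len(idx) < 2:
                continue  # contrastive term needs at least a pair
            xb = Tensor(X[idx])
            mu, logvar = encoder(xb)
            noise = rng.standard_normal(mu.data.shape)
            z = mu + (logvar * 0.5).exp() * noise
            a_mu, a_logvar = decoder(z)
            l1 = reconstruction_loss(A[idx], a_mu, a_logvar)
            l2 = contrastive_loss(z, Y[idx], config.epsilon,
                                  config.distance_measure)
            l3 = kl_regularizer(mu, logvar)
            loss = total_loss(l1, l2, l3, config.alpha1, config.alpha2,
                              config.alpha3)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: recon={l1.data:.4g} "
                    f"contrastive={l2.data:.4g} kl={l3.data:.4g}")
            for p in params:
                p.zero_grad()
            loss.backward()
            opt.step()
            ep["total"] += float(loss.data)
            ep["recon"] += float(l1.data)
            ep["contrastive"] += float(l2.data)
            ep["kl"] += float(l3.data)
            n_batches += 1
        history.append({k: v / max(n_batches, 1) for k, v in ep.items()})

    return TrainedModel(encoder=encoder, decoder=decoder, config=config,
                        factor_names=list(factor_names), loss_history=history)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def encode(snippet: TrajectorySnippet, encoder: Encoder) -> LatentEncoding:
    """Deterministic posterior parameters for one snippet."""
    if snippet.channels.shape[1] != encoder.n_channels:
        raise ValueError(
            f"snippet has {snippet.channels.shape[1]} channels, encoder expects "
            f"{encoder.n_channels}")
    mu, logvar = encoder(Tensor(snippet.channels[None]))
    return LatentEncoding(mean=mu.data[0], log_variance=logvar.data[0])


def encode_batch(snippets: list[TrajectorySnippet], encoder: Encoder) -> np.ndarray:
    """Latent means for a list of snippets, stacked (N, d)."""
    X = np.stack([s.channels for s in snippets])
    mu, _ = encoder(Tensor(X))
    return mu.data


def sample_latent(encoding: LatentEncoding, seed: int | np.random.Generator) -> np.ndarray:
    """Reparameterized draw z = mu + exp(lv/2) * eps, seeded."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(encoding.mean.shape)
    return encoding.mean + np.exp(0.5 * encoding.log_variance) * eps


def decode_action(z: np.ndarray, decoder: Decoder) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian over the next-step action: (mean, variance) per channel."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    mu, logvar = decoder(Tensor(z))
    return mu.data[0], np.exp(logvar.data[0])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: TrainedModel, path, extra_meta: dict | None = None) -> None:
    """Parameter archive (NPZ) plus JSON metadata."""
    path = pathlib.Path(path)
    arrays = model.encoder.state_arrays() + model.decoder.state_arrays()
    np.savez(path.with_suffix(".npz"),
             **{f"p{i}": a for i, a in enumerate(arrays)})
    meta = {
        "config": asdict(model.config),
        "factor_names": model.factor_names,
        "n_channels": model.encoder.n_channels,
        "loss_history": model.loss_history,
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_checkpoint(path) -> TrainedModel:
    path = pathlib.Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = TrainingConfig(**meta["config"])
    rng = np.random.default_rng(0)
    encoder = Encoder(meta["n_channels"], config.hidden_size, config.latent_dim, rng)
    decoder = Decoder(config.latent_dim, config.decoder_hidden, 2, rng)
    with np.load(path.with_suffix(".npz")) as z:
        arrays = [z[f"p{i}"] for i in range(len(z.files))]
    k = len(encoder.parameters())
    encoder.load_arrays(arrays[:k])
    decoder.load_arrays(arrays[k:])
    return TrainedModel(encoder=encoder, decoder=decoder, config=config,
                        factor_names=meta["factor_names"],
                        loss_history=meta.get("loss_history", []))
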