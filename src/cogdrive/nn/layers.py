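"""Recurrent variational encoder and Gaussian action decoder."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cogdrive.nn.autodiff import Tensor

__all__ = ["LatentEncoding", "Linear", "LSTM", "Encoder", "Decoder", "LOGVAR_CLAMP"]

#: numerical-stability clamp for every log-variance head
LOGVAR_CLAMP = (-10.0, 10.0)


@dataclass
class LatentEncoding:
    """Gaussian posterior over the latent: mean and log-variance vectors."""

    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.log_variance = np.atleast_1d(np.asarray(self.log_variance, dtype=float))
        if self.mean.shape != self.log_variance.shape:
            raise ValueError("mean and log_variance must have the same shape")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.log_variance))):
            raise ValueError("encoding must be finite")

    @property
    def dim(self) -> int:
        return self.mean.shape[-1]


class Module:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=float)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.uniform(-scale, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class LSTM(Module):
    """Single-layer LSTM; consumes (B, T, C) and returns the final hidden state.

    Gate order in the fused weight matrices is input, forget, cell, output;
    the forget-gate bias is initialized to one.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(hidden)
        self.Wx = Tensor(rng.uniform(-scale, scale, (n_in, 4 * hidden)), requires_grad=True)
        self.Wh = Tensor(rng.uniform(-scale, scale, (hidden, 4 * hidden)), requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden: 2 * hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)
        self.hidden = hidden
        self.n_in = n_in

    def __call__(self, x: Tensor) -> Tensor:
        """Run the recurrence as one fused graph node (hand-written BPTT).

        Building per-timestep autodiff nodes dominates runtime for long
        windows; the fused forward caches gate activations and the backward
        closure replays them in reverse.
        """
        if x.data.ndim != 3 or x.data.shape[2] != self.n_in:
            raise ValueError(
                f"expected input (B, T, {self.n_in}), got {x.data.shape}")
        B, T, _ = x.data.shape
        H = self.hidden
        Wx, Wh, b = self.Wx, self.Wh, self.b
        X = x.data

        # precompute the input projection for every step at once
        xproj = X.reshape(B * T, -1) @ Wx.data
        xproj = xproj.reshape(B, T, 4 * H)

        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        for t in range(T):
            a = xproj[:, t, :] + h @ Wh.data + b.data
            i = sig(a[:, :H])
            f = sig(a[:, H: 2 * H])
            g = np.tanh(a[:, 2 * H: 3 * H])
            o = sig(a[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            cache.append((h_prev, c_prev, i, f, g, o, tc))

        out = Tensor(h)
        out.requires_grad = (Wx.requires_grad or Wh.requires_grad
                             or b.requires_grad or x.requires_grad)
        if not out.requires_grad:
            return out
        out._parents = (x, Wx, Wh, b)

        def backward():
            dh = out.grad
            dWx = np.zeros_like(Wx.data)
            dWh = np.zeros_like(Wh.data)
            db = np.zeros_like(b.data)
            dX = np.zeros_like(X) if x.requires_grad else None
            dc = np.zeros((B, H))
            da = np.empty((B, 4 * H))
            for t in range(T - 1, -1, -1):
                h_prev, c_prev, i, f, g, o, tc = cache[t]
                dc = dc + dh * o * (1.0 - tc**2)
                da[:, :H] = dc * g * i * (1.0 - i)
                da[:, H: 2 * H] = dc * c_prev * f * (1.0 - f)
                da[:, 2 * H: 3 * H] = dc * i * (1.0 - g**2)
                da[:, 3 * H:] = dh * tc * o * (1.0 - o)
                dWx += X[:, t, :].T @ da
                dWh += h_prev.T @ da
                db += da.sum(axis=0)
                if dX is not None:
                    dX[:, t, :] = da @ Wx.data.T
                dh = da @ Wh.data.T
                dc = dc * f
            Wx._accum(dWx)
            Wh._accum(dWh)
            b._accum(db)
            if dX is not None:
                x._accum(dX)

        out._backward = backward
        return out

    def parameters(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]


class Encoder(Module):
    """q(z | trajectory window): LSTM followed by linear mean / log-variance heads."""

    def __init__(self, n_channels: int, hidden: int, latent_dim: int,
                 rng: np.random.Generator):
        self.lstm = LSTM(n_channels, hidden, rng)
        self.head_mean = Linear(hidden, latent_dim, rng)
        self.head_logvar = Linear(hidden, latent_dim, rng)
        self.latent_dim = latent_dim
        self.n_channels = n_channels

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.lstm(x)
        mu = self.head_mean(h)
        logvar = self.head_logvar(h).clip(*LOGVAR_CLAMP)
        return mu, logvar

    def parameters(self) -> list[Tensor]:
        return self.lstm.parameters() + self.head_mean.parameters() + \
            self.head_logvar.parameters()


class Decoder(Module):
    """p(a | z): small MLP producing a Gaussian over the next-step action."""

    def __init__(self, latent_dim: int, hidden: int, action_dim: int,
                 rng: np.random.Generator):
        self.fc1 = Linear(latent_dim, hidden, rng)
        self.head_mean = Linear(hidden, action_dim, rng)
        self.head_logvar = Linear(hidden, action_dim, rng)
        self.latent_dim = latent_dim
        self.action_dim = action_dim

    def __call__(self, z: Tensor) -> tuple[Tensor, Tensor]:
        if z.data.shape[-1] != self.latent_dim:
            raise ValueError(
                f"expected latent dim {self.latent_dim}, got {z.data.shape[-1]}")
        h = self.fc1(z).tanh()
        mu = self.head_mean(h)
        logvar = self.head_logvar(h).clip(*LOGVAR_CLAMP)
        return mu, logvar

    def parameters(self) -> list[Tensor]:
        return self.fc1.parameters() + self.head_mean.parameters() + \
            self.head_logvar.parameters()
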