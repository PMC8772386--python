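"""Character-level LSTM language model over the DNA alphabet.

Architecture: an embedding table maps each base index to a dense vector; a
single unidirectional LSTM consumes the embedded context left-to-right with
zero-initialised state; the final hidden state feeds a 4-way dense layer
whose softmax output is the predictive distribution over the next base.

The model is trained by minimising categorical cross-entropy with Adam.
Everything is implemented directly in NumPy so that training and
prediction are deterministic for a fixed seed on a given machine: forward,
backpropagation through time, and the Adam update live in this module.
Parameters and activations are float32 (input projections are batched into
single GEMMs across all timesteps); predictive distributions are returned
in float64 with the softmax taken in float64, so downstream scoring is
numerically clean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

ALPHABET_SIZE = 4


@dataclass(frozen=True)
class ModelConfig:
    """Model hyperparameters.

    embedding_dim
        Length of the per-base embedding vector (default 128).
    recurrent_units
        Number of LSTM units (default 512).
    learning_rate, beta1, beta2, epsilon
        Adam optimiser settings; standard out-of-the-box defaults.
    """

    embedding_dim: int = 128
    recurrent_units: int = 512
    alphabet_size: int = ALPHABET_SIZE
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.embedding_dim < 1 or self.recurrent_units < 1:
            raise ValueError(
                f"embedding_dim and recurrent_units must be >= 1, got "
                f"{self.embedding_dim} and {self.recurrent_units}"
            )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class ModelState:
    """Parameters and optimiser state of one per-gap language model.

    Weight layout (H = recurrent units, E = embedding dim); gates are
    ordered input, forget, cell, output along the 4H axis:

    - ``emb``: (4, E) embedding table (index lookup)
    - ``Wx``: (E, 4H), ``Wh``: (H, 4H), ``b``: (4H,) LSTM weights
    - ``Wy``: (H, 4), ``by``: (4,) dense output layer

    Initialisation is Glorot-uniform for input kernels, orthogonal for the
    recurrent kernel, zeros for biases with the forget-gate bias set to 1.
    """

    PARAM_NAMES = ("emb", "Wx", "Wh", "b", "Wy", "by")

    def __init__(self, config: ModelConfig, seed: int):
        self.config = config
        self.rng_seed = int(seed)
        rng = np.random.default_rng(seed)
        E, H = config.embedding_dim, config.recurrent_units
        A = config.alphabet_size

        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-limit, limit, size=shape)

        def orthogonal(rows, cols):
            # block-orthogonal per gate, the conventional recurrent init
            blocks = []
            for _ in range(cols // rows):
                a = rng.standard_normal((rows, rows))
                q, r = np.linalg.qr(a)
                q *= np.sign(np.diag(r))
                blocks.append(q)
            return np.concatenate(blocks, axis=1)

        self.params: dict[str, np.ndarray] = {
            "emb": rng.uniform(-0.05, 0.05, size=(A, E)).astype(np.float32),
            "Wx": glorot((E, 4 * H)).astype(np.float32),
            "Wh": orthogonal(H, 4 * H).astype(np.float32),
            "b": np.zeros(4 * H, dtype=np.float32),
            "Wy": glorot((H, A)).astype(np.float32),
            "by": np.zeros(A, dtype=np.float32),
        }
        self.params["b"][H : 2 * H] = 1.0  # forget-gate bias
        # Adam moments
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0

    # ------------------------------------------------------------------ #
    # incremental interface (used by beam search and sequence scoring)
    # ------------------------------------------------------------------ #
    def initial_state(self, batch: int = 1) -> tuple[np.ndarray, np.ndarray]:
        H = self.config.recurrent_units
        return (
            np.zeros((batch, H), dtype=np.float32),
            np.zeros((batch, H), dtype=np.float32),
        )

    def step(
        self, state: tuple[np.ndarray, np.ndarray], base_indices: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Advance the recurrent state by one base per batch row."""
        h, c = state
        H = self.config.recurrent_units
        p = self.params
        x = p["emb"][base_indices]
        z = x @ p["Wx"] + h @ p["Wh"] + p["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        return h_new, c_new

    def output_distribution(self, state: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
        """Softmax next-base distribution from the current hidden state.

        Logits are cast to float64 before the softmax so distributions are
        exact where the logits are (e.g. all-zero logits → exactly 0.25).
        """
        h, _ = state
        logits = (h @ self.params["Wy"] + self.params["by"]).astype(np.float64)
        return softmax(logits)

    def consume(self, context: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Feed an encoded context (1-D) and return the resulting state."""
        ctx = np.asarray(context, dtype=np.int64).reshape(1, -1)
        state = self.initial_state(1)
        for t in range(ctx.shape[1]):
            state = self.step(state, ctx[:, t])
        return state

    # ------------------------------------------------------------------ #
    # whole-sequence scoring
    # ------------------------------------------------------------------ #
    def stepwise_distributions(self, sequences: np.ndarray) -> np.ndarray:
        """Predictive distributions after every prefix of each sequence.

        ``sequences``: (B, T) encoded. Returns (B, T, 4) where entry
        ``[b, t]`` is the distribution over the base at position t+1 given
        bases 0..t of sequence b.
        """
        seqs = np.atleast_2d(np.asarray(sequences, dtype=np.int64))
        B, T = seqs.shape
        state = self.initial_state(B)
        out = np.empty((B, T, ALPHABET_SIZE))
        for t in range(T):
            state = self.step(state, seqs[:, t])
            out[:, t] = self.output_distribution(state)
        return out

    # ------------------------------------------------------------------ #
    # training
    # ------------------------------------------------------------------ #
    def next_base_distribution(self, context: np.ndarray) -> np.ndarray:
        """P(next base | context) as a length-4 probability vector."""
        context = np.asarray(context, dtype=np.int64)
        if context.ndim != 1 or context.size < 1:
            raise ValueError("context must be a non-empty 1-D index sequence")
        return self.output_distribution(self.consume(context))[0]

    def _forward_batch(self, contexts: np.ndarray):
        """Full forward pass with caches for BPTT.

        The input projection ``emb[contexts] @ Wx`` for all timesteps is
        one GEMM; only the recurrent part loops over time.
        """
        p = self.params
        H = self.config.recurrent_units
        B, T = contexts.shape
        x_all = p["emb"][contexts]  # (B, T, E)
        zx_all = x_all.reshape(B * T, -1) @ p["Wx"]
        zx_all = zx_all.reshape(B, T, 4 * H) + p["b"]
        h = np.zeros((B, H), dtype=np.float32)
        c = np.zeros((B, H), dtype=np.float32)
        gates = np.empty((T, B, 4 * H), dtype=np.float32)  # i, f, g, o
        h_prev = np.empty((T, B, H), dtype=np.float32)
        c_prev = np.empty((T, B, H), dtype=np.float32)
        tanh_c = np.empty((T, B, H), dtype=np.float32)
        for t in range(T):
            z = zx_all[:, t] + h @ p["Wh"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            gates[t, :, :H] = i
            gates[t, :, H : 2 * H] = f
            gates[t, :, 2 * H : 3 * H] = g
            gates[t, :, 3 * H :] = o
            h_prev[t] = h
            c_prev[t] = c
            c = f * c + i * g
            tanh_c[t] = np.tanh(c)
            h = o * tanh_c[t]
        logits = h @ p["Wy"] + p["by"]
        cache = (x_all, gates, h_prev, c_prev, tanh_c)
        return h, logits, cache

    def training_step(self, contexts: np.ndarray, targets: np.ndarray) -> float:
        """One Adam update on a batch of equal-length contexts.

        Returns the mean categorical cross-entropy of the batch evaluated
        *before* the parameter update. Contexts must form a rectangular
        array: within one batch all training sequences have uniform length.
        """
        if isinstance(contexts, (list, tuple)):
            lengths = {len(c) for c in contexts}
            if len(lengths) > 1:
                raise ValueError(
                    f"ragged batch: context lengths {sorted(lengths)}; training "
                    "sequences must have uniform length within a batch"
                )
            contexts = np.asarray(contexts, dtype=np.int64)
        contexts = np.asarray(contexts, dtype=np.int64)
        targets = np.asarray(targets, dtype=np.int64)
        if contexts.ndim != 2:
            raise ValueError("contexts must be a (batch, k) integer array")
        B, T = contexts.shape
        if targets.shape != (B,) or B < 1:
            raise ValueError("targets must be one base index per context")

        p = self.params
        H = self.config.recurrent_units
        E = self.config.embedding_dim
        h_final, logits, cache = self._forward_batch(contexts)
        x_all, gates, h_prev, c_prev, tanh_c = cache
        probs = softmax(logits.astype(np.float64))
        loss = float(-np.mean(np.log(probs[np.arange(B), targets] + 1e-300)))

        dlogits = probs.copy()
        dlogits[np.arange(B), targets] -= 1.0
        dlogits = (dlogits / B).astype(np.float32)
        grads = {
            "Wy": h_final.T @ dlogits,
            "by": dlogits.sum(axis=0),
        }
        dh = dlogits @ p["Wy"].T
        dc = np.zeros((B, H), dtype=np.float32)
        dz_all = np.empty((T, B, 4 * H), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :H]
            f = gates[t, :, H : 2 * H]
            g = gates[t, :, 2 * H : 3 * H]
            o = gates[t, :, 3 * H :]
            tc = tanh_c[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            dz = dz_all[t]
            dz[:, :H] = dc * g * i * (1.0 - i)
            dz[:, H : 2 * H] = dc * c_prev[t] * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dc * i * (1.0 - g**2)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            dh = dz @ p["Wh"].T
            dc = dc * f
        dz_flat = dz_all.transpose(1, 0, 2).reshape(B * T, 4 * H)
        grads["Wx"] = x_all.reshape(B * T, E).T @ dz_flat
        grads["Wh"] = h_prev.transpose(1, 0, 2).reshape(B * T, H).T @ dz_flat
        grads["b"] = dz_flat.sum(axis=0)
        dx_flat = dz_flat @ p["Wx"].T  # (B*T, E)
        onehot = np.eye(p["emb"].shape[0], dtype=np.float32)[contexts.reshape(-1)]
        grads["emb"] = onehot.T @ dx_flat

        self._adam_update(grads)
        return loss

    def _adam_update(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.config
        self._t += 1
        lr_t = cfg.learning_rate * (
            np.sqrt(1.0 - cfg.beta2**self._t) / (1.0 - cfg.beta1**self._t)
        )
        for k in self.PARAM_NAMES:
            g = grads[k]
            self._m[k] = cfg.beta1 * self._m[k] + (1.0 - cfg.beta1) * g
            self._v[k] = cfg.beta2 * self._v[k] + (1.0 - cfg.beta2) * g**2
            self.params[k] -= lr_t * self._m[k] / (np.sqrt(self._v[k]) + cfg.epsilon)

    # ------------------------------------------------------------------ #
    # parameter snapshots and checkpoints
    # ------------------------------------------------------------------ #
    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def restore(self, snapshot: dict[str, np.ndarray]) -> None:
        for k in self.PARAM_NAMES:
            self.params[k] = snapshot[k].copy()

    def save(self, path: str | Path) -> None:
        meta = {"config": asdict(self.config), "rng_seed": self.rng_seed, "t": self._t}
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.params,
            **{f"m_{k}": v for k, v in self._m.items()},
            **{f"v_{k}": v for k, v in self._v.items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(ModelConfig(**meta["config"]), meta["rng_seed"])
        for k in cls.PARAM_NAMES:
            model.params[k] = data[k]
            model._m[k] = data[f"m_{k}"]
            model._v[k] = data[f"v_{k}"]
        model._t = meta["t"]
        return model


def build_model(config: ModelConfig, seed: int) -> ModelState:
    """Freshly initialise a model; deterministic for a fixed seed."""
    return ModelState(config, seed)
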