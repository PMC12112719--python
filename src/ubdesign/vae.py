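"""LSTM variational autoencoder for scaffold sequence generation.

The generator learns a compressed latent representation of a library of
ubiquitin-scaffold variants and produces de novo sequences by decoding
random latent vectors drawn from N(0, 1).

Architecture
------------
* Encoder: one-hot input (max_len x 21: 20 amino acids + padding token)
  -> LSTM (256 units, last hidden state) -> fully connected 128 (ReLU)
  -> two parallel linear heads for the latent mean and log-variance.
* Decoder: two linear maps take the latent vector to the initial hidden
  and cell states of a 256-unit LSTM; the LSTM runs autoregressively over
  previously emitted tokens and a linear output layer produces 21-way
  logits per position.
* Objective: ELBO = reconstruction cross-entropy (summed over all
  positions, padding included, averaged over the batch) + analytic
  KL(q(z|x) || N(0, I)).  Teacher forcing is used during training.

Generation draws z ~ N(0,1) and decodes with temperature-controlled
softmax sampling; temperature <= 1e-6 degrades to greedy argmax decoding.
Decoding stops at the first padding token.

Implemented in NumPy with hand-written backpropagation (see `_nn`); the
model trains on CPU in minutes at library scale.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _nn
from .constants import AA_ALPHABET
from .seq_data import InvalidSequenceError, SequenceRecord, validate_sequence

PAD = "-"  # padding token, index 20
TOKENS = AA_ALPHABET + PAD
TOKEN_INDEX = {ch: i for i, ch in enumerate(TOKENS)}
PAD_INDEX = TOKEN_INDEX[PAD]

GREEDY_TEMPERATURE = 1e-6


class UntrainedModelError(RuntimeError):
    """Raised when generation is requested from an untrained model."""


@dataclass(frozen=True)
class EncodingSpec:
    """Positional one-hot encoding: max_len positions x 21 symbols."""

    max_len: int = 164

    @property
    def n_tokens(self) -> int:
        return len(TOKENS)

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise ValueError("max_len must be positive")


@dataclass(frozen=True)
class VAEConfig:
    """Model and training hyper-parameters (defaults at library scale)."""

    encoder_lstm_units: int = 256
    encoder_fc_units: int = 128
    latent_dim: int = 128
    decoder_state_units: int = 256
    decoder_lstm_units: int = 256
    learning_rate: float = 1e-3
    max_epochs: int = 200
    early_stop_patience: int = 5
    validation_fraction: float = 0.1
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.encoder_lstm_units,
            self.encoder_fc_units,
            self.latent_dim,
            self.decoder_state_units,
            self.decoder_lstm_units,
        ) < 1:
            raise ValueError("all unit counts must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass(frozen=True)
class GenerationConfig:
    """Sampling parameters: latent vectors come from N(0, 1)."""

    n_sequences: int = 500
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


def one_hot_encode(sequence: str, spec: EncodingSpec) -> np.ndarray:
    """Encode a sequence as a (max_len, 21) one-hot matrix.

    Rows past the sequence end are unit vectors on the padding column, so
    every row sums to one.
    """
    if sequence:
        validate_sequence(sequence)
    if len(sequence) > spec.max_len:
        raise InvalidSequenceError(
            f"sequence length {len(sequence)} exceeds max_len {spec.max_len}"
        )
    mat = np.zeros((spec.max_len, spec.n_tokens))
    for i in range(spec.max_len):
        tok = TOKEN_INDEX[sequence[i]] if i < len(sequence) else PAD_INDEX
        mat[i, tok] = 1.0
    return mat


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of `one_hot_encode`: argmax per row, truncated at the first
    padding token."""
    idx = np.asarray(matrix).argmax(axis=1)
    out = []
    for i in idx:
        if i == PAD_INDEX:
            break
        out.append(TOKENS[i])
    return "".join(out)


def _init_params(cfg: VAEConfig, spec: EncodingSpec, rng: np.random.Generator):
    D = spec.n_tokens
    He, F, Z = cfg.encoder_lstm_units, cfg.encoder_fc_units, cfg.latent_dim
    Hd = cfg.decoder_lstm_units
    p = {
        "enc_lstm_Wx": _nn.glorot(rng, D, 4 * He),
        "enc_lstm_Wh": _nn.glorot(rng, He, 4 * He),
        "enc_lstm_b": np.zeros(4 * He),
        "enc_fc_W": _nn.glorot(rng, He, F),
        "enc_fc_b": np.zeros(F),
        "mu_W": _nn.glorot(rng, F, Z),
        "mu_b": np.zeros(Z),
        "lv_W": _nn.glorot(rng, F, Z),
        "lv_b": np.zeros(Z),
        "dec_h0_W": _nn.glorot(rng, Z, cfg.decoder_state_units),
        "dec_h0_b": np.zeros(cfg.decoder_state_units),
        "dec_c0_W": _nn.glorot(rng, Z, cfg.decoder_state_units),
        "dec_c0_b": np.zeros(cfg.decoder_state_units),
        "dec_lstm_Wx": _nn.glorot(rng, D, 4 * Hd),
        "dec_lstm_Wh": _nn.glorot(rng, Hd, 4 * Hd),
        "dec_lstm_b": np.zeros(4 * Hd),
        "out_W": _nn.glorot(rng, Hd, D),
        "out_b": np.zeros(D),
    }
    # forget-gate bias at 1 helps gradient flow early in training
    for key in ("enc_lstm_b", "dec_lstm_b"):
        H = p[key].shape[0] // 4
        p[key][H : 2 * H] = 1.0
    return p


class GeneratorModel:
    """A (possibly trained) sequence VAE: parameters, encoding spec and
    per-epoch training history."""

    def __init__(self, config: VAEConfig, spec: EncodingSpec, params=None):
        self.config = config
        self.spec = spec
        self.params = params
        self.history: pd.DataFrame | None = None

    @property
    def trained(self) -> bool:
        return self.params is not None and self.history is not None

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, eps: np.ndarray):
        """Full forward pass with teacher forcing.

        Returns per-batch mean reconstruction and KL losses plus the caches
        needed by `_backward`.
        """
        p = self.params
        B = X.shape[0]
        h0 = np.zeros((B, self.config.encoder_lstm_units))
        c0 = np.zeros_like(h0)
        hs_e, (hT, _), cache_e = _nn.lstm_forward(
            X, h0, c0, p["enc_lstm_Wx"], p["enc_lstm_Wh"], p["enc_lstm_b"]
        )
        f_pre, cache_fc = _nn.dense_forward(hT, p["enc_fc_W"], p["enc_fc_b"])
        f = np.maximum(f_pre, 0.0)
        mu, cache_mu = _nn.dense_forward(f, p["mu_W"], p["mu_b"])
        lv, cache_lv = _nn.dense_forward(f, p["lv_W"], p["lv_b"])
        z = mu + eps * np.exp(0.5 * lv)
        dh0, cache_h0 = _nn.dense_forward(z, p["dec_h0_W"], p["dec_h0_b"])
        dc0, cache_c0 = _nn.dense_forward(z, p["dec_c0_W"], p["dec_c0_b"])
        Xin = np.concatenate([np.zeros_like(X[:, :1, :]), X[:, :-1, :]], axis=1)
        hs_d, _, cache_d = _nn.lstm_forward(
            Xin, dh0, dc0, p["dec_lstm_Wx"], p["dec_lstm_Wh"], p["dec_lstm_b"]
        )
        logits, cache_out = _nn.dense_forward(hs_d, p["out_W"], p["out_b"])
        probs = _nn.softmax(logits)
        recon = -np.log(np.clip((probs * X).sum(axis=2), 1e-12, None)).sum(axis=1).mean()
        kl = (-0.5 * (1.0 + lv - mu**2 - np.exp(lv)).sum(axis=1)).mean()
        caches = dict(
            X=X, eps=eps, probs=probs, mu=mu, lv=lv,
            cache_e=cache_e, cache_fc=cache_fc, f_pre=f_pre,
            cache_mu=cache_mu, cache_lv=cache_lv,
            cache_h0=cache_h0, cache_c0=cache_c0,
            cache_d=cache_d, cache_out=cache_out,
        )
        return recon, kl, caches

    def _backward(self, caches):
        p = self.params
        X, probs = caches["X"], caches["probs"]
        B = X.shape[0]
        dlogits = (probs - X) / B
        dhs_d, dW_out, db_out = _nn.dense_backward(dlogits, p["out_W"], caches["cache_out"])
        _, dh0, dc0, dWx_d, dWh_d, db_d = _nn.lstm_backward(
            dhs_d,
            np.zeros_like(dhs_d[:, 0, :]),
            np.zeros_like(dhs_d[:, 0, :]),
            p["dec_lstm_Wx"], p["dec_lstm_Wh"], caches["cache_d"],
        )
        dz_h, dW_h0, db_h0 = _nn.dense_backward(dh0, p["dec_h0_W"], caches["cache_h0"])
        dz_c, dW_c0, db_c0 = _nn.dense_backward(dc0, p["dec_c0_W"], caches["cache_c0"])
        dz = dz_h + dz_c
        mu, lv, eps = caches["mu"], caches["lv"], caches["eps"]
        dmu = dz + mu / B
        dlv = dz * eps * 0.5 * np.exp(0.5 * lv) + 0.5 * (np.exp(lv) - 1.0) / B
        df_mu, dW_mu, db_mu = _nn.dense_backward(dmu, p["mu_W"], caches["cache_mu"])
        df_lv, dW_lv, db_lv = _nn.dense_backward(dlv, p["lv_W"], caches["cache_lv"])
        df = (df_mu + df_lv) * (caches["f_pre"] > 0)
        dhT, dW_fc, db_fc = _nn.dense_backward(df, p["enc_fc_W"], caches["cache_fc"])
        T = X.shape[1]
        dhs_e = np.zeros((B, T, self.config.encoder_lstm_units))
        _, _, _, dWx_e, dWh_e, db_e = _nn.lstm_backward(
            dhs_e, dhT, np.zeros_like(dhT),
            p["enc_lstm_Wx"], p["enc_lstm_Wh"], caches["cache_e"],
        )
        return {
            "enc_lstm_Wx": dWx_e, "enc_lstm_Wh": dWh_e, "enc_lstm_b": db_e,
            "enc_fc_W": dW_fc, "enc_fc_b": db_fc,
            "mu_W": dW_mu, "mu_b": db_mu, "lv_W": dW_lv, "lv_b": db_lv,
            "dec_h0_W": dW_h0, "dec_h0_b": db_h0,
            "dec_c0_W": dW_c0, "dec_c0_b": db_c0,
            "dec_lstm_Wx": dWx_d, "dec_lstm_Wh": dWh_d, "dec_lstm_b": db_d,
            "out_W": dW_out, "out_b": db_out,
        }

    # -- public API ---------------------------------------------------------

    def encode(self, sequence: str) -> np.ndarray:
        """Latent mean of a sequence (deterministic embedding)."""
        self._require_trained()
        X = one_hot_encode(sequence, self.spec)[None]
        p = self.params
        h0 = np.zeros((1, self.config.encoder_lstm_units))
        _, (hT, _), _ = _nn.lstm_forward(
            X, h0, np.zeros_like(h0),
            p["enc_lstm_Wx"], p["enc_lstm_Wh"], p["enc_lstm_b"],
        )
        f = np.maximum(hT @ p["enc_fc_W"] + p["enc_fc_b"], 0.0)
        return (f @ p["mu_W"] + p["mu_b"])[0]

    def decode(
        self,
        z: np.ndarray,
        temperature: float = 1.0,
        rng: np.random.Generator | None = None,
    ) -> str:
        """Autoregressively decode one latent vector into a sequence.

        Temperature-controlled softmax sampling; temperature <= 1e-6 means
        greedy argmax.  Decoding stops at the first padding token or at
        max_len.
        """
        self._require_trained()
        p = self.params
        rng = rng or np.random.default_rng(0)
        z = np.asarray(z, dtype=float).reshape(1, -1)
        h = z @ p["dec_h0_W"] + p["dec_h0_b"]
        c = z @ p["dec_c0_W"] + p["dec_c0_b"]
        x = np.zeros((1, self.spec.n_tokens))
        out: list[str] = []
        for _ in range(self.spec.max_len):
            h, c, _ = _nn.lstm_step(
                x, h, c, p["dec_lstm_Wx"], p["dec_lstm_Wh"], p["dec_lstm_b"]
            )
            logits = (h @ p["out_W"] + p["out_b"])[0]
            if temperature <= GREEDY_TEMPERATURE:
                tok = int(logits.argmax())
            else:
                probs = _nn.softmax(logits / temperature)
                tok = int(rng.choice(self.spec.n_tokens, p=probs))
            if tok == PAD_INDEX:
                break
            out.append(TOKENS[tok])
            x = np.zeros((1, self.spec.n_tokens))
            x[0, tok] = 1.0
        return "".join(out)

    def _require_trained(self) -> None:
        if not self.trained:
            raise UntrainedModelError("model has not been trained or loaded")

    # -- persistence ----------------------------------------------------------

    CHECKPOINT_VERSION = 1

    def save(self, path: str | Path) -> None:
        """Write a single-archive checkpoint (parameters + config + spec +
        history) that reloads bit-identically."""
        self._require_trained()
        meta = {
            "version": self.CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "spec": asdict(self.spec),
            "history": self.history.to_dict(orient="list"),
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            buf = io.BytesIO()
            np.savez(buf, **self.params)
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            with np.load(io.BytesIO(zf.read("params.npz"))) as npz:
                params = {k: npz[k] for k in npz.files}
        model = cls(VAEConfig(**meta["config"]), EncodingSpec(**meta["spec"]), params)
        model.history = pd.DataFrame(meta["history"])
        return model


def train(
    records: Sequence[SequenceRecord] | Sequence[str],
    cfg: VAEConfig | None = None,
    spec: EncodingSpec | None = None,
) -> GeneratorModel:
    """Train the VAE on a sequence library.

    Stops at ``max_epochs`` or when the validation ELBO has not improved for
    ``early_stop_patience`` consecutive epochs; the best-validation weights
    are restored.  Fully deterministic for a fixed config seed.
    """
    cfg = cfg or VAEConfig()
    spec = spec or EncodingSpec()
    seqs = [r.sequence if isinstance(r, SequenceRecord) else r for r in records]
    if len(seqs) < 2:
        raise InvalidSequenceError("need at least 2 sequences to train")
    X = np.stack([one_hot_encode(s, spec) for s in seqs])
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(seqs))
    n_val = max(1, int(round(cfg.validation_fraction * len(seqs))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx = val_idx
    X_train, X_val = X[train_idx], X[val_idx]

    model = GeneratorModel(cfg, spec, _init_params(cfg, spec, rng))
    opt = _nn.Adam(lr=cfg.learning_rate)
    rows = []
    best_val = np.inf
    best_params = None
    stall = 0
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(len(X_train))
        tr_recon = tr_kl = 0.0
        for start in range(0, len(perm), cfg.batch_size):
            batch = X_train[perm[start : start + cfg.batch_size]]
            eps = rng.standard_normal((batch.shape[0], cfg.latent_dim))
            recon, kl, caches = model._forward(batch, eps)
            grads = model._backward(caches)
            opt.step(model.params, grads)
            tr_recon += recon * batch.shape[0]
            tr_kl += kl * batch.shape[0]
        tr_recon /= len(X_train)
        tr_kl /= len(X_train)
        # validation at the latent mean (eps = 0): deterministic ELBO proxy
        val_recon, val_kl, _ = model._forward(
            X_val, np.zeros((X_val.shape[0], cfg.latent_dim))
        )
        rows.append(
            {
                "epoch": epoch,
                "train_elbo": tr_recon + tr_kl,
                "val_elbo": val_recon + val_kl,
                "train_recon": tr_recon,
                "train_kl": tr_kl,
                "val_recon": val_recon,
                "val_kl": val_kl,
            }
        )
        val_loss = val_recon + val_kl
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            stall = 0
        else:
            stall += 1
            if stall >= cfg.early_stop_patience:
                break
    if best_params is not None:
        model.params = best_params
    model.history = pd.DataFrame(rows)
    return model


def generate(model: GeneratorModel, gen_cfg: GenerationConfig) -> list[str]:
    """Generate de novo sequences by decoding z ~ N(0, 1).

    Returns exactly ``n_sequences`` strings over the 20-letter alphabet;
    identical seeds give identical output.
    """
    model._require_trained()
    rng = np.random.default_rng(gen_cfg.seed)
    out = []
    for _ in range(gen_cfg.n_sequences):
        z = rng.standard_normal(model.config.latent_dim)
        out.append(model.decode(z, temperature=gen_cfg.temperature, rng=rng))
    return out


def write_history_csv(model: GeneratorModel, path: str | Path) -> None:
    model._require_trained()
    model.history.to_csv(path, index=False, float_format="%.6f")
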