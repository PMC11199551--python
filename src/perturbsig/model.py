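"""Dual variational autoencoder for chemical-induced transcriptional profiles.

The model couples two VAEs -- one over basal (vehicle-treated) profiles X1,
one over compound-perturbed profiles X2 -- with a compound encoder and an
affine latent fusion map.  Training jointly minimises six terms: the two
reconstruction errors, the error of the predicted differential expression
(X2' - X1 against X2 - X1), standard-normal KL penalties on both latents and
a KL term tying the fused latent (predicted from X1 and the compound) to the
encoder posterior of X2.  At inference time the model maps a basal profile
plus a compound feature vector to a predicted perturbed profile X2' and the
predicted differential-expression signature dX' = X2' - X1 using the latent
means, so prediction is deterministic.

Expression vectors are standardised per gene inside the model (statistics
fitted from the training pairs and inverted at the output boundary); the
loss terms are computed on that standardised scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, Adam
from .chem import CompoundTable
from .profiles import PairedSample

__all__ = [
    "GaussianLatent", "ModelConfig", "LossReport", "DualVAE",
    "kl_standard", "kl_gaussians", "forward", "train", "pretrain_init",
    "predict", "save_model", "load_model",
]


# ---------------------------------------------------------------------------
# Gaussian latents and KL closed forms
# ---------------------------------------------------------------------------

@dataclass
class GaussianLatent:
    """Diagonal Gaussian q(z) given by mean and log-variance vectors."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.logvar = np.asarray(self.logvar, dtype=float)
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar must have identical shapes")
        if not (np.all(np.isfinite(self.mu))
                and np.all(np.isfinite(self.logvar))):
            raise ValueError("latent parameters must be finite")


def kl_standard(z: GaussianLatent):
    """KL(q || N(0, I)) summed over latent dimensions.

    Closed form ``sum_i -1/2 (1 + logvar_i - exp(logvar_i) - mu_i^2)``.
    A 1-D latent returns a float; a batch (rows = samples) returns the
    per-sample vector.
    """
    kl = -0.5 * (1.0 + z.logvar - np.exp(z.logvar) - z.mu ** 2)
    out = kl.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def kl_gaussians(q: GaussianLatent, p: GaussianLatent):
    """KL(q || p) for two diagonal Gaussians, summed over dimensions.

    Closed form per dimension:
    ``-1/2 (1 + log(sq^2/sp^2) - (sq^2 + (mq - mp)^2) / sp^2)``.
    Reduces to :func:`kl_standard` when ``p`` is the standard normal.
    """
    if q.mu.shape != p.mu.shape:
        raise ValueError(f"dimension mismatch: {q.mu.shape} vs {p.mu.shape}")
    vq, vp = np.exp(q.logvar), np.exp(p.logvar)
    kl = -0.5 * (1.0 + (q.logvar - p.logvar)
                 - (vq + (q.mu - p.mu) ** 2) / vp)
    out = kl.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Configuration and loss bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and optimisation settings.

    Defaults follow the published architecture: encoders with hidden widths
    [1200, 100] feeding d = 100 Gaussian heads, decoders [100, 800] back to
    the 978 landmark genes, ReLU hidden activations with linear outputs, and
    an unweighted six-term objective.
    """

    input_dim: int = 978
    feature_dim: int = 2048
    latent_dim: int = 100
    enc_hidden: tuple = (1200, 100)
    dec_hidden: tuple = (100, 800)
    mol_hidden: tuple = (512,)
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    patience: int = 10
    # weights for (mse_x1, mse_x2, mse_dx, kl_z1, kl_z2, kl_fuse)
    loss_weights: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        for k in ("enc_hidden", "dec_hidden", "mol_hidden", "loss_weights"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class LossReport:
    """The six objective components; ``total`` is their weighted sum."""

    mse_x1: float
    mse_x2: float
    mse_dx: float
    kl_z1: float
    kl_z2: float
    kl_fuse: float
    total: float

    def __post_init__(self) -> None:
        for name in ("kl_z1", "kl_z2", "kl_fuse"):
            if getattr(self, name) < -1e-6:
                raise ValueError(f"{name} negative: {getattr(self, name)}")


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

class _MLP:
    """Fully connected stack; ReLU on hidden layers, linear output."""

    def __init__(self, dims, rng, w_scale: float | None = None):
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for i, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            scale = w_scale if w_scale is not None else np.sqrt(2.0 / din)
            self.weights.append(Tensor(
                rng.normal(0.0, scale, size=(din, dout)), requires_grad=True))
            self.biases.append(Tensor(np.zeros(dout), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                h = h.relu()
        return h

    @property
    def params(self) -> list[Tensor]:
        return self.weights + self.biases


class _GaussianEncoder:
    """MLP body with separate linear heads for mean and log-variance.

    Head weights start near zero so the initial posterior is close to the
    standard-normal prior (KL starts near 0).
    """

    def __init__(self, in_dim, hidden, latent_dim, rng):
        self.body = _MLP([in_dim, *hidden], rng)
        self.head_mu = _MLP([hidden[-1], latent_dim], rng, w_scale=1e-3)
        self.head_logvar = _MLP([hidden[-1], latent_dim], rng, w_scale=1e-3)

    def __call__(self, x: Tensor):
        h = self.body(x).relu()
        return self.head_mu(h), self.head_logvar(h)

    @property
    def params(self):
        return self.body.params + self.head_mu.params + self.head_logvar.params


def _recon_error(a: Tensor, b: Tensor, batch: int) -> Tensor:
    """Batch-mean of the per-sample sum of squared errors.

    Summing over genes (rather than averaging) keeps the reconstruction
    terms on the same per-sample scale as the dimension-summed KL terms --
    the standard Gaussian evidence-lower-bound convention.  Averaging over
    genes instead down-weights reconstruction by 1/n_genes relative to the
    KL penalties and drives the latents to the prior (posterior collapse).
    """
    return (a - b).square().sum() * (1.0 / batch)


def _kl_standard_t(mu: Tensor, logvar: Tensor, batch: int) -> Tensor:
    """Batch-mean of per-sample sum_i -1/2(1 + lv - e^lv - mu^2)."""
    kl = (1.0 + logvar - logvar.exp() - mu.square()) * -0.5
    return kl.sum() * (1.0 / batch)


def _kl_gaussians_t(mu_q: Tensor, lv_q: Tensor, mu_p: Tensor, lv_p: Tensor,
                    batch: int) -> Tensor:
    diff = mu_q - mu_p
    kl = (1.0 + (lv_q - lv_p)
          - (lv_q.exp() + diff.square()) * (lv_p * -1.0).exp()) * -0.5
    return kl.sum() * (1.0 / batch)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class DualVAE:
    """Dual-VAE over basal/perturbed profile pairs with a compound encoder."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.encoder_x1 = _GaussianEncoder(c.input_dim, c.enc_hidden,
                                           c.latent_dim, rng)
        self.encoder_x2 = _GaussianEncoder(c.input_dim, c.enc_hidden,
                                           c.latent_dim, rng)
        self.decoder_x1 = _MLP([c.latent_dim, *c.dec_hidden, c.input_dim], rng)
        self.decoder_x2 = _MLP([c.latent_dim, *c.dec_hidden, c.input_dim], rng)
        self.mol_encoder = _MLP([c.feature_dim, *c.mol_hidden, c.latent_dim],
                                rng)
        # affine map (z1_mean (+) z_mol) -> Gaussian parameters of the fused
        # latent; near-zero init keeps the initial fused posterior ~ N(0, I)
        self.fusion = _MLP([2 * c.latent_dim, 2 * c.latent_dim], rng,
                           w_scale=1e-3)
        # per-gene standardisation, identity until fitted on training data
        self.scale_mean = np.zeros(c.input_dim)
        self.scale_sd = np.ones(c.input_dim)
        self._scaler_fitted = False

    # -- parameter groups -------------------------------------------------
    @property
    def vae_params(self) -> list[Tensor]:
        return (self.encoder_x1.params + self.decoder_x1.params
                + self.encoder_x2.params + self.decoder_x2.params)

    @property
    def params(self) -> list[Tensor]:
        return self.vae_params + self.mol_encoder.params + self.fusion.params

    # -- scaling -----------------------------------------------------------
    def fit_scaler(self, pairs: list[PairedSample]) -> None:
        """Fit per-gene standardisation from training pairs (x1 and x2)."""
        stack = np.vstack([np.vstack([p.x1, p.x2]) for p in pairs])
        self.scale_mean = stack.mean(axis=0)
        self.scale_sd = np.maximum(stack.std(axis=0), 1e-3)
        self._scaler_fitted = True

    def _std(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.scale_mean) / self.scale_sd

    def _destd(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale_sd + self.scale_mean

    # -- forward pass ------------------------------------------------------
    def _check_dims(self, x1, x2, cmol):
        c = self.config
        for name, arr, dim in (("x1", x1, c.input_dim), ("x2", x2, c.input_dim),
                               ("cmol", cmol, c.feature_dim)):
            if arr is not None and np.asarray(arr).shape[-1] != dim:
                raise ValueError(
                    f"{name} has width {np.asarray(arr).shape[-1]}, "
                    f"model expects {dim}")

    def forward(self, x1, x2, cmol, rng: np.random.Generator):
        """One training forward pass on a batch (or single pair).

        Returns ``(x1_hat, x2_hat, x2_pred, LossReport)`` where the profiles
        are on the input scale and the loss terms are computed on the
        model's standardised scale.  Sampling uses the reparameterisation
        trick with noise drawn from ``rng``.
        """
        self._check_dims(x1, x2, cmol)
        out = self._forward_graph(np.atleast_2d(x1), np.atleast_2d(x2),
                                  np.atleast_2d(cmol), rng)
        report = self._loss_report(out)
        return (self._destd(out["x1_hat"].data), self._destd(out["x2_hat"].data),
                self._destd(out["x2_pred"].data), report)

    def _forward_graph(self, x1, x2, cmol, rng: np.random.Generator) -> dict:
        """Build the autodiff graph for a standardised batch."""
        b = x1.shape[0]
        d = self.config.latent_dim
        tx1 = Tensor(self._std(x1))
        tx2 = Tensor(self._std(x2))
        tc = Tensor(np.asarray(cmol, dtype=float))

        mu1, lv1 = self.encoder_x1(tx1)
        mu2, lv2 = self.encoder_x2(tx2)
        eps1 = Tensor(rng.standard_normal((b, d)))
        eps2 = Tensor(rng.standard_normal((b, d)))
        z1 = mu1 + (lv1 * 0.5).exp() * eps1
        z2 = mu2 + (lv2 * 0.5).exp() * eps2
        x1_hat = self.decoder_x1(z1)
        x2_hat = self.decoder_x2(z2)

        zmol = self.mol_encoder(tc)
        fused = self.fusion(Tensor.concat([mu1, zmol], axis=1))
        mu_f = Tensor(fused.data[:, :d], requires_grad=fused.requires_grad,
                      parents=(fused,),
                      backward=lambda g: (np.concatenate(
                          [g, np.zeros_like(g)], axis=1),))
        lv_f = Tensor(fused.data[:, d:], requires_grad=fused.requires_grad,
                      parents=(fused,),
                      backward=lambda g: (np.concatenate(
                          [np.zeros_like(g), g], axis=1),))
        eps3 = Tensor(rng.standard_normal((b, d)))
        z_f = mu_f + (lv_f * 0.5).exp() * eps3
        x2_pred = self.decoder_x2(z_f)

        return dict(tx1=tx1, tx2=tx2, batch=b,
                    mu1=mu1, lv1=lv1, mu2=mu2, lv2=lv2,
                    mu_f=mu_f, lv_f=lv_f,
                    x1_hat=x1_hat, x2_hat=x2_hat, x2_pred=x2_pred)

    def _loss_terms(self, out: dict) -> list[Tensor]:
        b = out["batch"]
        dx_true = out["tx2"] - out["tx1"]
        dx_pred = out["x2_pred"] - out["tx1"]
        return [
            _recon_error(out["tx1"], out["x1_hat"], b),
            _recon_error(out["tx2"], out["x2_hat"], b),
            _recon_error(dx_true, dx_pred, b),
            _kl_standard_t(out["mu1"], out["lv1"], b),
            _kl_standard_t(out["mu2"], out["lv2"], b),
            _kl_gaussians_t(out["mu_f"], out["lv_f"],
                            out["mu2"], out["lv2"], b),
        ]

    def _total(self, terms, weights) -> Tensor:
        total = terms[0] * weights[0]
        for t, w in zip(terms[1:], weights[1:]):
            total = total + t * w
        return total

    def _loss_report(self, out: dict) -> LossReport:
        terms = [t.item() for t in self._loss_terms(out)]
        w = self.config.loss_weights
        return LossReport(*terms, total=float(np.dot(terms, w)))

    # -- latent access (used by tests and downstream analysis) -------------
    def encode_basal(self, x1) -> GaussianLatent:
        mu, lv = self.encoder_x1(Tensor(self._std(np.atleast_2d(x1))))
        return GaussianLatent(mu.data.squeeze(), lv.data.squeeze())

    def encode_perturbed(self, x2) -> GaussianLatent:
        mu, lv = self.encoder_x2(Tensor(self._std(np.atleast_2d(x2))))
        return GaussianLatent(mu.data.squeeze(), lv.data.squeeze())

    def fuse(self, x1, cmol) -> GaussianLatent:
        """Predicted perturbed latent from a basal profile and a compound."""
        self._check_dims(x1, None, cmol)
        mu1, _ = self.encoder_x1(Tensor(self._std(np.atleast_2d(x1))))
        zmol = self.mol_encoder(Tensor(np.atleast_2d(
            np.asarray(cmol, dtype=float))))
        fused = self.fusion(Tensor.concat([mu1, zmol], axis=1)).data
        d = self.config.latent_dim
        return GaussianLatent(fused[:, :d].squeeze(), fused[:, d:].squeeze())

    # -- inference ----------------------------------------------------------
    def predict(self, x1, cmol, sample: bool = False,
                rng: np.random.Generator | None = None):
        """Predict (x2', dx') for basal profile(s) and compound feature(s).

        Deterministic by default (latent means); ``sample=True`` draws the
        fused latent stochastically using ``rng``.
        """
        self._check_dims(x1, None, cmol)
        x1 = np.asarray(x1, dtype=float)
        single = x1.ndim == 1
        lat = self.fuse(np.atleast_2d(x1), np.atleast_2d(cmol))
        mu = np.atleast_2d(lat.mu)
        if sample:
            if rng is None:
                rng = np.random.default_rng()
            mu = mu + np.exp(0.5 * np.atleast_2d(lat.logvar)) \
                * rng.standard_normal(mu.shape)
        x2p = self._destd(self.decoder_x2(Tensor(mu)).data)
        dx = x2p - np.atleast_2d(x1)
        if single:
            return x2p[0], dx[0]
        return x2p, dx

    # -- training ------------------------------------------------------------
    def _batched(self, pairs, features, ids=None):
        x1 = np.vstack([p.x1 for p in pairs])
        x2 = np.vstack([p.x2 for p in pairs])
        cm = features  # already a matrix aligned with pairs
        return x1, x2, cm

    def _feature_matrix(self, pairs: list[PairedSample],
                        features: CompoundTable) -> np.ndarray:
        missing = sorted({p.compound_id for p in pairs}
                         - set(features.smiles) - set(features.features))
        if missing:
            raise ValueError(f"no features for compounds: {missing[:10]}"
                             + ("..." if len(missing) > 10 else ""))
        return features.feature_matrix([p.compound_id for p in pairs])

    def fit(self, pairs: list[PairedSample], features: CompoundTable,
            val_pairs: list[PairedSample] | None = None,
            epochs: int | None = None, seed: int | None = None,
            param_subset: str = "all") -> list[LossReport]:
        """Mini-batch Adam training of the six-term objective.

        Returns the per-epoch mean :class:`LossReport` trajectory.  With
        ``val_pairs`` given, training stops early after ``config.patience``
        epochs without validation improvement and the best parameters are
        restored.  ``param_subset='vae'`` updates only the two VAEs
        (reconstruction + KL terms; used for pretraining initialisation).
        """
        if not pairs:
            raise ValueError("training requires at least one pair")
        c = self.config
        epochs = c.epochs if epochs is None else epochs
        rng = np.random.default_rng(c.seed if seed is None else seed)
        x1, x2, _ = self._batched(pairs, None)
        cmol = self._feature_matrix(pairs, features)
        if not self._scaler_fitted:
            self.fit_scaler(pairs)
        if param_subset == "vae":
            params = self.vae_params
            weights = (c.loss_weights[0], c.loss_weights[1], 0.0,
                       c.loss_weights[3], c.loss_weights[4], 0.0)
        else:
            params = self.params
            weights = c.loss_weights
        opt = Adam(params, lr=c.lr)
        n = len(pairs)
        history: list[LossReport] = []
        best_val = np.inf
        best_state = None
        stale = 0
        for _ in range(epochs):
            order = rng.permutation(n)
            totals = np.zeros(7)
            nb = 0
            for start in range(0, n, c.batch_size):
                idx = order[start:start + c.batch_size]
                out = self._forward_graph(x1[idx], x2[idx], cmol[idx], rng)
                terms = self._loss_terms(out)
                loss = self._total(terms, weights)
                opt.zero_grad()
                loss.backward()
                opt.step()
                vals = [t.item() for t in terms]
                totals += np.array(vals + [float(np.dot(vals, weights))])
                nb += 1
            history.append(LossReport(*(totals / nb)))
            if val_pairs is not None:
                vr = self.evaluate_loss(val_pairs, features,
                                        rng=np.random.default_rng(0))
                if vr.total < best_val - 1e-9:
                    best_val = vr.total
                    best_state = [p.data.copy() for p in params]
                    stale = 0
                else:
                    stale += 1
                    if stale >= c.patience:
                        break
        if best_state is not None:
            for p, d in zip(params, best_state):
                p.data = d
        return history

    def evaluate_loss(self, pairs, features: CompoundTable,
                      rng: np.random.Generator) -> LossReport:
        """Mean loss over a pair list without updating parameters."""
        x1 = np.vstack([p.x1 for p in pairs])
        x2 = np.vstack([p.x2 for p in pairs])
        cmol = self._feature_matrix(pairs, features)
        out = self._forward_graph(x1, x2, cmol, rng)
        return self._loss_report(out)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def forward(model: DualVAE, x1, x2, cmol, rng: np.random.Generator):
    """Single forward pass; see :meth:`DualVAE.forward`."""
    return model.forward(x1, x2, cmol, rng)


def train(model: DualVAE, pairs, features: CompoundTable,
          val_pairs=None, epochs=None, seed=None):
    """Train the full model; returns ``(model, loss_trajectory)``."""
    history = model.fit(pairs, features, val_pairs=val_pairs, epochs=epochs,
                        seed=seed)
    return model, history


def pretrain_init(model: DualVAE, shrna_pairs, epochs=None, seed=None):
    """Initialise the two VAEs from knockdown-style profile pairs.

    Only the encoder/decoder weights of both VAEs are trained, on the
    reconstruction and standard-normal KL terms; the compound encoder and
    fusion map are left untouched.  Knockdown pairs use the empty-vector
    control as x1 and the shRNA-perturbed profile as x2, formatted exactly
    like compound pairs.
    """
    if not shrna_pairs:
        raise ValueError("pretraining requires at least one pair")
    # knockdown perturbagens need a (dummy) feature vector for batching
    feats = CompoundTable(smiles={}, features={
        p.compound_id: np.zeros(model.config.feature_dim)
        for p in shrna_pairs})
    model.fit(shrna_pairs, feats, epochs=epochs, seed=seed,
              param_subset="vae")
    return model


def predict(model: DualVAE, x1, cmol, sample: bool = False, rng=None):
    """Predict ``(x2', dx')``; see :meth:`DualVAE.predict`."""
    return model.predict(x1, cmol, sample=sample, rng=rng)


# ---------------------------------------------------------------------------
# Persistence: npz parameter archive + JSON config sidecar
# ---------------------------------------------------------------------------

def _ckpt_paths(path) -> tuple[str, str]:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    return path, path[:-4] + ".json"


def save_model(model: DualVAE, path) -> None:
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params)}
    arrays["scale_mean"] = model.scale_mean
    arrays["scale_sd"] = model.scale_sd
    arrays["scaler_fitted"] = np.array(int(model._scaler_fitted))
    npz_path, sidecar = _ckpt_paths(path)
    np.savez(npz_path, **arrays)
    with open(sidecar, "w") as fh:
        fh.write(model.config.to_json())


def load_model(path) -> DualVAE:
    npz_path, sidecar = _ckpt_paths(path)
    with open(sidecar) as fh:
        config = ModelConfig.from_json(fh.read())
    model = DualVAE(config)
    with np.load(npz_path) as arch:
        for i, p in enumerate(model.params):
            p.data = arch[f"p{i}"]
        model.scale_mean = arch["scale_mean"]
        model.scale_sd = arch["scale_sd"]
        model._scaler_fitted = bool(int(arch["scaler_fitted"]))
    return model
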