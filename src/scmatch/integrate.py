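"""Technology-invariant latent space via adversarially trained autoencoders.

Each technology gets a variational autoencoder with a Gaussian posterior and
a Gaussian decoder.  The model is initialized by training a plain VAE on one
*source* technology; its latent codes are then frozen and every *target*
technology's autoencoder is trained to (i) reconstruct its own cells and
(ii) place its codes so that a shared, label-conditioned discriminator cannot
tell them apart from the source codes.  The result is a single latent space
in which analogous cells from different technologies lie close together,
ready for cross-technology cell matching.

The public surface follows a model/results pattern: build a :class:`SCIM`
from a list of datasets, call :meth:`SCIM.fit`, and work with the returned
:class:`SCIMResults` (codes, training history, divergence diagnostics,
matching).  Functional wrappers (:func:`train_vae`, :func:`train_scim`,
:func:`encode`, the loss functions) expose the individual pieces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._nn import MLP, Adam, sigmoid, softplus
from .datasets import ExpressionDataset, LatentCodes
from .divergence import divergence_score

__all__ = [
    "IntegrationConfig",
    "TechnologyModel",
    "Discriminator",
    "TrainingFault",
    "vae_loss",
    "discriminator_loss",
    "scim_objective",
    "train_vae",
    "train_scim",
    "encode",
    "reconstruction_error",
    "SCIM",
    "SCIMResults",
]

LOG2PI = math.log(2.0 * math.pi)


class TrainingFault(RuntimeError):
    """Raised when training produces non-finite losses or activations."""


@dataclass
class IntegrationConfig:
    """Hyperparameters of the integration model.

    ``beta`` weighs the KL term during VAE initialization (a small value is
    needed for structure to survive in the codes); ``beta_adv`` weighs the
    adversarial term during the alignment phase.  ``label_fraction`` is the
    share of cells whose label is revealed to the discriminator — the rest
    are assigned the censored class.
    """

    latent_dim: int = 8
    beta: float = 0.01
    beta_adv: float = 50.0
    lr_autoencoder: float = 5e-4
    lr_discriminator: float = 2e-3
    vae_epochs: int = 256
    scim_epochs: int = 256
    hidden_units: tuple[int, ...] = (64, 64)
    disc_hidden: tuple[int, ...] = (8, 8)
    label_fraction: float = 1.0
    batch_size: int = 64
    label_scale: float = 3.0
    preprocess: str = "log1p_standardize"
    divergence_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0.0 <= self.label_fraction <= 1.0:
            raise ValueError("label_fraction must lie in [0, 1]")
        if self.preprocess not in (
            "log1p_standardize",
            "arcsinh_standardize",
            "standardize",
            "none",
        ):
            raise ValueError(f"unknown preprocess {self.preprocess!r}")


class TechnologyModel:
    """Encoder/decoder pair for one technology.

    The encoder maps preprocessed features to a Gaussian posterior
    ``N(mu, diag(exp(logvar)))`` over the latent space; the decoder maps a
    latent point to per-feature Gaussian means with unit variance.
    Feature-wise preprocessing statistics are fitted once on the training
    data and stored on the model.
    """

    def __init__(
        self,
        n_features: int,
        cfg: IntegrationConfig,
        rng: np.random.Generator,
        technology: str = "tech",
    ):
        d = cfg.latent_dim
        hidden = list(cfg.hidden_units)
        self.encoder = MLP([n_features, *hidden, 2 * d], rng, out_activation=None)
        self.decoder = MLP([d, *hidden, n_features], rng, out_activation=None)
        self.n_features = n_features
        self.latent_dim = d
        self.technology = technology
        self.preprocess = cfg.preprocess
        self.feature_mean_: np.ndarray | None = None
        self.feature_std_: np.ndarray | None = None
        # affine code standardization (identity by default); the source
        # model's codes are standardized once after VAE init so the shared
        # latent space has zero mean and unit spread per dimension
        self.code_shift_ = np.zeros(d)
        self.code_scale_ = np.ones(d)

    # ---- preprocessing -------------------------------------------------
    def _raw_transform(self, counts: np.ndarray) -> np.ndarray:
        x = np.asarray(counts, dtype=float)
        if self.preprocess == "log1p_standardize":
            return np.log1p(x)
        if self.preprocess == "arcsinh_standardize":
            return np.arcsinh(x / 5.0)
        return x

    def fit_preprocess(self, counts: np.ndarray) -> None:
        x = self._raw_transform(counts)
        if self.preprocess == "none":
            self.feature_mean_ = np.zeros(x.shape[1])
            self.feature_std_ = np.ones(x.shape[1])
        else:
            self.feature_mean_ = x.mean(axis=0)
            self.feature_std_ = np.maximum(x.std(axis=0), 1e-8)

    def transform(self, counts: np.ndarray) -> np.ndarray:
        if self.feature_mean_ is None:
            raise RuntimeError("fit_preprocess must be called before transform")
        if counts.shape[1] != self.n_features:
            raise ValueError(
                f"dataset has {counts.shape[1]} features, model expects {self.n_features}"
            )
        return (self._raw_transform(counts) - self.feature_mean_) / self.feature_std_

    # ---- network passes ------------------------------------------------
    def encode_posterior(
        self, x: np.ndarray, train: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        out = self.encoder.forward(x, train=train)
        return out[:, : self.latent_dim], out[:, self.latent_dim :]

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        return self.decoder.forward(z, train=train)


class Discriminator:
    """Binary classifier on (latent code, one-hot label) with spectral norm.

    ``classes`` is the shared label vocabulary; an extra censored class is
    always appended, used for cells whose label is withheld.
    """

    def __init__(
        self, cfg: IntegrationConfig, classes: list[str], rng: np.random.Generator
    ):
        self.classes = list(classes)
        self.n_label_dims = len(self.classes) + 1  # + censored
        self.label_scale = cfg.label_scale
        self.latent_dim = cfg.latent_dim
        self.net = MLP(
            [cfg.latent_dim + self.n_label_dims, *cfg.disc_hidden, 1],
            rng,
            out_activation=None,
            spectral_norm=True,
        )

    def one_hot(self, labels: np.ndarray | None, n: int) -> np.ndarray:
        """One-hot encode labels; ``None`` entries / missing labels → censored."""
        oh = np.zeros((n, self.n_label_dims))
        if labels is None:
            oh[:, -1] = 1.0
            return oh * self.label_scale
        for i, lab in enumerate(labels):
            if lab is None:
                oh[i, -1] = 1.0
            else:
                oh[i, self.classes.index(str(lab))] = 1.0
        return oh * self.label_scale

    def logits(self, z: np.ndarray, one_hot: np.ndarray, train: bool = False) -> np.ndarray:
        if z.shape[1] != self.latent_dim:
            raise ValueError(
                f"codes have dimension {z.shape[1]}, discriminator expects {self.latent_dim}"
            )
        return self.net.forward(np.hstack([z, one_hot]), train=train)[:, 0]

    def predict_proba(self, z: np.ndarray, one_hot: np.ndarray) -> np.ndarray:
        return sigmoid(self.logits(z, one_hot, train=False))


# ---------------------------------------------------------------------------
# loss functions
# ---------------------------------------------------------------------------

def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Mean over the batch of KL(N(mu, e^logvar) || N(0, I)), in nats."""
    per_cell = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1)
    return float(per_cell.mean())


def gaussian_nll(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean per-cell negative log-likelihood under a unit-variance decoder."""
    per_cell = 0.5 * np.sum((x - x_hat) ** 2 + LOG2PI, axis=1)
    return float(per_cell.mean())


def vae_loss(
    x: np.ndarray,
    model: TechnologyModel,
    beta: float,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Evidence-lower-bound loss: reconstruction NLL plus ``beta`` x KL.

    With ``rng`` given, the latent point is a reparameterized posterior
    sample; otherwise the posterior mean is used (deterministic evaluation).
    Returns the components under keys ``total``, ``nll`` and ``kl``.
    """
    mu, logvar = model.encode_posterior(x)
    if rng is not None:
        z = mu + np.exp(0.5 * logvar) * rng.normal(size=mu.shape)
    else:
        z = mu
    x_hat = model.decode(z)
    nll = gaussian_nll(x, x_hat)
    kl = gaussian_kl(mu, logvar)
    if not (np.isfinite(nll) and np.isfinite(kl)):
        raise TrainingFault("non-finite VAE loss")
    return {"total": nll + beta * kl, "nll": nll, "kl": kl}


def _bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(softplus(logits) - y * logits))


def discriminator_loss(
    disc: Discriminator,
    codes_s: LatentCodes | np.ndarray,
    codes_t: LatentCodes | np.ndarray,
    labels_s: np.ndarray | None = None,
    labels_t: np.ndarray | None = None,
) -> float:
    """Binary cross-entropy of source-vs-target classification on codes."""
    zs = codes_s.codes if isinstance(codes_s, LatentCodes) else np.asarray(codes_s)
    zt = codes_t.codes if isinstance(codes_t, LatentCodes) else np.asarray(codes_t)
    ls = disc.logits(zs, disc.one_hot(labels_s, len(zs)))
    lt = disc.logits(zt, disc.one_hot(labels_t, len(zt)))
    logits = np.concatenate([ls, lt])
    y = np.concatenate([np.ones(len(zs)), np.zeros(len(zt))])
    return _bce_with_logits(logits, y)


def scim_objective(
    x_t: np.ndarray,
    z_s: np.ndarray,
    model_t: TechnologyModel,
    disc: Discriminator,
    beta: float,
    labels_t: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Target-technology objective: reconstruction NLL + ``beta`` x adversarial.

    The adversarial component is the loss the target encoder incurs when the
    discriminator recognizes its codes as non-source, ``-log D(z_t)``; the
    fixed source codes ``z_s`` define the distribution being matched and
    receive no gradient.
    """
    del z_s  # fixed reference distribution; no gradient flows to the source
    mu, logvar = model_t.encode_posterior(x_t)
    if rng is not None:
        z_t = mu + np.exp(0.5 * logvar) * rng.normal(size=mu.shape)
    else:
        z_t = mu
    x_hat = model_t.decode(z_t)
    nll = gaussian_nll(x_t, x_hat)
    logits = disc.logits(z_t, disc.one_hot(labels_t, len(z_t)))
    adv = float(np.mean(softplus(-logits)))
    if not (np.isfinite(nll) and np.isfinite(adv)):
        raise TrainingFault("non-finite objective")
    return {"total": nll + beta * adv, "nll": nll, "adv": adv}


# ---------------------------------------------------------------------------
# training steps (explicit backprop)
# ---------------------------------------------------------------------------

def _vae_step(
    model: TechnologyModel,
    x: np.ndarray,
    beta: float,
    opt: Adam,
    rng: np.random.Generator,
) -> tuple[float, float]:
    B = x.shape[0]
    opt.zero_grad()
    mu, logvar = model.encode_posterior(x, train=True)
    eps = rng.normal(size=mu.shape)
    z = mu + np.exp(0.5 * logvar) * eps
    x_hat = model.decode(z, train=True)
    nll = gaussian_nll(x, x_hat)
    kl = gaussian_kl(mu, logvar)
    if not (np.isfinite(nll) and np.isfinite(kl)):
        raise TrainingFault("non-finite VAE loss")
    d_xhat = (x_hat - x) / B
    dz = model.decoder.backward(d_xhat)
    dmu = dz + beta * mu / B
    dlv = dz * eps * 0.5 * np.exp(0.5 * logvar) + beta * 0.5 * (np.exp(logvar) - 1.0) / B
    model.encoder.backward(np.hstack([dmu, dlv]))
    opt.step()
    return nll, kl


def _scim_target_step(
    model_t: TechnologyModel,
    disc: Discriminator,
    x_t: np.ndarray,
    one_hot_t: np.ndarray,
    beta_adv: float,
    opt: Adam,
    rng: np.random.Generator,
) -> tuple[float, float]:
    B = x_t.shape[0]
    opt.zero_grad()
    mu, logvar = model_t.encode_posterior(x_t, train=True)
    del logvar  # the alignment phase trains a deterministic encoder path
    z_t = mu
    x_hat = model_t.decode(z_t, train=True)
    nll = gaussian_nll(x_t, x_hat)
    if not np.isfinite(nll):
        raise TrainingFault("non-finite reconstruction loss")
    d_xhat = (x_hat - x_t) / B
    dz = model_t.decoder.backward(d_xhat)
    # adversarial term: encoder wants the discriminator to call z_t "source"
    h = np.hstack([z_t, one_hot_t])
    logits = disc.net.forward(h, train=True)[:, 0]
    adv = float(np.mean(softplus(-logits)))
    d_logits = -sigmoid(-logits) / B
    dh = disc.net.backward(beta_adv * d_logits[:, None])
    dz = dz + dh[:, : model_t.latent_dim]
    model_t.encoder.backward(np.hstack([dz, np.zeros_like(dz)]))
    opt.step()
    return nll, adv


def _disc_step(
    disc: Discriminator,
    z_s: np.ndarray,
    one_hot_s: np.ndarray,
    z_t: np.ndarray,
    one_hot_t: np.ndarray,
    opt: Adam,
) -> float:
    opt.zero_grad()
    X = np.vstack([np.hstack([z_s, one_hot_s]), np.hstack([z_t, one_hot_t])])
    y = np.concatenate([np.ones(len(z_s)), np.zeros(len(z_t))])
    logits = disc.net.forward(X, train=True)[:, 0]
    loss = _bce_with_logits(logits, y)
    if not np.isfinite(loss):
        raise TrainingFault("non-finite discriminator loss")
    d_logits = (sigmoid(logits) - y) / len(y)
    disc.net.backward(d_logits[:, None])
    opt.step()
    return loss


# ---------------------------------------------------------------------------
# high-level training
# ---------------------------------------------------------------------------

def encode(data: ExpressionDataset, model: TechnologyModel) -> LatentCodes:
    """Posterior-mean codes of all cells; deterministic for fixed parameters."""
    x = model.transform(data.counts)
    mu, _ = model.encode_posterior(x)
    mu = (mu - model.code_shift_) / model.code_scale_
    return LatentCodes(codes=mu, technology=data.technology, cell_ids=list(data.cell_ids))


def reconstruction_error(data: ExpressionDataset, model: TechnologyModel) -> float:
    """Mean per-cell reconstruction NLL at the posterior mean."""
    x = model.transform(data.counts)
    mu, _ = model.encode_posterior(x)
    return gaussian_nll(x, model.decode(mu))


def train_vae(
    source: ExpressionDataset,
    cfg: IntegrationConfig | None = None,
    verbose: bool = False,
) -> tuple[TechnologyModel, LatentCodes]:
    """Train the initialization VAE on the source technology.

    Returns the trained model and the posterior-mean codes of all source
    cells, which seed the shared latent space for the adversarial phase.
    """
    cfg = cfg or IntegrationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    init_rng, train_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    model = TechnologyModel(source.n_features, cfg, init_rng, technology=source.technology)
    model.fit_preprocess(source.counts)
    x = model.transform(source.counts)
    opt = Adam([model.encoder, model.decoder], lr=cfg.lr_autoencoder)
    n = x.shape[0]
    for epoch in range(cfg.vae_epochs):
        order = train_rng.permutation(n)
        for b0 in range(0, n, cfg.batch_size):
            batch = order[b0 : b0 + cfg.batch_size]
            try:
                nll, kl = _vae_step(model, x[batch], cfg.beta, opt, train_rng)
            except TrainingFault as err:
                raise TrainingFault(
                    f"VAE diverged at epoch {epoch}, batch {b0 // cfg.batch_size}: {err}"
                ) from err
        if verbose:
            print(f"vae epoch {epoch}: nll={nll:.3f} kl={kl:.3f}")
    return model, encode(source, model)


class SCIM:
    """Adversarial integration model over two or more technologies.

    Parameters
    ----------
    datasets
        One :class:`ExpressionDataset` per technology with disjoint feature
        spaces.  Labels, when present, condition the discriminator.
    source_index
        Which dataset anchors the latent space (its VAE is trained first and
        its codes stay fixed).
    config
        :class:`IntegrationConfig`; defaults reproduce the standard settings.
    """

    def __init__(
        self,
        datasets: list[ExpressionDataset],
        source_index: int = 0,
        config: IntegrationConfig | None = None,
    ):
        if len(datasets) < 2:
            raise ValueError("at least two datasets are required")
        if not 0 <= source_index < len(datasets):
            raise ValueError("source_index out of range")
        self.datasets = list(datasets)
        self.source_index = source_index
        self.config = config or IntegrationConfig()

    @classmethod
    def from_anndata(cls, adatas, source_index: int = 0, config=None) -> "SCIM":
        """Build from a list of AnnData objects (X, obs.label, obs.pseudotime)."""
        from .io import dataset_from_anndata

        return cls([dataset_from_anndata(a) for a in adatas], source_index, config)

    def _label_classes(self) -> list[str]:
        classes: set[str] = set()
        for ds in self.datasets:
            if ds.labels is not None:
                classes.update(str(v) for v in ds.labels)
        return sorted(classes)

    def fit(self, verbose: bool = False) -> "SCIMResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        (vae_seed,) = ss.spawn(1)
        seeds = ss.spawn(4)
        init_rng = np.random.default_rng(seeds[0])
        train_rng = np.random.default_rng(seeds[1])
        mask_rng = np.random.default_rng(seeds[2])

        source = self.datasets[self.source_index]
        vae_cfg = replace(cfg, seed=int(vae_seed.generate_state(1)[0] % 2**31))
        source_model, source_codes = train_vae(source, vae_cfg, verbose=verbose)
        source_model.code_shift_ = source_codes.codes.mean(axis=0)
        source_model.code_scale_ = np.maximum(source_codes.codes.std(axis=0), 1e-8)
        source_codes = encode(source, source_model)
        z_s_all = source_codes.codes

        classes = self._label_classes()
        disc = Discriminator(cfg, classes, init_rng)

        # reveal label_fraction of each dataset's labels; the rest are censored
        revealed: list[np.ndarray | None] = []
        for ds in self.datasets:
            if ds.labels is None:
                revealed.append(None)
                continue
            keep = mask_rng.random(ds.n_cells) < cfg.label_fraction
            labs = np.array([str(v) if k else None for v, k in zip(ds.labels, keep)], dtype=object)
            revealed.append(labs)
        oh_all = [
            disc.one_hot(revealed[i], ds.n_cells) for i, ds in enumerate(self.datasets)
        ]

        targets = [i for i in range(len(self.datasets)) if i != self.source_index]
        models: dict[int, TechnologyModel] = {self.source_index: source_model}
        opts: dict[int, Adam] = {}
        x_all: dict[int, np.ndarray] = {}
        for i in targets:
            ds = self.datasets[i]
            m = TechnologyModel(ds.n_features, cfg, init_rng, technology=ds.technology)
            m.fit_preprocess(ds.counts)
            models[i] = m
            x_all[i] = m.transform(ds.counts)
            opts[i] = Adam([m.encoder, m.decoder], lr=cfg.lr_autoencoder)
        opt_d = Adam([disc.net], lr=cfg.lr_discriminator)

        k = cfg.divergence_k
        sub = 2000  # cells per side for the per-epoch divergence log
        def _div(i: int) -> float:
            zt = encode(self.datasets[i], models[i]).codes
            a = z_s_all if len(z_s_all) <= sub else z_s_all[:: len(z_s_all) // sub + 1]
            b = zt if len(zt) <= sub else zt[:: len(zt) // sub + 1]
            return divergence_score(a, b, k=k).value

        initial_divergence = {i: _div(i) for i in targets}
        initial_codes = {
            self.datasets[i].technology: encode(self.datasets[i], models[i])
            for i in targets
        }
        history: list[dict] = []
        n_s = source.n_cells
        for epoch in range(cfg.scim_epochs):
            stats = {i: [0.0, 0.0, 0.0, 0] for i in targets}
            orders = {i: train_rng.permutation(self.datasets[i].n_cells) for i in targets}
            n_steps = max(
                int(np.ceil(self.datasets[i].n_cells / cfg.batch_size)) for i in targets
            )
            for step in range(n_steps):
                for i in targets:
                    order = orders[i]
                    lo = (step * cfg.batch_size) % len(order)
                    bt = order[lo : lo + cfg.batch_size]
                    if len(bt) == 0:
                        continue
                    bs = train_rng.integers(0, n_s, size=len(bt))
                    try:
                        nll, adv = _scim_target_step(
                            models[i], disc, x_all[i][bt], oh_all[i][bt],
                            cfg.beta_adv, opts[i], train_rng,
                        )
                        z_t = models[i].encode_posterior(x_all[i][bt])[0]
                        dloss = _disc_step(
                            disc, z_s_all[bs], oh_all[self.source_index][bs],
                            z_t, oh_all[i][bt], opt_d,
                        )
                    except TrainingFault as err:
                        raise TrainingFault(
                            f"training diverged at epoch {epoch}, step {step}, "
                            f"target {self.datasets[i].technology!r}: {err}"
                        ) from err
                    s = stats[i]
                    s[0] += nll
                    s[1] += adv
                    s[2] += dloss
                    s[3] += 1
            for i in targets:
                nll, adv, dloss, cnt = stats[i]
                history.append(
                    {
                        "epoch": epoch,
                        "target": self.datasets[i].technology,
                        "nll": nll / cnt,
                        "adv": adv / cnt,
                        "disc": dloss / cnt,
                        "divergence": _div(i),
                    }
                )
            if verbose:
                row = history[-1]
                print(
                    f"epoch {epoch}: nll={row['nll']:.3f} adv={row['adv']:.3f} "
                    f"disc={row['disc']:.3f} div={row['divergence']:.3f}"
                )
        return SCIMResults(
            model=self,
            models=models,
            discriminator=disc,
            history=pd.DataFrame(history),
            initial_divergence={
                self.datasets[i].technology: v for i, v in initial_divergence.items()
            },
            initial_codes=initial_codes,
        )


@dataclass
class SCIMResults:
    """Fitted integration model: per-technology networks plus diagnostics."""

    model: SCIM
    models: dict[int, TechnologyModel]
    discriminator: Discriminator
    history: pd.DataFrame
    initial_divergence: dict[str, float] = field(default_factory=dict)
    #: target codes at initialization (before any adversarial update), per
    #: technology — the baseline for "did integration reduce the divergence"
    initial_codes: dict[str, LatentCodes] = field(default_factory=dict)

    @property
    def config(self) -> IntegrationConfig:
        return self.model.config

    @property
    def technologies(self) -> list[str]:
        return [ds.technology for ds in self.model.datasets]

    def _index(self, which: int | str) -> int:
        if isinstance(which, str):
            return self.technologies.index(which)
        return which

    def codes(self, which: int | str) -> LatentCodes:
        """Posterior-mean latent codes of one technology's cells."""
        i = self._index(which)
        return encode(self.model.datasets[i], self.models[i])

    def reconstruction_error(self, which: int | str) -> float:
        i = self._index(which)
        return reconstruction_error(self.model.datasets[i], self.models[i])

    def divergence(self, a: int | str, b: int | str, k: int | None = None):
        """Symmetric kNN divergence between two technologies' codes."""
        k = k or self.config.divergence_k
        return divergence_score(self.codes(a), self.codes(b), k=k)

    def match(self, source: int | str, target: int | str, k: int = 50, p: float = 95.0, **kw):
        """Pair cells of two technologies from their latent codes."""
        from .match import match_cells

        return match_cells(self.codes(source), self.codes(target), k=k, p=p, **kw)

    def summary(self) -> str:
        """Plain-text summary of the fitted integration."""
        cfg = self.config
        src = self.technologies[self.model.source_index]
        lines = [
            "Adversarial latent-space integration",
            "=" * 52,
            f"technologies:      {', '.join(self.technologies)} (source: {src})",
            f"latent dim:        {cfg.latent_dim}",
            f"epochs:            vae={cfg.vae_epochs} scim={cfg.scim_epochs}",
            f"beta (vae/adv):    {cfg.beta} / {cfg.beta_adv}",
            f"label fraction:    {cfg.label_fraction}",
            "-" * 52,
            f"{'technology':<14}{'recon NLL':>12}{'div init':>12}{'div final':>12}",
        ]
        final = (
            self.history.groupby("target")["divergence"].last()
            if len(self.history)
            else {}
        )
        for i, tech in enumerate(self.technologies):
            if i == self.model.source_index:
                continue
            lines.append(
                f"{tech:<14}{self.reconstruction_error(i):>12.3f}"
                f"{self.initial_divergence.get(tech, float('nan')):>12.3f}"
                f"{final.get(tech, float('nan')):>12.3f}"
            )
        return "\n".join(lines)


def train_scim(
    datasets: list[ExpressionDataset],
    source_index: int = 0,
    cfg: IntegrationConfig | None = None,
    verbose: bool = False,
) -> SCIMResults:
    """Fit the full integration model (VAE init + adversarial alignment)."""
    return SCIM(datasets, source_index=source_index, config=cfg).fit(verbose=verbose)
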