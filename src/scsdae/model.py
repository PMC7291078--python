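"""The scSDAE imputation model and its SDAE / SDAE0 ablations.

The model is a symmetric stacked autoencoder over normalized expression
vectors of single cells: an encoder n -> d_1 -> ... -> d_k compressing to a
bottleneck of width d_k and a mirrored decoder d_k -> ... -> n.  All hidden
layers are ReLU except the bottleneck and the final output, which are
linear.  Training follows the classic denoising-autoencoder recipe:

1. *Layer-wise pretraining.*  Each layer is trained as a one-hidden-layer
   denoising autoencoder on the (corruption-masked) activations of the
   previous layer.  The first autoencoder sees the expression vectors and
   minimizes the variant loss; the inner autoencoders minimize plain MSE.
2. *Fine-tuning.*  The pretrained layers are stacked into one deep network
   and trained end-to-end on uncorrupted input under the variant loss.
3. *Masked imputation.*  Observed (non-zero) entries are copied through
   unchanged; only zeros receive the network output:
   x_imputed = x_out * (1 - m) + x * m  with  m_j = I(x_j > 0).

The three variants differ only in the training loss (see
:mod:`scsdae.losses`): ``scsdae`` adds an L1 penalty of weight ``alpha``
on outputs at zero entries, ``sdae0`` drops it (alpha = 0), and ``sdae``
uses the plain all-feature MSE.

The statsmodels-style front door is :class:`SCSDAE` / :class:`SCSDAEResults`;
the individual stages are also exposed as functions (``corrupt``,
``pretrain_layers``, ``stack_and_finetune``, ``impute``, ``fit_impute``).
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import MLP, Adam, Layer, MinibatchSampler, make_layer
from .losses import VARIANTS, batch_loss, batch_loss_grad
from .preprocess import (
    CountMatrix,
    NormalizedMatrix,
    ZeroMask,
    compute_mask,
    filter_matrix,
    normalize,
)


class NumericalError(RuntimeError):
    """Raised when the training loss becomes NaN or infinite."""


@dataclass
class NetworkSpec:
    """Layer widths (n, d_1, ..., d_k), d_k being the bottleneck."""

    layer_widths: tuple[int, ...]

    def __post_init__(self) -> None:
        self.layer_widths = tuple(int(w) for w in self.layer_widths)
        if len(self.layer_widths) < 2:
            raise ValueError("need at least input width and one hidden width")
        if any(w <= 0 for w in self.layer_widths):
            raise ValueError("layer widths must be positive")

    @classmethod
    def default(cls, n_genes: int) -> "NetworkSpec":
        """The reference architecture n-500-500-2000-10."""
        return cls((n_genes, 500, 500, 2000, 10))

    @property
    def n_input(self) -> int:
        return self.layer_widths[0]

    @property
    def k(self) -> int:
        return len(self.layer_widths) - 1

    def encoder_activation(self, i: int) -> str:
        """Activation of encoder layer i (1-based); bottleneck is linear."""
        return "linear" if i == self.k else "relu"

    def decoder_activation(self, i: int) -> str:
        """Activation of decoder layer i (1-based); final output is linear."""
        return "linear" if i == 1 else "relu"


@dataclass
class TrainConfig:
    """Training hyperparameters; the defaults are the reference settings."""

    variant: str = "scsdae"
    alpha: float = 1.0
    corruption_rate: float = 0.2
    pretrain_iters: int = 1000
    finetune_iters: int = 2000
    batch_size: int = 256
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    seed: int = 0
    clip_nonnegative: bool = True
    # Zero-masking noise never alters an already-zero entry, so restricting
    # corruption to observed entries is behaviourally identical; the flag is
    # kept for explicitness.
    corrupt_observed_only: bool = False
    log_every: int = 100

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 0.0 <= self.corruption_rate < 1.0:
            raise ValueError("corruption_rate must be in [0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.variant == "scsdae" else 0.0


@dataclass
class TrainedModel:
    """Stacked encoder/decoder weights after pretraining and fine-tuning."""

    encoder: list[Layer]
    decoder: list[Layer]  # in application order: d_k -> ... -> n
    spec: NetworkSpec
    config: TrainConfig
    training_log: dict[str, list[float]] = field(default_factory=dict)

    def network(self) -> MLP:
        return MLP(self.encoder + self.decoder)

    def forward(self, X: np.ndarray) -> np.ndarray:
        return self.network().forward(np.asarray(X, dtype=np.float64))

    def embed(self, X: np.ndarray) -> np.ndarray:
        """Bottleneck representation z = f_k(...f_1(x))."""
        return MLP(self.encoder).forward(np.asarray(X, dtype=np.float64))

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["layer_widths"] = list(self.spec.layer_widths)
            f.attrs["config"] = json.dumps(asdict(self.config))
            for name, layers in (("encoder", self.encoder), ("decoder", self.decoder)):
                grp = f.create_group(name)
                for i, layer in enumerate(layers):
                    g = grp.create_group(str(i))
                    g.create_dataset("W", data=layer.W)
                    g.create_dataset("b", data=layer.b)
                    g.attrs["activation"] = layer.activation
            if self.training_log:
                g = f.create_group("log")
                for key, vals in self.training_log.items():
                    g.create_dataset(key, data=np.asarray(vals))

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        import h5py

        with h5py.File(path, "r") as f:
            spec = NetworkSpec(tuple(int(w) for w in f.attrs["layer_widths"]))
            cfg = TrainConfig(**json.loads(f.attrs["config"]))
            enc, dec = [], []
            for name, out in (("encoder", enc), ("decoder", dec)):
                grp = f[name]
                for i in range(len(grp)):
                    g = grp[str(i)]
                    out.append(Layer(g["W"][...], g["b"][...], g.attrs["activation"]))
            log = {}
            if "log" in f:
                log = {k: list(map(float, f["log"][k][...])) for k in f["log"]}
        return cls(enc, dec, spec, cfg, log)


@dataclass
class ImputationResult:
    """Mask-preserving imputed matrix plus the raw network output."""

    x_imputed: np.ndarray
    x_out: np.ndarray
    mask: ZeroMask


def corrupt(x: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-masking noise: each entry independently set to 0 with
    probability ``rate``.  Returns a new array; the input is untouched."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return np.array(x, dtype=np.float64, copy=True)
    keep = rng.random(x.shape) >= rate
    return np.where(keep, x, 0.0)


def _train_network(net: MLP, X: np.ndarray, variant: str, alpha: float,
                   iters: int, corruption: float, cfg: TrainConfig,
                   rng: np.random.Generator, tag: str) -> list[float]:
    """Run ``iters`` minibatch Adam steps; the loss target is always the
    clean batch, the network input its corrupted copy."""
    n = X.shape[0]
    if iters <= 0:
        return []
    sampler = MinibatchSampler(n, cfg.batch_size, rng)
    params = net.parameters()
    opt = Adam(params, cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps)
    log: list[float] = []
    for step in range(iters):
        idx = sampler.next_batch()
        clean = X[idx]
        noisy = corrupt(clean, corruption, rng) if corruption > 0 else clean
        out, cache = net.forward(noisy, cache=True)
        loss = batch_loss(variant, clean, out, alpha)
        if not np.isfinite(loss):
            raise NumericalError(f"non-finite loss at {tag} step {step}: {loss}")
        grads = net.backward(cache, batch_loss_grad(variant, clean, out, alpha))
        flat = [g for pair in grads for g in pair]
        opt.step(flat)
        log.append(loss)
    return log


def pretrain_layers(X: NormalizedMatrix | np.ndarray, spec: NetworkSpec,
                    cfg: TrainConfig) -> tuple[list[tuple[Layer, Layer]], dict[str, list[float]]]:
    """Greedy layer-wise pretraining.

    Layer 1 is trained as a denoising autoencoder n -> d_1 -> n on the
    expression matrix under the variant loss; layer i >= 2 as
    d_{i-1} -> d_i -> d_{i-1} on the previous layer's clean activations
    under plain MSE.  After each layer is trained, its encoder is applied
    to the *uncorrupted* input to produce the next layer's training data.
    Returns the k (encoder, decoder) layer pairs and the loss logs.
    """
    Xv = X.values if isinstance(X, NormalizedMatrix) else np.asarray(X, dtype=np.float64)
    if spec.n_input != Xv.shape[1]:
        raise ValueError(f"spec input width {spec.n_input} != gene count {Xv.shape[1]}")
    ss = np.random.SeedSequence(cfg.seed)
    init_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
    widths = spec.layer_widths
    pairs: list[tuple[Layer, Layer]] = []
    logs: dict[str, list[float]] = {}
    H = Xv
    for i in range(1, spec.k + 1):
        d_in, d_out = widths[i - 1], widths[i]
        enc = make_layer(init_rng, d_in, d_out, spec.encoder_activation(i))
        dec = make_layer(init_rng, d_out, d_in,
                         "linear" if i == 1 else "relu")
        dae = MLP([enc, dec])
        train_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
        if i == 1:
            variant, alpha = cfg.variant, cfg.effective_alpha
        else:
            variant, alpha = "sdae", 0.0
        logs[f"pretrain_{i}"] = _train_network(
            dae, H, variant, alpha, cfg.pretrain_iters,
            cfg.corruption_rate, cfg, train_rng, f"pretrain layer {i}")
        pairs.append((enc, dec))
        if i < spec.k:
            H = MLP([enc]).forward(H)
    return pairs, logs


def stack_and_finetune(X: NormalizedMatrix | np.ndarray,
                       layers: list[tuple[Layer, Layer]],
                       spec: NetworkSpec, cfg: TrainConfig,
                       pretrain_logs: dict[str, list[float]] | None = None) -> TrainedModel:
    """Stack pretrained layers into one deep network and fine-tune it.

    The stacked forward pass before any fine-tuning step equals the
    composition of the pretrained encoders/decoders by construction.
    Fine-tuning applies no corruption and minimizes the variant loss.
    """
    Xv = X.values if isinstance(X, NormalizedMatrix) else np.asarray(X, dtype=np.float64)
    if len(layers) != spec.k:
        raise ValueError("pretrained layers do not match spec")
    encoder = [enc for enc, _ in layers]
    decoder = [dec for _, dec in reversed(layers)]
    # Decoder activations in the stacked net: the final output (decoder
    # layer 1) is linear, the rest ReLU — identical to their DAE roles.
    net = MLP(encoder + decoder)
    ss = np.random.SeedSequence((cfg.seed, 1))
    rng = np.random.Generator(np.random.PCG64(ss))
    logs = dict(pretrain_logs or {})
    logs["finetune"] = _train_network(
        net, Xv, cfg.variant, cfg.effective_alpha, cfg.finetune_iters,
        0.0, cfg, rng, "fine-tune")
    return TrainedModel(encoder, decoder, spec, cfg, logs)


def impute(X: NormalizedMatrix | np.ndarray, model: TrainedModel,
           mask: ZeroMask | None = None, clip: bool | None = None) -> ImputationResult:
    """Replace only the zero entries with the network output.

    Observed entries are copied through bit-identically.  With ``clip``
    (the config default) negative network outputs at zero entries are
    clamped at 0, since expression cannot be negative.
    """
    Xv = X.values if isinstance(X, NormalizedMatrix) else np.asarray(X, dtype=np.float64)
    if Xv.shape[1] != model.spec.n_input:
        raise ValueError("gene count does not match model input width")
    if mask is None:
        mask = compute_mask(Xv)
    if clip is None:
        clip = model.config.clip_nonnegative
    x_out = model.forward(Xv)
    fill = np.maximum(x_out, 0.0) if clip else x_out
    x_imputed = np.where(mask.values, Xv, fill)
    return ImputationResult(x_imputed=x_imputed, x_out=x_out, mask=mask)


def fit_impute(counts: CountMatrix | np.ndarray, spec: NetworkSpec | None = None,
               cfg: TrainConfig | None = None, log_base: float | str = "e"):
    """End-to-end convenience: filter -> normalize -> pretrain -> fine-tune
    -> impute.  Returns an :class:`SCSDAEResults`."""
    model = SCSDAE(counts, spec=spec, config=cfg, log_base=log_base)
    return model.fit()


# ---------------------------------------------------------------------------
# statsmodels-style front door


class SCSDAE:
    """Sparsity-penalized stacked denoising autoencoder imputation model.

    Parameters
    ----------
    data
        Raw counts as a :class:`~scsdae.preprocess.CountMatrix`, a cells x
        genes array, or a DataFrame (rows = cells).  Cells and genes with
        no expression are filtered out and the matrix is log-CPM
        normalized before training.  Pass ``normalized=True`` if the data
        are already on log scale (they are then used as-is, post filter).
    spec
        Network architecture; defaults to n-500-500-2000-10.
    config
        Training configuration (variant, alpha, iteration budgets, seed).

    Examples
    --------
    >>> model = SCSDAE(counts, config=TrainConfig(alpha=1.0, seed=0))
    >>> res = model.fit()
    >>> res.imputed  # doctest: +SKIP
    """

    def __init__(self, data, spec: NetworkSpec | None = None,
                 config: TrainConfig | None = None,
                 normalized: bool = False, log_base: float | str = "e"):
        if not isinstance(data, CountMatrix):
            try:
                import pandas as pd
                if isinstance(data, pd.DataFrame):
                    data = CountMatrix(data.to_numpy(dtype=np.float64),
                                       [str(i) for i in data.index],
                                       [str(c) for c in data.columns])
            except ImportError:  # pragma: no cover
                pass
        if not isinstance(data, CountMatrix):
            data = CountMatrix(np.asarray(data, dtype=np.float64))
        counts = filter_matrix(data)
        if normalized:
            self.data = NormalizedMatrix(counts.values, counts.values.sum(axis=1),
                                         counts.cell_ids, counts.gene_ids)
        else:
            self.data = normalize(counts, log_base=log_base)
        self.counts = counts
        self.mask = compute_mask(self.data)
        self.spec = spec or NetworkSpec.default(self.data.shape[1])
        self.config = config or TrainConfig()
        if self.spec.n_input != self.data.shape[1]:
            raise ValueError("spec input width must equal the (filtered) gene count")

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "SCSDAE":
        return cls(df, **kwargs)

    def fit(self) -> "SCSDAEResults":
        layers, logs = pretrain_layers(self.data, self.spec, self.config)
        trained = stack_and_finetune(self.data, layers, self.spec, self.config, logs)
        result = impute(self.data, trained, self.mask)
        return SCSDAEResults(self, trained, result)


class SCSDAEResults:
    """Fit results: trained weights, training log, and the imputed matrix."""

    def __init__(self, model: SCSDAE, trained: TrainedModel, imputation: ImputationResult):
        self.model = model
        self.trained = trained
        self.imputation = imputation

    @property
    def imputed(self) -> np.ndarray:
        """Imputed matrix (observed entries preserved exactly)."""
        return self.imputation.x_imputed

    @property
    def x_out(self) -> np.ndarray:
        """Raw network reconstruction of every entry."""
        return self.imputation.x_out

    @property
    def embedding(self) -> np.ndarray:
        """Bottleneck (width d_k) representation of each cell."""
        return self.trained.embed(self.model.data.values)

    @property
    def training_log(self) -> dict[str, list[float]]:
        return self.trained.training_log

    def imputed_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.imputed, index=self.model.data.cell_ids,
                            columns=self.model.data.gene_ids)

    def save(self, path: str) -> None:
        self.trained.save(path)

    def summary(self) -> str:
        cfg, spec = self.model.config, self.model.spec
        n_cells, n_genes = self.model.data.shape
        mask = self.imputation.mask.values
        n_zero = int((~mask).sum())
        fill = self.imputation.x_imputed[~mask]
        buf = _io.StringIO()
        w = buf.write
        w("scSDAE Imputation Results\n")
        w("=" * 58 + "\n")
        rows = [
            ("Variant", cfg.variant),
            ("Alpha (L1 weight)", f"{cfg.alpha:g}" if cfg.variant == "scsdae" else "-"),
            ("Cells x genes", f"{n_cells} x {n_genes}"),
            ("Architecture", "-".join(map(str, spec.layer_widths))),
            ("Corruption rate", f"{cfg.corruption_rate:g}"),
            ("Pretrain / finetune iters", f"{cfg.pretrain_iters} / {cfg.finetune_iters}"),
            ("Batch size", f"{min(cfg.batch_size, n_cells)}"),
            ("Seed", f"{cfg.seed}"),
            ("Zero entries (imputed)", f"{n_zero} ({n_zero / mask.size:.1%})"),
            ("Mean imputed value at zeros", f"{fill.mean():.4f}" if n_zero else "-"),
            ("Nonzero imputed at zeros", f"{(fill > 0).mean():.1%}" if n_zero else "-"),
        ]
        ft = self.training_log.get("finetune")
        if ft:
            rows.append(("Final fine-tune loss", f"{ft[-1]:.6f}"))
        for name, val in rows:
            w(f"{name:<30}{val:>28}\n")
        w("=" * 58 + "\n")
        return buf.getvalue()

    def plot_training(self, ax=None):
        """Loss curves per training phase (pretraining layers + fine-tune)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for key, vals in self.training_log.items():
            if vals:
                ax.plot(vals, label=key)
        ax.set_xlabel("minibatch step")
        ax.set_ylabel("loss")
        ax.set_yscale("log")
        ax.legend()
        return ax
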