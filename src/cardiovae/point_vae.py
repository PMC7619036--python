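"""Multi-class variational point-cloud autoencoder for biventricular anatomy.

The encoder ingests the labeled ED+ES point clouds of one subject as a
(2n) x 4 tensor (x, y, z, class label), runs two PointNet-style blocks
(shared per-point MLP -> symmetric max-pool -> global feature concatenated
back to the points) with an additive residual connection, and an MLP head
that outputs the mean and standard deviation of a 16-dimensional diagonal
Gaussian posterior.  The decoder first maps the latent vector to a coarse
multi-class point cloud of m points per channel, then folds a 4 x 4 grid
patch placed around each coarse anchor through a shared MLP conditioned on
the latent vector, producing the dense output of p = 16 m points per
channel.  Channels are laid out phase-major, class-minor.

Training minimises  L_total = L_reconstruction + beta * L_KL  with
L_reconstruction = sum over (phase, class) of the coarse Chamfer term plus
alpha times the dense Chamfer term, alpha following a monotone annealing
ramp.  Chamfer terms inside the loss use squared Euclidean distances (mm^2);
reported evaluation distances use the Euclidean (mm) convention of
:func:`cardiovae.shape_metrics.chamfer_distance`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import nn
from .synthetic_anatomy import AnatomySample, MultiClassPointCloud

__all__ = [
    "PointVAEConfig", "LatentCode", "DecodedAnatomy", "LossBreakdown",
    "PointVAE", "encode", "reparameterize", "decode", "kl_loss",
    "reconstruction_loss", "alpha_schedule", "train", "reconstruct",
    "save_model", "load_model",
]


@dataclass(frozen=True)
class PointVAEConfig:
    """Hyperparameters of the Point VAE.

    ``beta`` weighs the KL term (the KL is summed over latent dimensions so
    beta has a fixed meaning); ``alpha_start``/``alpha_end`` bound the dense
    reconstruction weight ramp.  Desk-scale defaults (m_coarse = 128,
    5,000 steps) keep a full training run around a quarter hour on one CPU
    core; all sizes are exposed so larger budgets can simply raise them.
    """

    latent_dim: int = 16
    n_input_points: int = 1024        # per class per phase
    m_coarse: int = 128
    grid_side: int = 4
    beta: float = 0.2
    alpha_start: float = 0.1
    alpha_end: float = 1.0
    alpha_ramp_fraction: float = 0.5  # ramp over the first half of training
    beta_warmup_steps: int = 0        # linear KL-weight ramp 0 -> beta
    total_steps: int = 5000
    batch_size: int = 4
    phases: int = 2
    n_classes: int = 3
    seed: int = 0
    enc_point_width: int = 32         # per-point feature width
    enc_global_width: int = 64        # second-block pooled feature width
    dec_widths: tuple = (128, 256)
    fold_width: int = 80
    fold_depth: int = 2
    learning_rate: float = 2e-3
    lr_final_fraction: float = 0.05   # linear LR decay to this over the 2nd half
    coord_scale: float = 50.0         # mm; normalises coordinates inside the net
    eval_grid_side: int = 8           # patch sampling density at inference
    val_every: int = 250
    # stochastic subsampling inside the training loss only (inference and
    # evaluation always use every point): encoder point dropout per class
    # per phase, and the number of points queried per Chamfer direction
    train_enc_points: int = 512
    train_query_points: int = 512
    # late-phase refinement: after this fraction of steps the Chamfer query
    # subsample doubles (lower gradient noise near convergence)
    late_refine_fraction: float = 0.8
    # Polyak averaging of the weights over the second half of training;
    # the averaged weights are the ones used at inference
    ema_decay: float = 0.999

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.grid_side < 2:
            raise ValueError("grid_side must be >= 2")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0 <= self.alpha_start <= self.alpha_end:
            raise ValueError("need 0 <= alpha_start <= alpha_end")
        if self.phases not in (1, 2):
            raise ValueError("phases must be 1 or 2")

    @property
    def n_channels(self) -> int:
        return self.phases * self.n_classes

    @property
    def p_dense(self) -> int:
        return self.grid_side**2 * self.m_coarse

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "PointVAEConfig":
        d = json.loads(s)
        d["dec_widths"] = tuple(d["dec_widths"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PointVAEConfig":
        """Load a config from a YAML or TOML file mirroring the fields."""
        text = open(path, "rb").read()
        if str(path).endswith(".toml"):
            import tomllib

            d = tomllib.loads(text.decode())
        else:
            import yaml

            d = yaml.safe_load(text.decode())
        if "dec_widths" in d:
            d["dec_widths"] = tuple(d["dec_widths"])
        return cls(**d)


@dataclass
class LatentCode:
    """Diagonal Gaussian posterior (and optionally a sample) in latent space."""

    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray | None = None

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.sigma))):
            raise ValueError("latent code must be finite")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")


@dataclass
class DecodedAnatomy:
    """Decoder output: coarse (m, 3, C) and dense (p, 3, C) point tensors.

    Channel k encodes phase ``k // n_classes`` and class ``k % n_classes + 1``
    (phase-major, class-minor), phases ordered ED then ES.
    """

    coarse: np.ndarray
    dense: np.ndarray

    def channel(self, which: str, phase_idx: int, class_idx: int, n_classes: int = 3):
        arr = self.coarse if which == "coarse" else self.dense
        return arr[:, :, phase_idx * n_classes + class_idx]


@dataclass
class LossBreakdown:
    """All loss components of one step; total always reconstructs from parts."""

    step: int
    total: float
    kl: float
    alpha: float
    coarse: dict    # (phase_idx, class_idx) -> squared-Chamfer value, mm^2
    dense: dict
    beta: float

    def reconstruction(self) -> float:
        return float(
            sum(self.coarse.values()) + self.alpha * sum(self.dense.values())
        )

    def check_identity(self, rtol: float = 1e-5) -> bool:
        expect = self.reconstruction() + self.beta * self.kl
        return abs(self.total - expect) <= rtol * max(abs(expect), 1.0)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class PointVAE:
    """Parameter container plus forward passes (see module docstring)."""

    def __init__(self, config: PointVAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        w, gw = c.enc_point_width, c.enc_global_width
        P = nn.Parameter
        hi = nn.he_init
        p = {}
        # encoder block 1
        p["e1_w"], p["e1_b"] = P(hi(rng, 4, w)), P(np.zeros(w))
        p["e2_w"], p["e2_b"] = P(hi(rng, w, w)), P(np.zeros(w))
        # encoder block 2 (input: per-point feature ++ tiled global)
        p["e3_w"], p["e3_b"] = P(hi(rng, 2 * w, w)), P(np.zeros(w))
        p["e4_w"], p["e4_b"] = P(hi(rng, w, gw)), P(np.zeros(gw))
        # posterior head on the concatenated pooled features of both blocks
        hw = (w + gw) // 2
        p["h1_w"], p["h1_b"] = P(hi(rng, w + gw, hw)), P(np.zeros(hw))
        p["h2_w"] = P(0.01 * hi(rng, hw, 2 * c.latent_dim))
        p["h2_b"] = P(np.zeros(2 * c.latent_dim))
        # coarse decoder
        d1, d2 = c.dec_widths
        p["d1_w"], p["d1_b"] = P(hi(rng, c.latent_dim, d1)), P(np.zeros(d1))
        p["d2_w"], p["d2_b"] = P(hi(rng, d1, d2)), P(np.zeros(d2))
        n_out = c.m_coarse * 3 * c.n_channels
        p["d3_w"] = P(0.05 * hi(rng, d2, n_out))
        p["d3_b"] = P(np.zeros(n_out))
        # folding MLP: [z, anchor, uv, channel one-hot] -> offset
        fin = c.latent_dim + 3 + 2 + c.n_channels
        fw = c.fold_width
        p["f1_w"], p["f1_b"] = P(hi(rng, fin, fw)), P(np.zeros(fw))
        p["f2_w"], p["f2_b"] = P(hi(rng, fw, fw)), P(np.zeros(fw))
        if c.fold_depth >= 3:
            p["f2b_w"], p["f2b_b"] = P(hi(rng, fw, fw)), P(np.zeros(fw))
        p["f3_w"] = P(0.05 * hi(rng, fw, 3))
        p["f3_b"] = P(np.zeros(3))
        self.params = p
        self._fold_consts = {}
        self.trained = False

    def _fold_const(self, grid_side: int) -> np.ndarray:
        """Per-dense-point (uv, channel one-hot) features, shape (1, C*p, 2+C).

        The folding MLP is a continuous map of the patch coordinates, so it
        can be sampled on any grid density; constants are cached per grid.
        """
        if grid_side not in self._fold_consts:
            c = self.config
            g = np.linspace(-1.0, 1.0, grid_side, dtype=nn.DTYPE)
            uu, vv = np.meshgrid(g, g, indexing="ij")
            uv = np.column_stack([uu.ravel(), vv.ravel()])        # (G^2, 2)
            uv_full = np.tile(uv, (c.n_channels * c.m_coarse, 1))
            onehot = np.repeat(np.eye(c.n_channels, dtype=nn.DTYPE),
                               c.m_coarse * grid_side**2, axis=0)
            self._fold_consts[grid_side] = np.concatenate(
                [uv_full, onehot], axis=1)[None]                  # (1, C*p, 2+C)
        return self._fold_consts[grid_side]

    # ---- forward passes ------------------------------------------------
    def encoder_forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """x: (B, N, 4) normalized; returns (mu, logvar) tensors (B, latent).

        The 4th input column carries a joint phase-class code
        ((class - 2) + 3 * phase) so the per-point features can separate
        both phase and substructure.
        """
        p = self.params
        B, N, _ = x.shape
        h = nn.relu(nn.linear(x, p["e1_w"], p["e1_b"]))
        f1 = nn.relu(nn.linear(h, p["e2_w"], p["e2_b"]))
        g1 = nn.max_pool_axis1(f1)                            # (B, w)
        ones = nn.Tensor(np.ones((1, N, 1), dtype=nn.DTYPE))
        g1_tiled = ones @ g1.reshape(B, 1, -1)                # (B, N, w)
        cat = nn.concat([f1, g1_tiled], axis=-1)
        f2 = nn.relu(nn.linear(cat, p["e3_w"], p["e3_b"])) + f1   # residual
        f3 = nn.relu(nn.linear(f2, p["e4_w"], p["e4_b"]))
        g2 = nn.max_pool_axis1(f3)                            # (B, gw)
        g = nn.concat([g1, g2], axis=-1)
        hh = nn.relu(nn.linear(g, p["h1_w"], p["h1_b"]))
        out = nn.linear(hh, p["h2_w"], p["h2_b"])             # (B, 2*latent)
        L = self.config.latent_dim
        mu = _slice_last(out, 0, L)
        logvar = _slice_last(out, L, 2 * L)
        return mu, logvar

    def decoder_forward(self, z: nn.Tensor,
                        grid_side: int | None = None
                        ) -> tuple[nn.Tensor, nn.Tensor]:
        """z: (B, latent); returns coarse (B, C, m, 3), dense (B, C, p, 3)
        with p = grid_side^2 * m (training default from the config)."""
        p, c = self.params, self.config
        gs = c.grid_side if grid_side is None else grid_side
        B = z.shape[0]
        h = nn.relu(nn.linear(z, p["d1_w"], p["d1_b"]))
        h = nn.relu(nn.linear(h, p["d2_w"], p["d2_b"]))
        coarse = nn.linear(h, p["d3_w"], p["d3_b"]).reshape(
            B, c.n_channels, c.m_coarse, 3
        )
        # anchors replicated for each grid patch point
        G2 = gs**2
        p_dense = G2 * c.m_coarse
        anchors = _repeat_axis2(coarse, G2)                   # (B, C, m*G2, 3)
        anchors_flat = anchors.reshape(B, c.n_channels * p_dense, 3)
        n_pts = c.n_channels * p_dense
        ones = nn.Tensor(np.ones((1, n_pts, 1), dtype=nn.DTYPE))
        z_tiled = ones @ z.reshape(B, 1, c.latent_dim)
        fc = self._fold_const(gs)
        const = nn.Tensor(np.broadcast_to(fc, (B,) + fc.shape[1:]))
        feat = nn.concat([z_tiled, anchors_flat, const], axis=-1)
        f = nn.relu(nn.linear(feat, p["f1_w"], p["f1_b"]))
        f = nn.relu(nn.linear(f, p["f2_w"], p["f2_b"]))
        if c.fold_depth >= 3:
            f = nn.relu(nn.linear(f, p["f2b_w"], p["f2b_b"]))
        offset = nn.linear(f, p["f3_w"], p["f3_b"])
        dense = (anchors_flat + offset).reshape(B, c.n_channels, p_dense, 3)
        return coarse, dense


def _slice_last(t: nn.Tensor, lo: int, hi: int) -> nn.Tensor:
    def bwd(g):
        if t.requires_grad:
            nn._grad_buffer(t)[..., lo:hi] += g

    return nn.Tensor(t.data[..., lo:hi], (t,), bwd)


def _repeat_axis2(t: nn.Tensor, k: int) -> nn.Tensor:
    """(B, C, m, 3) -> (B, C, m*k, 3) repeating each point k times."""
    B, C, m, d = t.data.shape

    def bwd(g):
        if t.requires_grad:
            nn._accum(t, g.reshape(B, C, m, k, d).sum(axis=3))

    out = np.repeat(t.data, k, axis=2)
    return nn.Tensor(out, (t,), bwd)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _phase_clouds(sample, config: PointVAEConfig) -> list[MultiClassPointCloud]:
    if isinstance(sample, AnatomySample):
        if config.phases != 2:
            raise ValueError("phases: model is single-phase but got an ED/ES pair")
        return [sample.ed, sample.es]
    if isinstance(sample, MultiClassPointCloud):
        if config.phases != 1:
            raise ValueError("phases: model is two-phase but got a single cloud")
        return [sample]
    raise TypeError(f"unsupported input type {type(sample).__name__}")


def prepare_sample(sample, config: PointVAEConfig):
    """Per-subject arrays: encoder input, per-channel targets (mm), center.

    Coordinates are centered at the subject's joint ED/ES centroid; the
    encoder input additionally divides by ``coord_scale`` and appends the
    centered class label (label - 2 in {-1, 0, 1}).  Targets stay in
    centered mm so that loss values are in mm^2.
    """
    clouds = _phase_clouds(sample, config)
    n = config.n_input_points
    all_pts = np.vstack([c.points for c in clouds])
    center = all_pts.mean(axis=0)
    enc_rows, targets = [], []
    for phase_idx, cloud in enumerate(clouds):
        present = np.unique(cloud.labels)
        for class_id in range(1, config.n_classes + 1):
            if class_id not in present:
                raise ValueError(f"labels: class {class_id} missing from input cloud")
            pts = cloud.points_of_class(class_id)
            if pts.shape[0] != n:
                raise ValueError(
                    f"n_input_points: class {class_id} has {pts.shape[0]} points, "
                    f"model expects {n}"
                )
            centered = (pts - center).astype(nn.DTYPE)
            targets.append(centered)
            # 4th column: joint phase-class code (ED classes -1,0,1;
            # ES classes shifted by +3) so the per-point MLP can separate
            # both phase and substructure
            code = (class_id - 2) + 3 * phase_idx
            enc_rows.append(np.column_stack([
                centered / config.coord_scale,
                np.full(n, code, dtype=nn.DTYPE),
            ]))
    return np.vstack(enc_rows).astype(nn.DTYPE), targets, center


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def encode(sample, model: PointVAE) -> LatentCode:
    """Posterior (mu, sigma) for one subject; permutation-invariant."""
    enc_in, _, _ = prepare_sample(sample, model.config)
    mu, logvar = model.encoder_forward(nn.Tensor(enc_in[None]))
    sigma = np.exp(0.5 * logvar.data[0].astype(float))
    return LatentCode(mu=mu.data[0].astype(float), sigma=sigma)


def reparameterize(code: LatentCode, seed: int) -> np.ndarray:
    """z = mu + sigma * eps with eps ~ N(0, I) drawn from ``seed``."""
    eps = np.random.default_rng(seed).standard_normal(code.mu.shape)
    return code.mu + code.sigma * eps


def decode(z, model: PointVAE, grid_side: int | None = None) -> DecodedAnatomy:
    """Deterministic decode of a latent vector into coarse+dense clouds (mm,
    centered at the origin).

    ``grid_side`` optionally samples each learned folding patch on a denser
    grid than the training 4 x 4 (the fold is a continuous parametric
    surface); the dense output then has grid_side^2 * m points per channel.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[None]
    if not np.all(np.isfinite(z)):
        raise ValueError("z contains non-finite values")
    if z.shape[1] != model.config.latent_dim:
        raise ValueError(
            f"z has length {z.shape[1]}, expected {model.config.latent_dim}"
        )
    coarse, dense = model.decoder_forward(nn.Tensor(z.astype(nn.DTYPE)),
                                          grid_side=grid_side)
    # (B, C, m, 3) -> (m, 3, C) for B == 1
    return DecodedAnatomy(
        coarse=np.moveaxis(coarse.data[0].astype(float), 0, -1),
        dense=np.moveaxis(dense.data[0].astype(float), 0, -1),
    )


def kl_loss(code: LatentCode) -> float:
    """Closed-form KL(Q(z|X) || N(0, I)) summed over latent dimensions."""
    mu, s2 = code.mu, code.sigma**2
    return float(0.5 * np.sum(mu**2 + s2 - 1.0 - np.log(s2)))


def _kl_tensor(mu: nn.Tensor, logvar: nn.Tensor) -> nn.Tensor:
    """Batch-mean KL, summed over latent dims, as a graph node."""
    B = mu.shape[0]
    neg = nn.Tensor(-1.0)
    term = mu.square() + logvar.exp() + neg * logvar + neg
    return nn.Tensor(0.5 / B) * term.sum()


def _dir_term(pred: nn.Tensor, rows, ref_pts: np.ndarray) -> nn.Tensor:
    """Mean squared distance from selected predicted rows to fixed points.

    ``pred`` is (1, M, 3); ``rows`` indexes the predicted points paired with
    ``ref_pts`` (k, 3), or None to pair every row in order.
    """
    sel = nn.gather(pred, rows[None]) if rows is not None else pred
    diff = sel - nn.Tensor(ref_pts[None])
    return diff.square().sum() * nn.Tensor(1.0 / ref_pts.shape[0])


def _fast_chamfer_sq(pred: nn.Tensor, target: np.ndarray, target_tree: cKDTree,
                     rng: np.random.Generator, n_query: int) -> nn.Tensor:
    """Stochastic symmetric squared Chamfer for the training loss.

    Both directions are estimated on random subsets of at most ``n_query``
    points per side (an unbiased mini-batching of the point sums); nearest
    neighbours are exact over the full opposite set.
    """
    pd = pred.data[0]
    M = pd.shape[0]
    # predicted -> target
    if M > n_query:
        rows_p = rng.integers(0, M, size=n_query)
        qp = pd[rows_p]
    else:
        rows_p, qp = None, pd
    ref_p = target[target_tree.query(qp)[1]]
    term1 = _dir_term(pred, rows_p, ref_p)
    # target -> predicted
    n = target.shape[0]
    tsub = target if n <= n_query else target[rng.integers(0, n, size=n_query)]
    tree_pred = cKDTree(pd, balanced_tree=False, compact_nodes=False)
    rows_t = tree_pred.query(tsub)[1]
    term2 = _dir_term(pred, rows_t, tsub)
    return nn.Tensor(0.5) * (term1 + term2)


def _chamfer_sq_tensor(pred: nn.Tensor, target: np.ndarray,
                       target_tree: cKDTree) -> nn.Tensor:
    """Squared symmetric Chamfer between predicted (B, M, 3) and a fixed
    target (n, 3) shared across the batch, as a graph node (mm^2)."""
    B, M, _ = pred.shape
    pd = pred.data
    # nearest target for each predicted point
    flat = pd.reshape(-1, 3).astype(np.float64)
    idx_p2t = target_tree.query(flat)[1].reshape(B, M)
    t_sel = target[idx_p2t]  # (B, M, 3) constant
    term1 = (pred - nn.Tensor(t_sel)).square().sum() * nn.Tensor(1.0 / (B * M))
    # nearest predicted point for each target point, per batch element
    n = target.shape[0]
    idx_t2p = np.empty((B, n), dtype=np.int64)
    for b in range(B):
        idx_t2p[b] = cKDTree(pd[b]).query(target)[1]
    p_sel = nn.gather(pred, idx_t2p)  # (B, n, 3)
    term2 = (p_sel - nn.Tensor(np.broadcast_to(target, (B, n, 3)))).square().sum() \
        * nn.Tensor(1.0 / (B * n))
    return nn.Tensor(0.5) * (term1 + term2)


def reconstruction_loss(out: DecodedAnatomy, target, alpha: float,
                        config: PointVAEConfig | None = None) -> LossBreakdown:
    """Coarse + alpha*dense squared-Chamfer terms per (phase, class).

    Numpy-level evaluation counterpart of the in-graph training loss; target
    is an :class:`AnatomySample` (or single-phase cloud) whose channels must
    match the decoder layout.  Coordinates are compared in centered mm.
    """
    config = config or PointVAEConfig()
    _, targets, _ = prepare_sample(target, config)
    coarse_terms, dense_terms = {}, {}
    for k, tgt in enumerate(targets):
        if tgt.shape[0] == 0:
            raise ValueError(f"empty target subset for channel {k}")
        ph, cl = divmod(k, config.n_classes)
        from .shape_metrics import chamfer_distance

        coarse_terms[(ph, cl)] = chamfer_distance(out.coarse[:, :, k], tgt, squared=True)
        dense_terms[(ph, cl)] = chamfer_distance(out.dense[:, :, k], tgt, squared=True)
    recon = sum(coarse_terms.values()) + alpha * sum(dense_terms.values())
    return LossBreakdown(step=-1, total=recon, kl=0.0, alpha=alpha,
                         coarse=coarse_terms, dense=dense_terms, beta=0.0)


def alpha_schedule(step: int, config: PointVAEConfig) -> float:
    """Monotone annealing: linear ramp alpha_start -> alpha_end over the
    first ``alpha_ramp_fraction`` of training, constant afterwards."""
    if not 0 <= step <= config.total_steps:
        raise ValueError(f"step {step} outside [0, {config.total_steps}]")
    ramp = max(1, int(config.alpha_ramp_fraction * config.total_steps))
    frac = min(step / ramp, 1.0)
    return config.alpha_start + (config.alpha_end - config.alpha_start) * frac


def train(dataset, config: PointVAEConfig, val_dataset=None,
          progress: bool = False):
    """Train a Point VAE end-to-end; returns (model, history DataFrame).

    The history records every loss component per step (validation total loss
    every ``val_every`` steps when a validation set is given).  All
    randomness (init, batch order, reparameterization noise) derives from
    ``config.seed``, so identical config + data reproduce the run exactly.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("training dataset is empty")
    model = PointVAE(config)
    prepared = [prepare_sample(s, config) for s in dataset]
    enc_all = np.stack([p[0] for p in prepared])
    targets_all = [p[1] for p in prepared]
    # fixed KD-trees over each sample's per-channel targets
    trees_all = [[cKDTree(t) for t in ts] for ts in targets_all]
    val_prep = None
    if val_dataset:
        val_prep = [prepare_sample(s, config) for s in val_dataset]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    opt = nn.Adam(model.params, lr=config.learning_rate)
    ema = None
    history = []
    n = len(dataset)
    C = config.n_channels
    n_in, n_cls = config.n_input_points, config.n_classes
    blocks = config.phases * n_cls
    half = config.total_steps // 2
    for step in range(config.total_steps):
        if step >= half and config.total_steps > half:
            frac = (step - half) / max(config.total_steps - half, 1)
            opt.lr = config.learning_rate * (
                1.0 - (1.0 - config.lr_final_fraction) * frac)
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        alpha = alpha_schedule(step, config)
        if config.train_enc_points < n_in:
            # encoder point dropout: a random subset per class-phase block
            sub = (rng.integers(0, n_in, size=(blocks, config.train_enc_points))
                   + np.arange(blocks)[:, None] * n_in).ravel()
            x = nn.Tensor(enc_all[idx][:, sub])
        else:
            x = nn.Tensor(enc_all[idx])
        mu, logvar = model.encoder_forward(x)
        eps = rng.standard_normal(mu.shape).astype(nn.DTYPE)
        sigma = (nn.Tensor(0.5) * logvar).exp()
        z = mu + sigma * nn.Tensor(eps)
        coarse, dense = model.decoder_forward(z)
        kl = _kl_tensor(mu, logvar)
        beta_t = config.beta
        if config.beta_warmup_steps > 0:
            beta_t *= min(1.0, (step + 1) / config.beta_warmup_steps)
        total = nn.Tensor(beta_t) * kl
        coarse_terms, dense_terms = {}, {}
        for k in range(C):
            # all batch samples share channel layout but have different
            # targets; loop batch elements grouped per channel via shared
            # trees (targets differ per sample, so Chamfer is per-element)
            ph, cl = divmod(k, config.n_classes)
            c_term = nn.Tensor(0.0)
            d_term = nn.Tensor(0.0)
            nq = config.train_query_points
            if step >= config.late_refine_fraction * config.total_steps:
                nq = min(2 * nq, config.n_input_points)
            for j, b in enumerate(idx):
                tgt, tree = targets_all[b][k], trees_all[b][k]
                c_term = c_term + _fast_chamfer_sq(
                    _slice_batch(coarse, j, k), tgt, tree, rng, nq)
                d_term = d_term + _fast_chamfer_sq(
                    _slice_batch(dense, j, k), tgt, tree, rng, nq)
            inv = nn.Tensor(1.0 / len(idx))
            c_term, d_term = c_term * inv, d_term * inv
            coarse_terms[(ph, cl)] = float(c_term.data)
            dense_terms[(ph, cl)] = float(d_term.data)
            total = total + c_term + nn.Tensor(alpha) * d_term
        if not np.isfinite(total.data):
            raise RuntimeError(f"training diverged: non-finite loss at step {step}")
        total.backward()
        opt.step()
        if config.ema_decay and step >= half:
            if ema is None:
                ema = {k: p.data.copy() for k, p in model.params.items()}
            else:
                d = config.ema_decay
                for k, p in model.params.items():
                    ema[k] *= d
                    ema[k] += (1.0 - d) * p.data
        rec = LossBreakdown(step=step, total=float(total.data),
                            kl=float(kl.data), alpha=alpha,
                            coarse=coarse_terms, dense=dense_terms,
                            beta=beta_t)
        history.append(rec)
        if progress and step % 200 == 0:
            print(f"step {step}: total={rec.total:.3f} kl={rec.kl:.3f}")
    if ema is not None:
        for k, p in model.params.items():
            p.data = ema[k]
    model.trained = True
    hist = pd.DataFrame([{
        "step": h.step, "total": h.total, "kl": h.kl, "alpha": h.alpha,
        "reconstruction": h.reconstruction(),
        **{f"coarse_p{p}c{c}": v for (p, c), v in h.coarse.items()},
        **{f"dense_p{p}c{c}": v for (p, c), v in h.dense.items()},
    } for h in history])
    if val_prep is not None:
        hist.attrs["val"] = _validation_curve(model, val_prep, config)
    return model, hist


def _slice_batch(t: nn.Tensor, j: int, k: int) -> nn.Tensor:
    """Select (batch j, channel k) from a (B, C, M, 3) tensor -> (1, M, 3)."""

    def bwd(g):
        if t.requires_grad:
            nn._grad_buffer(t)[j, k] += g[0]

    return nn.Tensor(t.data[j, k][None], (t,), bwd)


def _validation_curve(model, val_prep, config):
    losses = []
    for enc_in, targets, _ in val_prep:
        mu, logvar = model.encoder_forward(nn.Tensor(enc_in[None]))
        coarse, dense = model.decoder_forward(mu)
        tot = config.beta * float(_kl_tensor(mu, logvar).data)
        for k, tgt in enumerate(targets):
            tree = cKDTree(tgt)
            tot += float(_chamfer_sq_tensor(_slice_batch(coarse, 0, k), tgt, tree).data)
            tot += config.alpha_end * float(
                _chamfer_sq_tensor(_slice_batch(dense, 0, k), tgt, tree).data)
        losses.append(tot)
    return float(np.mean(losses))


def reconstruct(model: PointVAE, sample,
                grid_side: int | None = None) -> AnatomySample:
    """Noiseless reconstruction: encode with z = mu, decode, re-label.

    Returns an :class:`AnatomySample` whose ED/ES clouds are the dense
    decoder outputs, shifted back to the subject's original centroid.  The
    learned folding patches are sampled at ``eval_grid_side`` (default 8,
    p = 64 m points per channel) — denser than the 4 x 4 training grid,
    which refines the reconstructed surface representation at no training
    cost.
    """
    config = model.config
    enc_in, _, center = prepare_sample(sample, config)
    mu, _ = model.encoder_forward(nn.Tensor(enc_in[None]))
    gs = grid_side if grid_side is not None else config.eval_grid_side
    dec = decode(mu.data[0], model, grid_side=gs)
    clouds = []
    p = gs**2 * config.m_coarse
    for ph, phase in enumerate(["ED", "ES"][: config.phases]):
        pts, labels = [], []
        for cl in range(config.n_classes):
            ch = dec.dense[:, :, ph * config.n_classes + cl] + center
            pts.append(ch)
            labels.append(np.full(p, cl + 1))
        clouds.append(MultiClassPointCloud(
            points=np.vstack(pts), labels=np.concatenate(labels), phase=phase))
    if config.phases == 1:
        return clouds[0]
    sid = getattr(sample, "subject_id", "reconstruction")
    return AnatomySample(subject_id=f"{sid}-recon", ed=clouds[0], es=clouds[1])


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: PointVAE, path) -> None:
    """Single-archive checkpoint: JSON config + weights (bit-exact reload)."""
    arrays = {k: p.data for k, p in model.params.items()}
    np.savez(path, __config__=np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8), **arrays)


def load_model(path) -> PointVAE:
    with np.load(path) as z:
        config = PointVAEConfig.from_json(bytes(z["__config__"]).decode())
        model = PointVAE(config)
        for k in model.params:
            model.params[k].data = z[k].astype(nn.DTYPE)
    model.trained = True
    return model
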