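"""Cascade graph encoder with view-proxy loss.

The encoder compresses each kernel slice of a barcode-like timeline to a 2D
latent point; the ordered points form the graph chart diagram.  Two devices
shape the latent space:

* **Cascade wiring** — separate sub-auto-encoders first compress the
  4-channel vessels block and the 8-channel heart block of a slice to 2D
  each (the sub-graph chart diagrams); their latents, concatenated with the
  flattened 6-channel others block, feed a main auto-encoder whose 2-neuron
  bottleneck yields the main diagram.
* **View-proxy loss** — the encodings of synthesized ideal 4CV and 3VTV
  slices are pulled toward fixed anchor coordinates (0,1) and (1,0)
  (squared Euclidean distance, main diagram only).  Real diagnostic-plane
  frames carry no annotations, so the synthetic ideal slices act as proxies;
  attracting them pins the diagram's orientation across trainings.

Training is one-class: only normal sweeps are ever consumed.  The total
objective is ``lambda_recon * reconstruction + lambda_proxy * view_proxy``.
Sub blocks use binary cross-entropy; the main auto-encoder reconstructs its
own mixed input (real-valued sub-latents + binary others block) with MSE on
the latent dims (targets detached) and BCE on the binary dims.

`GraphChartEncoder` follows the scikit-learn estimator protocol
(``fit`` / ``transform`` / ``get_params``), so it composes with sklearn
model-selection utilities; the module-level ``train`` / ``encode_slice`` /
``make_ablation_variant`` functions are thin wrappers over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import MLP, Adam, bce_logits, bce_logits_grad
from .registry import SubstructureRegistry, default_registry
from .timeline import BarcodeTimeline, KernelSlice, slice_matrix, synthesize_ideal_slice

__all__ = [
    "PROXY_TARGETS",
    "LatentPoint",
    "GraphChartEncoder",
    "train",
    "encode_slice",
    "view_proxy_loss",
    "make_ablation_variant",
    "ABLATION_VARIANTS",
]

#: Anchor coordinates the ideal diagnostic-plane encodings are pulled toward.
PROXY_TARGETS: dict[str, tuple[float, float]] = {
    "FOUR_CV": (0.0, 1.0),
    "THREE_VTV": (1.0, 0.0),
}

#: Table-style ablation grid: (use_cascade, use_view_proxy) -> variant label.
ABLATION_VARIANTS: dict[tuple[bool, bool], str] = {
    (True, True): "cascade+proxy",
    (True, False): "cascade",
    (False, True): "proxy",
    (False, False): "simple",
}


@dataclass(frozen=True)
class LatentPoint:
    """2D encodings of one kernel slice (main + optional sub diagrams)."""

    main: tuple[float, float]
    kernel_start: int = 0
    sub_vessels: tuple[float, float] | None = None
    sub_heart: tuple[float, float] | None = None


def _group_flat_indices(registry: SubstructureRegistry, group: str, width: int):
    """Flat column indices of a group inside a frame-major flattened slice."""
    ch = registry.group_indices(group)
    C = registry.n_channels
    return np.array([f * C + c for f in range(width) for c in ch])


class _CascadeCore:
    """Weights + forward/backward of the cascade (or simple) auto-encoder."""

    def __init__(
        self,
        width: int,
        registry: SubstructureRegistry,
        hidden: tuple[int, int],
        use_cascade: bool,
        rng: np.random.Generator,
    ):
        self.width = width
        self.registry = registry
        self.use_cascade = use_cascade
        h1, h2 = hidden
        if use_cascade:
            self.iv = _group_flat_indices(registry, "vessels", width)
            self.ih = _group_flat_indices(registry, "heart", width)
            self.io = _group_flat_indices(registry, "others", width)
            nv, nh, no = len(self.iv), len(self.ih), len(self.io)
            self.enc_v = MLP([nv, h1, h2, 2], rng)
            self.dec_v = MLP([2, h2, h1, nv], rng)
            self.enc_h = MLP([nh, h1, h2, 2], rng)
            self.dec_h = MLP([2, h2, h1, nh], rng)
            self.enc_m = MLP([4 + no, h1, h2, 2], rng)
            self.dec_m = MLP([2, h2, h1, 4 + no], rng)
            self.nets = [self.enc_v, self.dec_v, self.enc_h, self.dec_h,
                         self.enc_m, self.dec_m]
        else:
            n = width * registry.n_channels
            self.enc = MLP([n, h1, h2, 2], rng)
            self.dec = MLP([2, h2, h1, n], rng)
            self.nets = [self.enc, self.dec]

    @property
    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for net in self.nets:
            out.extend(net.params)
        return out

    # ---- inference -------------------------------------------------------

    def encode(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Latents for a batch of flattened slices.

        Returns ``{"main": (n,2)}`` plus ``sub_vessels`` / ``sub_heart`` for
        cascade models.
        """
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if not self.use_cascade:
            return {"main": self.enc(X)}
        zv = self.enc_v(X[:, self.iv])
        zh = self.enc_h(X[:, self.ih])
        u = np.concatenate([zv, zh, X[:, self.io]], axis=1)
        return {"main": self.enc_m(u), "sub_vessels": zv, "sub_heart": zh}

    # ---- training --------------------------------------------------------

    def _zero_grads(self) -> list[np.ndarray]:
        return [np.zeros_like(p) for p in self.params]

    def loss_grads(
        self,
        X: np.ndarray,
        proxies: dict[str, np.ndarray] | None,
        lambda_recon: float,
        lambda_proxy: float,
        stage: str = "joint",
    ) -> tuple[dict[str, float], list[np.ndarray]]:
        """Losses and parameter gradients for one minibatch.

        ``stage`` selects joint end-to-end training (default), or the two
        phases of the optional stage-wise mode: ``"sub"`` (sub-auto-encoders
        only) and ``"main"`` (main + proxy, sub weights frozen).
        """
        if self.use_cascade:
            return self._cascade_loss_grads(
                X, proxies, lambda_recon, lambda_proxy, stage
            )
        return self._simple_loss_grads(X, proxies, lambda_recon, lambda_proxy)

    def _simple_loss_grads(self, X, proxies, lr_w, lp_w):
        grads = self._zero_grads()
        z, ce = self.enc.forward(X)
        logits, cd = self.dec.forward(z)
        L_recon = bce_logits(logits, X)

        d_logits = lr_w * bce_logits_grad(logits, X)
        dz, g_dec = self.dec.backward(cd, d_logits)
        _, g_enc = self.enc.backward(ce, dz)
        n_enc = len(self.enc.params)
        for i, g in enumerate(g_enc):
            grads[i] += g
        for i, g in enumerate(g_dec):
            grads[n_enc + i] += g

        L_proxy = 0.0
        if proxies is not None:
            for plane, xp in proxies.items():
                target = np.array(PROXY_TARGETS[plane])
                zp, cep = self.enc.forward(xp)
                diff = zp - target
                L_proxy += float(np.sum(diff**2))
                _, g_enc = self.enc.backward(cep, lp_w * 2.0 * diff)
                for i, g in enumerate(g_enc):
                    grads[i] += g
        losses = {
            "recon": L_recon,
            "proxy": L_proxy,
            "total": lr_w * L_recon + lp_w * L_proxy,
        }
        return losses, grads

    def _cascade_loss_grads(self, X, proxies, lr_w, lp_w, stage):
        grads = self._zero_grads()
        offsets = []
        k = 0
        for net in self.nets:
            offsets.append(k)
            k += len(net.params)

        def add(net_idx: int, gs: list[np.ndarray]) -> None:
            o = offsets[net_idx]
            for i, g in enumerate(gs):
                grads[o + i] += g

        xv, xh, xo = X[:, self.iv], X[:, self.ih], X[:, self.io]
        zv, cev = self.enc_v.forward(xv)
        pv, cdv = self.dec_v.forward(zv)
        zh, ceh = self.enc_h.forward(xh)
        ph, cdh = self.dec_h.forward(zh)
        u = np.concatenate([zv, zh, xo], axis=1)
        zm, cem = self.enc_m.forward(u)
        pm, cdm = self.dec_m.forward(zm)

        L_sub = bce_logits(pv, xv) + bce_logits(ph, xh)
        lat, lat_t = pm[:, :4], u[:, :4]  # latent targets detached
        L_main = float(np.mean((lat - lat_t) ** 2)) + bce_logits(pm[:, 4:], xo)
        L_recon = L_sub + L_main

        dzv_acc = np.zeros_like(zv)
        dzh_acc = np.zeros_like(zh)

        if stage in ("joint", "main"):
            d_pm = np.empty_like(pm)
            d_pm[:, :4] = lr_w * 2.0 * (lat - lat_t) / lat.size
            d_pm[:, 4:] = lr_w * bce_logits_grad(pm[:, 4:], xo)
            dzm, g_dm = self.dec_m.backward(cdm, d_pm)
            du, g_em = self.enc_m.backward(cem, dzm)
            add(5, g_dm)
            add(4, g_em)
            if stage == "joint":
                dzv_acc += du[:, :2]
                dzh_acc += du[:, 2:4]

        if stage in ("joint", "sub"):
            d_pv = lr_w * bce_logits_grad(pv, xv)
            dzv, g_dv = self.dec_v.backward(cdv, d_pv)
            add(1, g_dv)
            dzv_acc += dzv
            d_ph = lr_w * bce_logits_grad(ph, xh)
            dzh, g_dh = self.dec_h.backward(cdh, d_ph)
            add(3, g_dh)
            dzh_acc += dzh

        if stage != "main":
            _, g_ev = self.enc_v.backward(cev, dzv_acc)
            add(0, g_ev)
            _, g_eh = self.enc_h.backward(ceh, dzh_acc)
            add(2, g_eh)

        L_proxy = 0.0
        if proxies is not None and stage in ("joint", "main"):
            for plane, xp in proxies.items():
                target = np.array(PROXY_TARGETS[plane])
                zvp, cevp = self.enc_v.forward(xp[:, self.iv])
                zhp, cehp = self.enc_h.forward(xp[:, self.ih])
                up = np.concatenate([zvp, zhp, xp[:, self.io]], axis=1)
                zmp, cemp = self.enc_m.forward(up)
                diff = zmp - target
                L_proxy += float(np.sum(diff**2))
                dup, g_em = self.enc_m.backward(cemp, lp_w * 2.0 * diff)
                add(4, g_em)
                if stage == "joint":
                    _, g_ev = self.enc_v.backward(cevp, dup[:, :2])
                    add(0, g_ev)
                    _, g_eh = self.enc_h.backward(cehp, dup[:, 2:4])
                    add(2, g_eh)

        losses = {
            "recon": L_recon,
            "proxy": L_proxy,
            "total": lr_w * L_recon + lp_w * L_proxy,
        }
        return losses, grads


class GraphChartEncoder(BaseEstimator, TransformerMixin):
    """Auto-encoder that turns barcode-timeline kernel slices into 2D points.

    Parameters
    ----------
    kernel_width, kernel_stride
        Sliding-window size and step (frames) used when building diagrams.
    hidden_sizes
        Hidden-layer widths of every encoder/decoder.
    use_cascade
        Wire vessels/heart sub-auto-encoders in front of the main one.
        ``False`` gives the simple-auto-encoder ablation (18*w inputs).
    use_view_proxy
        Add the view-proxy loss pulling ideal 4CV / 3VTV encodings toward
        (0,1) / (1,0).
    epochs, batch_size, learning_rate
        Adam training schedule.
    lambda_recon, lambda_proxy
        Loss weights; the proxy term is added to every minibatch.
    train_stride
        Kernel stride used to harvest training slices (coarser than the
        diagram stride purely to cut redundant windows).
    training_mode
        ``"joint"`` trains sub and main nets end-to-end; ``"stagewise"``
        trains the sub-auto-encoders first, then the main one with sub
        weights frozen.

    Attributes
    ----------
    core_ : the trained network stack
    loss_history_ : per-epoch DataFrame (recon / proxy / total)
    proxy_distances_, initial_proxy_distances_ : Euclidean distance of each
        ideal-plane encoding to its anchor, after and before training.
    """

    def __init__(
        self,
        kernel_width: int = 16,
        kernel_stride: int = 1,
        hidden_sizes: tuple[int, int] = (64, 16),
        use_cascade: bool = True,
        use_view_proxy: bool = True,
        epochs: int = 80,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        lambda_recon: float = 1.0,
        lambda_proxy: float = 1.0,
        train_stride: int = 4,
        training_mode: str = "joint",
        random_state: int = 0,
        registry: SubstructureRegistry | None = None,
    ):
        self.kernel_width = kernel_width
        self.kernel_stride = kernel_stride
        self.hidden_sizes = hidden_sizes
        self.use_cascade = use_cascade
        self.use_view_proxy = use_view_proxy
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lambda_recon = lambda_recon
        self.lambda_proxy = lambda_proxy
        self.train_stride = train_stride
        self.training_mode = training_mode
        self.random_state = random_state
        self.registry = registry

    # ---- helpers ---------------------------------------------------------

    def _registry(self) -> SubstructureRegistry:
        return self.registry or default_registry()

    def _proxy_inputs(self) -> dict[str, np.ndarray]:
        reg = self._registry()
        return {
            plane: synthesize_ideal_slice(plane, reg, self.kernel_width).flatten()[None, :]
            for plane in PROXY_TARGETS
        }

    def _ideal_distances(self) -> dict[str, float]:
        out = {}
        for plane, xp in self._proxy_inputs().items():
            z = self.core_.encode(xp)["main"][0]
            out[plane] = float(np.linalg.norm(z - np.array(PROXY_TARGETS[plane])))
        return out

    # ---- estimator API ---------------------------------------------------

    def fit(self, X: list[BarcodeTimeline], y=None) -> "GraphChartEncoder":
        """Train on normal sweeps only (one-class contract).

        ``X`` is a collection of :class:`BarcodeTimeline`; an
        abnormal-labelled timeline raises ``ValueError``.
        """
        if self.training_mode not in ("joint", "stagewise"):
            raise ValueError(f"unknown training_mode {self.training_mode!r}")
        timelines = list(X)
        if not timelines:
            raise ValueError("no training timelines")
        for tl in timelines:
            if getattr(tl, "label", "normal") != "normal":
                raise ValueError(
                    "one-class training: abnormal-labelled timeline "
                    f"{tl.video_id!r} in training set"
                )
        reg = self._registry()
        rng = np.random.default_rng(self.random_state)
        Xtr = np.concatenate(
            [slice_matrix(tl, self.kernel_width, self.train_stride) for tl in timelines]
        )
        self.n_features_in_ = Xtr.shape[1]

        self.core_ = _CascadeCore(
            self.kernel_width, reg, tuple(self.hidden_sizes), self.use_cascade, rng
        )
        proxies = self._proxy_inputs() if self.use_view_proxy else None
        self.initial_proxy_distances_ = self._ideal_distances()

        opt = Adam(self.core_.params, lr=self.learning_rate)
        if self.training_mode == "joint":
            schedule = [("joint", self.epochs)]
        else:
            half = max(1, self.epochs // 2)
            schedule = [("sub", half), ("main", self.epochs - half or 1)]

        history: list[dict[str, float]] = []
        n = Xtr.shape[0]
        for stage, n_epochs in schedule:
            for _ in range(n_epochs):
                order = rng.permutation(n)
                ep = {"recon": 0.0, "proxy": 0.0, "total": 0.0}
                n_batches = 0
                for lo in range(0, n, self.batch_size):
                    batch = Xtr[order[lo : lo + self.batch_size]]
                    losses, grads = self.core_.loss_grads(
                        batch, proxies, self.lambda_recon, self.lambda_proxy, stage
                    )
                    opt.step(grads)
                    for k in ep:
                        ep[k] += losses[k]
                    n_batches += 1
                history.append(
                    {"stage": stage, **{k: v / n_batches for k, v in ep.items()}}
                )
        self.loss_history_ = pd.DataFrame(history)
        self.proxy_distances_ = self._ideal_distances()
        self.ideal_latents_ = {
            plane: tuple(self.core_.encode(xp)["main"][0])
            for plane, xp in self._proxy_inputs().items()
        }
        return self

    def encode(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Latents of flattened slices; keys ``main`` (+ subs for cascade)."""
        self._check_fitted()
        return self.core_.encode(X)

    def transform(self, X: list[BarcodeTimeline]):
        """Graph chart diagrams (main + subs) for each timeline."""
        from .geometry import diagram_from_timeline

        self._check_fitted()
        return [diagram_from_timeline(self, tl) for tl in X]

    def view_proxy_loss(self) -> float:
        """Current view-proxy loss (sum of squared anchor distances)."""
        self._check_fitted()
        return view_proxy_loss(
            lambda Z: self.core_.encode(Z)["main"], self._registry(), self.kernel_width
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "core_"):
            raise RuntimeError("encoder is not fitted; call fit() first")

    # ---- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize weights (npz) + config (json) next to each other."""
        path = Path(path)
        self._check_fitted()
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p for i, p in enumerate(self.core_.params)}
        np.savez(path.with_suffix(".npz"), **arrays)
        params = self.get_params()
        params.pop("registry")
        cfg = {
            "params": params,
            "registry": {
                "names": list(self._registry().names),
                "groups": self._registry().groups,
                "plane_visibility": {
                    k: sorted(v) for k, v in self._registry().plane_visibility.items()
                },
            },
        }
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GraphChartEncoder":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        reg_cfg = cfg["registry"]
        reg = SubstructureRegistry(
            names=tuple(reg_cfg["names"]),
            groups=dict(reg_cfg["groups"]),
            plane_visibility={
                k: frozenset(v) for k, v in reg_cfg["plane_visibility"].items()
            },
        )
        params = cfg["params"]
        params["hidden_sizes"] = tuple(params["hidden_sizes"])
        est = cls(**params, registry=reg)
        est.core_ = _CascadeCore(
            est.kernel_width, reg, tuple(est.hidden_sizes), est.use_cascade,
            np.random.default_rng(0),
        )
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(est.core_.params):
            p[...] = data[f"p{i}"]
        est.initial_proxy_distances_ = {}
        est.proxy_distances_ = est._ideal_distances()
        est.ideal_latents_ = {
            plane: tuple(est.core_.encode(xp)["main"][0])
            for plane, xp in est._proxy_inputs().items()
        }
        est.loss_history_ = pd.DataFrame()
        return est


# ---- functional wrappers ------------------------------------------------


def train(timelines: list[BarcodeTimeline], **params) -> GraphChartEncoder:
    """Fit a :class:`GraphChartEncoder` on normal timelines."""
    return GraphChartEncoder(**params).fit(timelines)


def encode_slice(encoder: GraphChartEncoder, sl: KernelSlice) -> LatentPoint:
    """Encode one kernel slice to its latent point(s)."""
    if sl.width != encoder.kernel_width:
        raise ValueError(
            f"slice width {sl.width} != encoder kernel width {encoder.kernel_width}"
        )
    z = encoder.encode(sl.flatten()[None, :])
    return LatentPoint(
        main=tuple(z["main"][0]),
        kernel_start=sl.start_frame,
        sub_vessels=tuple(z["sub_vessels"][0]) if "sub_vessels" in z else None,
        sub_heart=tuple(z["sub_heart"][0]) if "sub_heart" in z else None,
    )


def view_proxy_loss(
    encode_fn,
    registry: SubstructureRegistry | None = None,
    width: int = 16,
    targets: dict[str, tuple[float, float]] = PROXY_TARGETS,
) -> float:
    """Sum of squared distances of ideal-plane encodings to their anchors.

    ``encode_fn`` maps a (n, width*18) batch to (n, 2) main latents, so any
    encoder (or stub) can be probed.
    """
    registry = registry or default_registry()
    total = 0.0
    for plane, target in targets.items():
        xp = synthesize_ideal_slice(plane, registry, width).flatten()[None, :]
        z = np.asarray(encode_fn(xp)).reshape(-1)
        total += float(np.sum((z - np.array(target)) ** 2))
    return total


def make_ablation_variant(use_cascade: bool, use_view_proxy: bool):
    """Constructor for one cell of the cascade x proxy ablation grid."""
    import functools

    return functools.partial(
        GraphChartEncoder, use_cascade=use_cascade, use_view_proxy=use_view_proxy
    )
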