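"""Synthetic sweep simulator for barcode-like timelines.

Emulates the screening acquisition the method assumes: the probe sweeps from
the fetal abdomen up through the four-chamber view (4CV) to the three-vessel
trachea view (3VTV).  A latent sweep position in [0, 1] advances with
multiplicative speed noise and occasional backtracking (probe jitter); the
position maps to an acquisition phase, each phase emits its visible channel
set, transitions blend the neighbouring sets, and per-frame detector noise
(dropout / false positives) corrupts the result.

Disease templates are *suppression-only*: an abnormal sweep is the paired
normal sweep with detections of affected channels removed at template
probabilities.  This mirrors the premise the abnormality score exploits —
an abnormal heart makes normal substructure patterns absent; it does not add
new ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registry import (
    ABDOMINAL_VISIBILITY,
    SubstructureRegistry,
    default_registry,
)
from .timeline import BarcodeTimeline

__all__ = [
    "SweepConfig",
    "DiseaseTemplate",
    "SyntheticDataset",
    "generate_normal_sweep",
    "generate_abnormal_sweep",
    "generate_dataset",
    "tof_like_template",
    "hlhs_like_template",
    "default_templates",
]

#: Phase order and default mean dwell-time fractions of the sweep.
DEFAULT_PHASES: tuple[tuple[str, float], ...] = (
    ("abdomen", 0.20),
    ("transition1", 0.15),
    ("four_cv", 0.25),
    ("transition2", 0.15),
    ("three_vtv", 0.25),
)


@dataclass
class SweepConfig:
    """Parameters of one simulated sweep.

    ``dropout_prob`` / ``false_pos_prob`` model per-frame per-channel
    detector errors; ``jitter_prob`` is the per-step probability that the
    probe moves backwards; ``speed_sigma`` is the standard deviation of the
    multiplicative step-size noise.
    """

    n_frames: int = 200
    phase_fractions: tuple[tuple[str, float], ...] = DEFAULT_PHASES
    dropout_prob: float = 0.10
    false_pos_prob: float = 0.02
    jitter_prob: float = 0.10
    speed_sigma: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 20:
            raise ValueError("n_frames must be >= 20")
        for p in (self.dropout_prob, self.false_pos_prob, self.jitter_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.speed_sigma < 0:
            raise ValueError("speed_sigma must be >= 0")
        fracs = [f for _, f in self.phase_fractions]
        if any(f <= 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("phase fractions must be positive and sum to 1")


@dataclass
class DiseaseTemplate:
    """Channel-suppression profile of a congenital-heart-disease-like case.

    ``suppression`` maps channel name to the probability that each detection
    of that channel is removed; ``phases`` optionally restricts suppression
    to frames acquired in the named phases.
    """

    name: str
    suppression: dict[str, float]
    phases: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.suppression:
            raise ValueError("template must suppress at least one channel")
        for ch, p in self.suppression.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"suppression prob for {ch!r} outside [0, 1]")
        if all(p == 0 for p in self.suppression.values()):
            # An all-zero template is allowed structurally (identity case in
            # tests) but flagged: it does not describe a disease.
            pass


def tof_like_template() -> DiseaseTemplate:
    """Tetralogy-of-Fallot-like profile: great-vessel detections vanish."""
    return DiseaseTemplate(
        name="TOF-like",
        suppression={
            "pulmonary artery": 1.0,
            "ascending aorta": 0.7,
            "ductus arteriosus": 0.8,
        },
    )


def hlhs_like_template() -> DiseaseTemplate:
    """Hypoplastic-left-heart-like profile: left-sided structures vanish."""
    return DiseaseTemplate(
        name="HLHS-like",
        suppression={
            "left ventricle": 1.0,
            "mitral valve": 1.0,
            "ascending aorta": 0.8,
        },
    )


def default_templates() -> list[DiseaseTemplate]:
    return [tof_like_template(), hlhs_like_template()]


def _sweep_positions(cfg: SweepConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent probe position per frame: monotone on average, with jitter."""
    pos = np.empty(cfg.n_frames)
    p = 0.0
    base = 1.0 / cfg.n_frames
    for t in range(cfg.n_frames):
        step = base * abs(rng.normal(1.0, cfg.speed_sigma))
        if rng.random() < cfg.jitter_prob:
            step = -step
        p = min(max(p + step, 0.0), 1.0)
        pos[t] = p
    peak = pos.max()
    if peak > 0:  # rescale so the sweep spans the full anatomical range
        pos /= peak
    return pos


def _phase_edges(cfg: SweepConfig) -> list[tuple[str, float, float]]:
    edges, lo = [], 0.0
    for name, frac in cfg.phase_fractions:
        edges.append((name, lo, lo + frac))
        lo += frac
    edges[-1] = (edges[-1][0], edges[-1][1], 1.0 + 1e-12)
    return edges


def _phase_sets(registry: SubstructureRegistry) -> dict[str, frozenset[str]]:
    return {
        "abdomen": frozenset(ABDOMINAL_VISIBILITY),
        "four_cv": registry.plane_visibility["FOUR_CV"],
        "three_vtv": registry.plane_visibility["THREE_VTV"],
    }


def _emission_probs(
    position: float,
    edges: list[tuple[str, float, float]],
    sets: dict[str, frozenset[str]],
    registry: SubstructureRegistry,
) -> np.ndarray:
    """Per-channel activation probability at a sweep position.

    Pure phases emit their visibility set deterministically; within a
    transition each fading channel's probability ramps linearly from the
    previous phase's set to the next one's.
    """
    probs = np.zeros(registry.n_channels)
    for i, (name, lo, hi) in enumerate(edges):
        if lo <= position < hi or (i == len(edges) - 1 and position >= lo):
            if name in sets:
                for ch in sets[name]:
                    probs[registry.index(ch)] = 1.0
            else:  # transition between the neighbouring pure phases
                alpha = (position - lo) / (hi - lo)
                prev_set = sets[edges[i - 1][0]]
                next_set = sets[edges[i + 1][0]]
                for ch in prev_set | next_set:
                    j = registry.index(ch)
                    if ch in prev_set and ch in next_set:
                        probs[j] = 1.0
                    elif ch in prev_set:
                        probs[j] = 1.0 - alpha
                    else:
                        probs[j] = alpha
            return probs
    raise AssertionError("position outside [0, 1]")


def _phase_of(position: float, edges: list[tuple[str, float, float]]) -> str:
    for name, lo, hi in edges:
        if lo <= position < hi:
            return name
    return edges[-1][0]


def generate_normal_sweep(
    cfg: SweepConfig, registry: SubstructureRegistry | None = None, **meta
) -> BarcodeTimeline:
    """Simulate one normal screening sweep; deterministic given ``cfg.seed``."""
    registry = registry or default_registry()
    rng = np.random.default_rng(cfg.seed)
    edges = _phase_edges(cfg)
    sets = _phase_sets(registry)
    positions = _sweep_positions(cfg, rng)

    mat = np.zeros((cfg.n_frames, registry.n_channels), dtype=np.uint8)
    for t, p in enumerate(positions):
        probs = _emission_probs(p, edges, sets, registry)
        mat[t] = rng.random(registry.n_channels) < probs
    if cfg.dropout_prob > 0:
        mat[(mat == 1) & (rng.random(mat.shape) < cfg.dropout_prob)] = 0
    if cfg.false_pos_prob > 0:
        mat[(mat == 0) & (rng.random(mat.shape) < cfg.false_pos_prob)] = 1

    tl = BarcodeTimeline(
        frames=mat,
        video_id=meta.get("video_id", f"sim-{cfg.seed}"),
        case_id=meta.get("case_id", f"case-{cfg.seed}"),
        label="normal",
        registry=registry,
    )
    tl.sweep_positions = positions  # kept for phase-aware suppression
    return tl


def generate_abnormal_sweep(
    cfg: SweepConfig,
    template: DiseaseTemplate,
    registry: SubstructureRegistry | None = None,
    **meta,
) -> BarcodeTimeline:
    """Simulate a disease-perturbed sweep: paired normal sweep, then
    suppression-only removal of affected channels."""
    registry = registry or default_registry()
    normal = generate_normal_sweep(cfg, registry, **meta)
    edges = _phase_edges(cfg)
    sup_rng = np.random.default_rng((int(cfg.seed), 0x5D15EA5E))

    mat = normal.frames.copy()
    if template.phases is not None:
        phase_mask = np.array(
            [_phase_of(p, edges) in template.phases for p in normal.sweep_positions]
        )
    else:
        phase_mask = np.ones(cfg.n_frames, dtype=bool)
    for ch, prob in template.suppression.items():
        j = registry.index(ch)
        hit = phase_mask & (mat[:, j] == 1) & (sup_rng.random(cfg.n_frames) < prob)
        mat[hit, j] = 0

    return BarcodeTimeline(
        frames=mat,
        video_id=meta.get("video_id", f"sim-{cfg.seed}-{template.name}"),
        case_id=meta.get("case_id", f"case-{cfg.seed}"),
        label="abnormal",
        disease_tag=template.name,
        registry=registry,
    )


@dataclass
class SyntheticDataset:
    """Train (normal-only) and test (mixed) timeline collections."""

    train: list[BarcodeTimeline]
    test: list[BarcodeTimeline]
    base_seed: int = 0
    manifest: dict = field(default_factory=dict)

    def save(self, out_dir) -> None:
        """Write all timelines (CSV + sidecar) and a JSON manifest."""
        import json
        from pathlib import Path

        from .timeline import save_timeline

        out = Path(out_dir)
        for split, tls in (("train", self.train), ("test", self.test)):
            for tl in tls:
                save_timeline(tl, out / split / f"{tl.video_id}.csv")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True), encoding="utf-8"
        )


def _video_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % 2**31)


def generate_dataset(
    n_train_normal: int = 60,
    n_test_normal: int = 20,
    n_test_abnormal: int = 20,
    templates: list[DiseaseTemplate] | None = None,
    base_seed: int = 0,
    cfg: SweepConfig | None = None,
    registry: SubstructureRegistry | None = None,
    videos_per_case: int = 2,
) -> SyntheticDataset:
    """Generate the screening benchmark: normal-only training videos plus a
    mixed test set, with disjoint case identifiers across splits.

    Videos are grouped ``videos_per_case`` per synthetic case (default two
    sweeps of the same fetus); abnormal cases cycle through ``templates``.
    Per-video seeds derive reproducibly from ``base_seed``.
    """
    if min(n_train_normal, n_test_normal, n_test_abnormal) < 1:
        raise ValueError("all split sizes must be >= 1")
    registry = registry or default_registry()
    cfg = cfg or SweepConfig()
    templates = templates if templates is not None else default_templates()

    train: list[BarcodeTimeline] = []
    test: list[BarcodeTimeline] = []
    counter = 0

    def make_cfg(seed: int) -> SweepConfig:
        from dataclasses import replace

        return replace(cfg, seed=seed)

    for i in range(n_train_normal):
        seed = _video_seed(base_seed, counter)
        counter += 1
        train.append(
            generate_normal_sweep(
                make_cfg(seed),
                registry,
                video_id=f"train_v{i:03d}",
                case_id=f"train_c{i // videos_per_case:03d}",
            )
        )
    for i in range(n_test_normal):
        seed = _video_seed(base_seed, counter)
        counter += 1
        test.append(
            generate_normal_sweep(
                make_cfg(seed),
                registry,
                video_id=f"testn_v{i:03d}",
                case_id=f"testn_c{i // videos_per_case:03d}",
            )
        )
    for i in range(n_test_abnormal):
        seed = _video_seed(base_seed, counter)
        counter += 1
        case = i // videos_per_case
        template = templates[case % len(templates)]
        test.append(
            generate_abnormal_sweep(
                make_cfg(seed),
                template,
                registry,
                video_id=f"testa_v{i:03d}",
                case_id=f"testa_c{case:03d}",
            )
        )

    manifest = {
        "base_seed": base_seed,
        "n_train_normal": n_train_normal,
        "n_test_normal": n_test_normal,
        "n_test_abnormal": n_test_abnormal,
        "sweep_config": {
            "n_frames": cfg.n_frames,
            "dropout_prob": cfg.dropout_prob,
            "false_pos_prob": cfg.false_pos_prob,
            "jitter_prob": cfg.jitter_prob,
            "speed_sigma": cfg.speed_sigma,
        },
        "templates": [
            {"name": t.name, "suppression": t.suppression} for t in templates
        ],
        "videos": {
            "train": [tl.video_id for tl in train],
            "test": [
                {"video_id": tl.video_id, "case_id": tl.case_id, "label": tl.label}
                for tl in test
            ],
        },
    }
    return SyntheticDataset(train=train, test=test, base_seed=base_seed, manifest=manifest)
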