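"""Cascade encoder: determinism, ablation contracts, proxy loss, training."""

import numpy as np
import pytest

from graphchart import (
    GraphChartEncoder,
    SweepConfig,
    encode_slice,
    generate_dataset,
    generate_normal_sweep,
    make_ablation_variant,
    slice_kernels,
    view_proxy_loss,
)
from graphchart.model import PROXY_TARGETS


class TestEncodeSlice:
    def test_same_weights_same_slice_identical_points(self, tiny_encoder, tiny_dataset):
        sl = slice_kernels(tiny_dataset.test[0], 8, 1)[0]
        a = encode_slice(tiny_encoder, sl)
        b = encode_slice(tiny_encoder, sl)
        assert a == b
        assert a.sub_vessels is not None and a.sub_heart is not None

    def test_distinct_inputs_map_to_distinct_points(self, tiny_encoder):
        zeros = np.zeros((1, 8 * 18))
        ones = np.ones((1, 8 * 18))
        za = tiny_encoder.encode(zeros)["main"]
        zb = tiny_encoder.encode(ones)["main"]
        assert np.linalg.norm(za - zb) > 1e-6

    def test_width_mismatch_raises(self, tiny_encoder, tiny_dataset):
        sl = slice_kernels(tiny_dataset.test[0], 12, 1)[0]
        with pytest.raises(ValueError, match="width"):
            encode_slice(tiny_encoder, sl)

    def test_simple_ablation_has_no_sub_points(self, tiny_dataset):
        enc = GraphChartEncoder(
            kernel_width=8, use_cascade=False, epochs=2, random_state=0
        ).fit(tiny_dataset.train)
        sl = slice_kernels(tiny_dataset.test[0], 8, 1)[0]
        pt = encode_slice(enc, sl)
        assert pt.sub_vessels is None and pt.sub_heart is None
        assert enc.n_features_in_ == 8 * 18


class TestViewProxyLoss:
    def test_exact_hit_gives_zero(self, registry):
        def stub(X):
            # maps ideal 4CV -> (0,1) and ideal 3VTV -> (1,0) by channel sums
            heart = sum(X[0, i::18] for i in registry.group_indices("heart")).sum()
            return np.array([[0.0, 1.0] if heart > 0 else [1.0, 0.0]])

        assert view_proxy_loss(stub, registry, width=4) == pytest.approx(0.0)

    def test_origin_encoder_gives_two(self, registry):
        loss = view_proxy_loss(lambda X: np.zeros((1, 2)), registry, width=4)
        assert loss == pytest.approx(2.0)  # 1 + 1 under squared Euclidean

    def test_loss_mostly_decreases_during_training(self, tiny_dataset):
        """Training pulls ideal-plane encodings toward their anchors."""
        enc = GraphChartEncoder(
            kernel_width=8, epochs=20, random_state=1, train_stride=4
        ).fit(tiny_dataset.train)
        proxy = enc.loss_history_["proxy"].to_numpy()
        drops = (np.diff(proxy) < 0).mean()
        assert drops >= 0.6
        assert proxy[-1] < proxy[0]


class TestTraining:
    def test_one_class_contract_rejects_abnormal(self, tiny_dataset):
        mixed = tiny_dataset.train + [tl for tl in tiny_dataset.test if tl.label == "abnormal"][:1]
        with pytest.raises(ValueError, match="one-class"):
            GraphChartEncoder(kernel_width=8, epochs=1).fit(mixed)

    def test_reconstruction_loss_drops_on_repeated_timeline(self, registry):
        tl = generate_normal_sweep(SweepConfig(n_frames=60, seed=0), registry)
        enc = GraphChartEncoder(
            kernel_width=8, epochs=300, train_stride=2, batch_size=16,
            learning_rate=3e-3, random_state=0,
        ).fit([tl] * 4)
        recon = enc.loss_history_["recon"].to_numpy()
        assert recon[-1] < 0.1 * recon[0]

    def test_proxy_training_moves_ideal_3vtv_toward_anchor(self, tiny_dataset):
        enc = GraphChartEncoder(
            kernel_width=8, epochs=15, random_state=2, train_stride=4
        ).fit(tiny_dataset.train)
        assert (
            enc.proxy_distances_["THREE_VTV"]
            < enc.initial_proxy_distances_["THREE_VTV"]
        )
        assert enc.proxy_distances_["FOUR_CV"] < enc.initial_proxy_distances_["FOUR_CV"]

    def test_same_seed_identical_weights(self, tiny_dataset):
        def weights_hash(enc):
            import hashlib

            h = hashlib.sha256()
            for p in enc.core_.params:
                h.update(p.tobytes())
            return h.hexdigest()

        a = GraphChartEncoder(kernel_width=8, epochs=3, random_state=5).fit(
            tiny_dataset.train
        )
        b = GraphChartEncoder(kernel_width=8, epochs=3, random_state=5).fit(
            tiny_dataset.train
        )
        assert weights_hash(a) == weights_hash(b)

    def test_outputs_finite_on_all_binary_corners(self, tiny_encoder):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, (50, 8 * 18)).astype(float)
        for z in tiny_encoder.encode(X).values():
            assert np.isfinite(z).all()

    def test_stagewise_mode_trains(self, tiny_dataset):
        enc = GraphChartEncoder(
            kernel_width=8, epochs=6, training_mode="stagewise", random_state=0
        ).fit(tiny_dataset.train)
        assert set(enc.loss_history_["stage"]) == {"sub", "main"}
        assert np.isfinite(enc.loss_history_["total"]).all()

    def test_checkpoint_round_trip(self, tiny_encoder, tiny_dataset, tmp_path):
        tiny_encoder.save(tmp_path / "ckpt")
        back = GraphChartEncoder.load(tmp_path / "ckpt")
        X = np.zeros((3, 8 * 18))
        np.testing.assert_allclose(
            back.encode(X)["main"], tiny_encoder.encode(X)["main"]
        )
        assert back.kernel_width == tiny_encoder.kernel_width


class TestAblationVariants:
    @pytest.mark.parametrize(
        "cascade,proxy", [(False, False), (True, True), (False, True), (True, False)]
    )
    def test_variant_constructor_sets_flags(self, cascade, proxy):
        enc = make_ablation_variant(cascade, proxy)(kernel_width=8, epochs=1)
        assert enc.use_cascade is cascade
        assert enc.use_view_proxy is proxy

    def test_bottlenecks_are_two_dimensional(self, tiny_encoder):
        core = tiny_encoder.core_
        assert core.enc_v.sizes[-1] == 2
        assert core.enc_h.sizes[-1] == 2
        assert core.enc_m.sizes[-1] == 2
        assert core.dec_m.sizes[0] == 2

    def test_proxy_anchors_are_axis_units(self):
        assert PROXY_TARGETS["FOUR_CV"] == (0.0, 1.0)
        assert PROXY_TARGETS["THREE_VTV"] == (1.0, 0.0)


class TestProxyStabilisation:
    def test_proxy_loss_reduces_anchor_dispersion_across_seeds(self):
        """Across random inits, ideal-plane encodings cluster only with the
        proxy loss active (the latent-geometry form of the stabilisation
        effect)."""
        ds = generate_dataset(6, 2, 2, base_seed=21, cfg=SweepConfig(n_frames=60))

        def dispersion(use_proxy):
            pts = []
            for seed in range(3):
                enc = GraphChartEncoder(
                    kernel_width=8, epochs=12, train_stride=4,
                    use_view_proxy=use_proxy, random_state=seed,
                ).fit(ds.train)
                pts.append(enc.ideal_latents_["THREE_VTV"])
            pts = np.array(pts)
            return np.mean(
                [np.linalg.norm(a - b) for i, a in enumerate(pts) for b in pts[i + 1:]]
            )

        assert dispersion(True) < dispersion(False)
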