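import numpy as np
import pytest

from lmbisnet import nn
from lmbisnet.network import (PARAMETER_BUDGET, ChannelPlan, LMBiSNet,
                              MultipathBlock, MultipathBlockSpec,
                              build_ablation_variant, build_network,
                              count_parameters, multipath_block_forward)
from lmbisnet.types import ValidationError


@pytest.fixture(scope="module")
def full_graph():
    return build_network(seed=0)


class TestStructure:
    def test_two_maxpool_layers(self, full_graph):
        assert full_graph.count_maxpool() == 2

    def test_three_encoder_and_three_decoder_blocks(self, full_graph):
        assert full_graph.count_encoder_blocks() == 3
        assert full_graph.count_decoder_blocks() == 3

    def test_two_stride2_upsampling_nodes(self, full_graph):
        assert sum(1 for l in full_graph.layers if l.kind == "tconv") == 2

    def test_graph_is_acyclic_including_reverse_skips(self, full_graph):
        assert any(s.direction == "reverse" for s in full_graph.skips)
        assert full_graph.is_acyclic()

    def test_softmax_head_emits_num_classes(self, full_graph):
        head = [l for l in full_graph.layers if l.name == "head"][0]
        assert head.out_channels == 2
        assert full_graph.layers[-1].kind == "softmax"


class TestParameterCounting:
    def test_budget_respected_and_accounting_agrees(self, full_graph):
        total = count_parameters(full_graph)
        assert total <= PARAMETER_BUDGET
        assert total == full_graph.model.num_parameters()

    def test_closed_form_examples(self, full_graph):
        table = {l.name: l.param_count for l in full_graph.layers}
        # stem: 3x3 conv 3->8 with bias
        assert table["stem"] == 9 * 3 * 8 + 8
        # encoder batch-norm: 2 per channel
        assert table["enc1.bn"] == 2 * 8

    def test_budget_violation_raises_with_table(self):
        wide = ChannelPlan(stem_channels=64, encoder_channels=(64, 128, 256),
                           multipath_channels=256, bottleneck_channels=256,
                           decoder_channels=(256, 128, 64))
        with pytest.raises(ValidationError, match="parameter budget"):
            build_network(wide)

    def test_parameter_table_csv_sums_to_total(self, full_graph):
        df = full_graph.parameter_table()
        assert df["params"].sum() == count_parameters(full_graph)


class TestMultipathBlock:
    def test_kernel_set_follows_n_eq_2k_minus_1(self):
        spec = MultipathBlockSpec(in_channels=4, out_channels=4)
        assert tuple(spec.kernel_sizes) == (1, 3, 5)
        with pytest.raises(ValidationError):
            MultipathBlockSpec(in_channels=4, out_channels=4, kernel_sizes=(1, 3, 7))

    def test_output_equals_explicit_path_sum(self, rng):
        block = MultipathBlock(MultipathBlockSpec(3, 5), np.random.default_rng(1),
                               dtype=np.float64)
        x = rng.random((1, 3, 6, 6))
        out = multipath_block_forward(x, block)
        s1 = sum(p.forward(x) for p in block.stage1.paths)
        expected = sum(p.forward(s1) for p in block.stage2.paths)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_zero_weights_propagate_zero(self, rng):
        block = MultipathBlock(MultipathBlockSpec(2, 3), np.random.default_rng(2),
                               dtype=np.float64)
        for p in block.parameters():
            if p.name != "bn.gamma":
                p.value[...] = 0.0
        out = multipath_block_forward(rng.random((1, 2, 4, 4)), block)
        np.testing.assert_allclose(out, 0.0)

    def test_spatial_size_preserved(self, rng):
        block = MultipathBlock(MultipathBlockSpec(2, 7), np.random.default_rng(3))
        out = multipath_block_forward(rng.random((2, 2, 9, 11)).astype(np.float32), block)
        assert out.shape == (2, 7, 9, 11)

    def test_one_by_one_path_only_is_affine_per_pixel(self):
        """With the 3x3/5x5 paths zeroed, the block's first stage reduces to
        a per-pixel affine map computable by hand."""
        rng = np.random.default_rng(4)
        block = MultipathBlock(MultipathBlockSpec(2, 2), rng, dtype=np.float64)
        stage = block.stage1
        for p in stage.paths[1:]:
            for par in p.parameters():
                if par.name != "bn.gamma":
                    par.value[...] = 0.0
        x = rng.random((1, 2, 3, 3))
        out = stage.forward(x)
        p0 = stage.paths[0]
        w = p0.conv.weight.value[:, :, 0, 0]     # (out, in)
        b = p0.conv.bias.value
        pre = np.einsum("oc,nchw->nohw", w, x) + b[None, :, None, None]
        act = np.maximum(pre, 0)
        inv = 1 / np.sqrt(p0.bn.running_var + p0.bn.eps)
        expected = (p0.bn.gamma.value * inv)[None, :, None, None] * act \
            + (p0.bn.beta.value - p0.bn.gamma.value * p0.bn.running_mean * inv)[None, :, None, None]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        block = MultipathBlock(MultipathBlockSpec(3, 3), np.random.default_rng(0))
        with pytest.raises(ValidationError):
            block.forward(rng.random((1, 4, 4, 4)).astype(np.float32))


class TestForward:
    def test_output_shape_matches_input(self, full_graph, rng):
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        p = full_graph.model.forward(x)
        assert p.shape == (1, 2, 64, 64)

    def test_probabilities_sum_to_one(self, full_graph, rng):
        x = rng.random((2, 3, 32, 32)).astype(np.float32)
        p = full_graph.model.forward(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)
        assert (p >= 0).all()

    def test_deterministic_given_weights(self, rng):
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        a = build_network(seed=5).model.forward(x)
        b = build_network(seed=5).model.forward(x)
        assert np.array_equal(a, b)

    def test_zero_weight_network_is_uniform(self, rng):
        g = build_network(seed=0)
        for p in g.model.parameters():
            if p.name != "bn.gamma":
                p.value[...] = 0.0
        out = g.model.forward(rng.random((1, 3, 16, 16)).astype(np.float32))
        np.testing.assert_allclose(out, 0.5, atol=1e-6)

    def test_indivisible_side_rejected(self, full_graph, rng):
        with pytest.raises(ValidationError):
            full_graph.model.forward(rng.random((1, 3, 30, 30)).astype(np.float32))


class TestReverseSkip:
    def test_zero_projection_leaves_encoder_features_unchanged(self, rng):
        """With the reverse-skip projection zeroed the full model computes
        exactly what the no-reverse-skip variant computes."""
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        full = build_network(seed=3)
        ablated = build_ablation_variant("lbl_mfeb", seed=3)
        proj_params = {id(full.model.rev_proj.weight), id(full.model.rev_proj.bias)}
        shared = [p for p in full.model.parameters() if id(p) not in proj_params]
        for src, dst in zip(shared, ablated.model.parameters()):
            dst.value[...] = src.value
        full.model.rev_proj.weight.value[...] = 0.0
        full.model.rev_proj.bias.value[...] = 0.0
        np.testing.assert_allclose(full.model.forward(x), ablated.model.forward(x),
                                   atol=1e-6)

    def test_refinement_adds_projected_decoder_features(self):
        """Identity 1x1 projection on matched 1-channel features: the refined
        encoder map equals encoder + decoder features (upsampled across the
        2x scale gap) and takes the encoder stage's shape."""
        from lmbisnet.network import remap_reverse_skip

        rng = np.random.default_rng(0)
        proj = nn.Conv2d(1, 1, 1, rng, dtype=np.float64)
        proj.weight.value[...] = 1.0
        proj.bias.value[...] = 0.0
        enc = rng.random((1, 1, 4, 4))
        dec = rng.random((1, 1, 2, 2))
        refined = remap_reverse_skip(dec, enc, proj)
        np.testing.assert_allclose(refined, enc + dec.repeat(2, 2).repeat(2, 3))
        assert refined.shape == enc.shape
        # matched shapes need no resize
        same = remap_reverse_skip(enc, enc, proj)
        np.testing.assert_allclose(same, 2 * enc)
        # zero projection is the additive identity
        proj.weight.value[...] = 0.0
        np.testing.assert_allclose(remap_reverse_skip(dec, enc, proj), enc)

    def test_incompatible_stage_shapes_rejected(self):
        from lmbisnet.network import remap_reverse_skip
        from lmbisnet.types import ValidationError

        rng = np.random.default_rng(1)
        proj = nn.Conv2d(1, 1, 1, rng, dtype=np.float64)
        with pytest.raises(ValidationError):
            remap_reverse_skip(rng.random((1, 1, 2, 2)), rng.random((1, 1, 8, 8)), proj)


class TestAblations:
    def test_parameter_ordering(self):
        counts = {v: count_parameters(build_ablation_variant(v))
                  for v in ("lightweight_baseline", "lbl_mfeb", "full")}
        assert counts["lightweight_baseline"] < counts["lbl_mfeb"] < counts["full"]

    def test_full_matches_default_build(self, full_graph):
        v = build_ablation_variant("full")
        assert count_parameters(v) == count_parameters(full_graph)
        assert [l.name for l in v.layers] == [l.name for l in full_graph.layers]

    def test_multipath_presence(self):
        lbl = build_ablation_variant("lightweight_baseline")
        mfeb = build_ablation_variant("lbl_mfeb")
        assert not any("multipath" in l.name for l in lbl.layers)
        assert any("multipath" in l.name for l in mfeb.layers)

    def test_unet_baseline_is_heaviest(self):
        assert count_parameters(build_ablation_variant("baseline_unet")) \
            > count_parameters(build_ablation_variant("full"))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValidationError):
            build_ablation_variant("resnet")
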