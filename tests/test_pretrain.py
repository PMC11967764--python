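"""Self-supervised objectives and the joint training loop."""

import importlib

import numpy as np
import pytest

import molssl as M
from molssl import autodiff as ad

# the package root re-exports pretrain() the function, so fetch the module
pt = importlib.import_module("molssl.pretrain")


def _zeroed_heads(latent_dim, granularities):
    heads = M.StructuralClassifier.init(latent_dim, granularities, seed=0)
    for p in heads.params.values():
        p.data[:] = 0.0
    return heads


def test_mlct_uniform_logits_closed_form():
    """Zero heads give uniform class probabilities, so the loss is the sum
    of ln K over the granularities."""
    heads = _zeroed_heads(8, (100, 1000, 10000))
    latents = ad.constant(np.random.default_rng(0).normal(size=(5, 8)))
    labels = np.zeros((5, 3), dtype=int)
    loss, per_head = M.mlct_loss(heads, latents, labels)
    expected = np.log(100) + np.log(1000) + np.log(10000)
    assert float(loss.data) == pytest.approx(expected, abs=1e-4)
    assert per_head == pytest.approx((np.log(100), np.log(1000), np.log(10000)),
                                     abs=1e-6)


def test_mlct_point_mass_loss_vanishes():
    heads = _zeroed_heads(4, (3, 5))
    heads.params["head_0_b"].data[2] = 50.0  # probability ~1 on class 2
    heads.params["head_1_b"].data[0] = 50.0
    latents = ad.constant(np.zeros((4, 4)))
    labels = np.tile([2, 0], (4, 1))
    loss, _ = M.mlct_loss(heads, latents, labels)
    assert float(loss.data) < 1e-6


def test_mlct_mean_reduction_over_copies():
    rng = np.random.default_rng(1)
    heads = M.StructuralClassifier.init(6, (4,), seed=1)
    one = rng.normal(size=(1, 6))
    l1, _ = M.mlct_loss(heads, ad.constant(one), np.array([[2]]))
    ln, _ = M.mlct_loss(heads, ad.constant(np.repeat(one, 7, axis=0)),
                        np.tile([2], (7, 1)))
    assert float(l1.data) == pytest.approx(float(ln.data), rel=1e-12)


def test_mlct_label_out_of_range():
    heads = _zeroed_heads(4, (3,))
    with pytest.raises(ValueError):
        M.mlct_loss(heads, ad.constant(np.zeros((2, 4))), np.array([[3], [0]]))


def test_mcl_hand_cases():
    z = np.zeros((2, 4))
    assert float(M.mcl_loss(ad.constant(z), ad.constant(z)).data) == 0.0
    e = np.zeros((1, 4)); e[0, 0] = 1.0
    assert float(M.mcl_loss(ad.constant(np.zeros((1, 4))),
                            ad.constant(e)).data) == pytest.approx(1.0)
    a = np.array([[0.0, 0.0], [0.0, 0.0]])
    b = np.array([[3.0, 0.0], [0.0, 4.0]])  # distances 3 and 4
    assert float(M.mcl_loss(ad.constant(a), ad.constant(b)).data) == \
        pytest.approx(3.5)
    assert float(M.mcl_loss(ad.constant(a), ad.constant(b),
                            squared=True).data) == pytest.approx(12.5)


def test_mcl_shape_mismatch():
    with pytest.raises(ValueError):
        M.mcl_loss(ad.constant(np.zeros((2, 3))), ad.constant(np.zeros((3, 3))))


def test_total_loss_modes():
    assert M.total_loss(2.0, 3.0, "full") == 5.0
    assert M.total_loss(2.0, 3.0, "mlct_only") == 2.0
    assert M.total_loss(2.0, 3.0, "mcl_only") == 3.0
    assert M.total_loss(0.0, 0.0, "full") == 0.0
    with pytest.raises(FloatingPointError):
        M.total_loss(float("nan"), 1.0, "full")


@pytest.fixture(scope="module")
def tiny_run(small_corpus, small_fingerprints, tiny_encoder_config):
    corpus, _ = small_corpus
    cfg = M.PretrainConfig(epochs=15, batch_size=32, granularities=(3, 5),
                           mask_ratio=0.25, encoder=tiny_encoder_config, seed=4)
    return M.pretrain(list(corpus), cfg, fingerprints=small_fingerprints)


def test_mode_none_returns_untouched_encoder(small_corpus, tiny_encoder_config):
    corpus, _ = small_corpus
    cfg = M.PretrainConfig(epochs=5, granularities=(3,), mode="none",
                           encoder=tiny_encoder_config)
    result = M.pretrain(list(corpus), cfg)
    assert result.log == []
    fresh = M.init_encoder(tiny_encoder_config)
    for k in fresh.params:
        np.testing.assert_array_equal(result.encoder.params[k].data,
                                      fresh.params[k].data)


def test_loss_decreases_and_reports_consistent(tiny_run):
    log = tiny_run.log
    assert len(log) == 15
    assert log[-1].l_all < log[0].l_all
    for entry in log:
        assert entry.l_mlct >= 0 and entry.l_mcl >= 0
        assert entry.l_all == pytest.approx(entry.l_mlct + entry.l_mcl,
                                            abs=1e-6)
        assert entry.l_mlct == pytest.approx(sum(entry.per_head_ce), abs=1e-6)


def test_pretrain_deterministic(small_corpus, small_fingerprints,
                                tiny_encoder_config):
    corpus, _ = small_corpus
    cfg = M.PretrainConfig(epochs=2, batch_size=32, granularities=(3,),
                           encoder=tiny_encoder_config, seed=8)
    r1 = M.pretrain(list(corpus), cfg, fingerprints=small_fingerprints)
    r2 = M.pretrain(list(corpus), cfg, fingerprints=small_fingerprints)
    assert [e.l_all for e in r1.log] == [e.l_all for e in r2.log]
    for k in r1.encoder.params:
        np.testing.assert_array_equal(r1.encoder.params[k].data,
                                      r2.encoder.params[k].data)


def test_mlct_only_never_masks(small_corpus, small_fingerprints,
                               tiny_encoder_config, monkeypatch):
    corpus, _ = small_corpus
    calls = {"mask": 0}
    orig = pt.mask_graph

    def counting_mask(*args, **kwargs):
        calls["mask"] += 1
        return orig(*args, **kwargs)

    monkeypatch.setattr(pt, "mask_graph", counting_mask)
    cfg = M.PretrainConfig(epochs=1, batch_size=64, granularities=(3,),
                           mode="mlct_only", encoder=tiny_encoder_config)
    result = M.pretrain(list(corpus), cfg, fingerprints=small_fingerprints)
    assert calls["mask"] == 0
    assert all(e.l_mcl == 0.0 for e in result.log)


def test_mcl_only_has_no_classifier(small_corpus, small_fingerprints,
                                    tiny_encoder_config):
    corpus, _ = small_corpus
    cfg = M.PretrainConfig(epochs=1, batch_size=64, granularities=(3,),
                           mode="mcl_only", encoder=tiny_encoder_config)
    result = M.pretrain(list(corpus), cfg, fingerprints=small_fingerprints)
    assert result.heads is None
    assert all(e.l_mlct == 0.0 for e in result.log)


def test_coarse_head_learns_above_chance(tiny_run):
    """On the structured corpus the coarsest head clearly beats its 1/K
    chance rate even after a short run (the full-margin desk-scale check
    lives in the acceptance suite)."""
    acc = tiny_run.head_accuracy[0]
    assert acc > 1.2 * (1.0 / 3.0)  # K=3

def test_mcl_distance_shrinks(tiny_run):
    assert tiny_run.log[-1].l_mcl < tiny_run.log[0].l_mcl


def test_training_log_file(tmp_path, small_corpus, small_fingerprints,
                           tiny_encoder_config):
    corpus, _ = small_corpus
    cfg = M.PretrainConfig(epochs=2, batch_size=64, granularities=(3,),
                           encoder=tiny_encoder_config, seed=1)
    log_path = str(tmp_path / "log.csv")
    M.pretrain(list(corpus), cfg, fingerprints=small_fingerprints,
               log_path=log_path)
    lines = open(log_path).read().strip().splitlines()
    assert lines[0].startswith("epoch,l_mlct,l_mcl,l_all")
    assert len(lines) == 3
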