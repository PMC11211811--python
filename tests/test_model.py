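"""Architectural invariants of the perturbation-response network: attention
normalization, indicator masking, NA-bias behaviour, decoder locality, and
oracle checks of each encoder against step-by-step hand compositions."""

import numpy as np
import pytest

import pertattn as pa
from pertattn.model import _BN_EPS

RNG = np.random.default_rng(42)


@pytest.fixture()
def cond2():
    return pa.Condition([3, 11])


class TestInit:
    def test_same_seed_bit_identical(self, small_model_config):
        a = pa.init_model(small_model_config, seed=5)
        b = pa.init_model(small_model_config, seed=5)
        for key, arr in a.state_dict().items():
            assert np.array_equal(arr, b.state_dict()[key]), key

    def test_embeddings_initialize_all_three_gene_embeddings(
            self, small_model_config):
        genes = pa.GeneIndex([f"G{i}" for i in range(20)])
        table = pa.EmbeddingTable(genes, RNG.normal(size=(20, 16)))
        m = pa.init_model(small_model_config, table, seed=0)
        for emb in (m.e_w, m.e_p, m.e_g):
            assert np.array_equal(emb.data, table.matrix)

    def test_random_init_rows_differ_across_embeddings(self, small_model):
        assert not np.array_equal(small_model.e_w.data, small_model.e_p.data)
        assert not np.array_equal(small_model.e_w.data, small_model.e_g.data)

    def test_width_mismatch_rejected(self, small_model_config):
        genes = pa.GeneIndex([f"G{i}" for i in range(20)])
        table = pa.EmbeddingTable(genes, RNG.normal(size=(20, 7)))
        with pytest.raises(ValueError):
            pa.init_model(small_model_config, table)


class TestPertWeight:
    def test_attention_rows_sum_to_one(self, small_model, small_props, cond2):
        _, parts = pa.pertweight_forward(cond2, small_model, small_props[0],
                                         return_parts=True)
        sums = parts["attention"].sum(axis=-1)
        assert sums == pytest.approx(np.ones_like(sums), abs=1e-6)

    def test_masked_value_rows_zero_outside_condition(self, small_model,
                                                      small_props, cond2):
        _, parts = pa.pertweight_forward(cond2, small_model, small_props[0],
                                         return_parts=True)
        v = parts["v_masked"]  # (H, K, d_v)
        nonzero_rows = np.any(v != 0, axis=(0, 2))
        assert set(np.nonzero(nonzero_rows)[0]) == set(cond2.genes)
        assert nonzero_rows.sum() == cond2.m

    def test_mha_matches_explicit_weighted_sum(self, small_model, small_props):
        """Each gene's attention output is sum_{j in c} W_kj v_j per head."""
        model, (go_prop, _) = small_model, small_props
        c = pa.Condition([1, 7, 13])
        _, parts = pa.pertweight_forward(c, model, go_prop, return_parts=True)
        v_full = pa.sgconv(go_prop, model.e_p.data, model.t_v.data)
        h, dv = model.config.n_heads, model.config.d_v
        k = model.config.n_genes
        expected = np.zeros((k, h * dv))
        for head in range(h):
            v_head = v_full[:, head * dv:(head + 1) * dv]
            for gene in range(k):
                acc = np.zeros(dv)
                for j in c.genes:
                    acc += parts["attention"][head, gene, j] * v_head[j]
                expected[gene, head * dv:(head + 1) * dv] = acc
        assert parts["h_mha"] == pytest.approx(expected, abs=1e-10)

    def test_pre_projection_additivity_over_disjoint_conditions(
            self, small_model, small_props):
        go_prop = small_props[0]
        c1, c2 = pa.Condition([2, 5]), pa.Condition([9, 17])
        union = pa.Condition([2, 5, 9, 17])
        parts = {}
        for name, c in (("c1", c1), ("c2", c2), ("union", union)):
            _, parts[name] = pa.pertweight_forward(c, small_model, go_prop,
                                                   return_parts=True)
        assert parts["union"]["h_mha"] == pytest.approx(
            parts["c1"]["h_mha"] + parts["c2"]["h_mha"], abs=1e-5)
        assert parts["union"]["sum_p"] == pytest.approx(
            parts["c1"]["sum_p"] + parts["c2"]["sum_p"], abs=1e-5)


class TestNaBias:
    def test_identity_for_single_gene_bit_exact(self, small_model):
        z = pa.Condition([4])
        biased = pa.na_bias(z, small_model, beta=0.05)
        plain = np.where(z.indicator(20)[:, None] == 1,
                         small_model.e_z.data[1], small_model.e_z.data[0])
        assert np.array_equal(biased, plain)

    def test_beta_zero_limit_for_pairs(self, small_model, cond2):
        biased0 = pa.na_bias(cond2, small_model, beta=0.0)
        plain = np.where(cond2.indicator(20)[:, None] == 1,
                         small_model.e_z.data[1], small_model.e_z.data[0])
        assert np.array_equal(biased0, plain)
        tiny = pa.na_bias(cond2, small_model, beta=1e-9)
        assert tiny == pytest.approx(plain, abs=1e-8)

    def test_triple_matches_direct_formula(self, small_model):
        """m=3: each row is E_z scaled by 1 + 2 beta tanh(K_NA z), entrywise."""
        c = pa.Condition([0, 6, 12])
        beta = 0.07
        z = c.indicator(20)
        got = pa.na_bias(c, small_model, beta=beta)
        plain = np.where(z[:, None] == 1,
                         small_model.e_z.data[1], small_model.e_z.data[0])
        mod = 1.0 + beta * 2.0 * np.tanh(small_model.k_na.data @ z)
        assert got == pytest.approx(plain * mod[None, :], abs=1e-12)


class TestPertLocal:
    def test_single_gene_output_independent_of_beta(self, small_model_config,
                                                    small_props):
        cfg_a = pa.ModelConfig(**{**small_model_config.__dict__, "beta": 0.0})
        cfg_b = pa.ModelConfig(**{**small_model_config.__dict__, "beta": 0.05})
        a = pa.init_model(cfg_a, seed=8)
        b = pa.init_model(cfg_b, seed=8)
        z = pa.Condition([9])
        out_a = pa.pertlocal_forward(z, a, small_props[1])
        out_b = pa.pertlocal_forward(z, b, small_props[1])
        assert np.array_equal(out_a, out_b)

    def test_pair_output_depends_on_beta(self, small_model_config,
                                         small_props, cond2):
        cfg_a = pa.ModelConfig(**{**small_model_config.__dict__, "beta": 0.0})
        cfg_b = pa.ModelConfig(**{**small_model_config.__dict__, "beta": 0.05})
        a = pa.init_model(cfg_a, seed=8)
        b = pa.init_model(cfg_b, seed=8)
        out_a = pa.pertlocal_forward(cond2, a, small_props[1])
        out_b = pa.pertlocal_forward(cond2, b, small_props[1])
        assert not np.allclose(out_a, out_b)

    def test_matches_hand_composed_pipeline(self, small_model, small_props,
                                            cond2):
        """Step-by-step composition: SGConv(E_g + E'_z) -> f3 -> + f4(E_z)."""
        m, aug_prop = small_model, small_props[1]
        z = cond2.indicator(20)
        beta = m.config.beta
        plain = np.where(z[:, None] == 1, m.e_z.data[1], m.e_z.data[0])
        biased = plain * (1.0 + beta * (cond2.m - 1)
                          * np.tanh(m.k_na.data @ z))[None, :]
        sgc = aug_prop.s @ (m.e_g.data + biased) @ m.t_b.data

        def eval_bn(x, lin, bn):
            y = x @ lin.w.data + lin.b.data
            yhat = (y - bn.running_mean) / np.sqrt(bn.running_var + _BN_EPS)
            return yhat * bn.gain.data + bn.bias.data

        expected = (eval_bn(sgc, m.f3, m.f3_bn)
                    + eval_bn(plain, m.f4, m.f4_bn))
        got = pa.pertlocal_forward(cond2, m, aug_prop)
        assert got == pytest.approx(expected, abs=1e-10)


class TestDecoder:
    def test_zeroed_feedforward_returns_biases(self, small_model_config):
        m = pa.init_model(small_model_config, seed=1)
        for p in (m.f5_w1, m.f5_b1, m.f5_w2, m.f5_b2, m.dec_w):
            p.data[:] = 0.0
        m.dec_b.data[:] = np.arange(20.0)
        h = RNG.normal(size=(20, 8))
        assert np.array_equal(pa.decode(h, np.zeros((20, 8)), m),
                              np.arange(20.0))

    def test_per_gene_locality(self, small_model):
        h_pw = RNG.normal(size=(20, 8))
        h_pl = RNG.normal(size=(20, 8))
        base = pa.decode(h_pw, h_pl, small_model)
        bumped = h_pw.copy()
        bumped[7] += 5.0
        out = pa.decode(bumped, h_pl, small_model)
        changed = np.nonzero(out != base)[0]
        assert list(changed) == [7]

    def test_matches_per_gene_loop_oracle(self, small_model):
        m = small_model
        h_pw = RNG.normal(size=(20, 8))
        h_pl = RNG.normal(size=(20, 8))
        expected = np.empty(20)
        for k in range(20):
            hidden = np.maximum(
                (h_pw[k] + h_pl[k]) @ m.f5_w1.data + m.f5_b1.data, 0.0)
            hidden = hidden @ m.f5_w2.data + m.f5_b2.data
            expected[k] = m.dec_w.data[k] @ hidden + m.dec_b.data[k]
        assert pa.decode(h_pw, h_pl, m) == pytest.approx(expected, abs=1e-12)


class TestPredict:
    def test_shift_plus_control_recomposition(self, small_model, small_props,
                                              cond2):
        go_prop, aug_prop = small_props
        ctrl = RNG.normal(size=20)
        y = pa.predict(cond2, ctrl, small_model, go_prop, aug_prop)
        shift = pa.predict_shift(cond2, small_model, go_prop, aug_prop)
        assert y - ctrl == pytest.approx(shift, abs=1e-12)

    def test_shift_independent_of_control_cell(self, small_model, small_props,
                                               cond2):
        go_prop, aug_prop = small_props
        c1, c2 = RNG.normal(size=20), RNG.normal(size=20)
        y1 = pa.predict(cond2, c1, small_model, go_prop, aug_prop)
        y2 = pa.predict(cond2, c2, small_model, go_prop, aug_prop)
        assert y1 - c1 == pytest.approx(y2 - c2, abs=1e-12)
        assert not np.array_equal(y1, y2)

    def test_control_condition_is_legal_input(self, small_model, small_props):
        shift = pa.predict_shift(pa.Condition(), small_model, *small_props)
        assert np.all(np.isfinite(shift))

    def test_eval_forward_deterministic(self, small_model, small_props, cond2):
        a = pa.predict_shift(cond2, small_model, *small_props)
        b = pa.predict_shift(cond2, small_model, *small_props)
        assert np.array_equal(a, b)

    def test_batched_path_matches_single_condition_path(self, small_model,
                                                        small_props):
        from pertattn.autodiff import no_grad
        conds = [pa.Condition([1]), pa.Condition([3, 11]), pa.Condition()]
        z = np.stack([c.indicator(20) for c in conds])
        with no_grad():
            batch = small_model.forward_shifts(z, *small_props).data
        for row, c in zip(batch, conds):
            single = pa.predict_shift(c, small_model, *small_props)
            assert row == pytest.approx(single, abs=1e-12)


class TestCombinedLoss:
    def test_perfect_prediction_gives_zero(self):
        y = RNG.normal(size=(4, 6))
        assert pa.combined_loss(y, y, np.zeros(6)) == 0.0

    def test_reduces_to_mse_without_focus_and_direction(self):
        pred = RNG.normal(size=(3, 5))
        truth = RNG.normal(size=(3, 5))
        loss = pa.combined_loss(pred, truth, np.zeros(5),
                                gamma=0.0, lambda_dir=0.0)
        assert loss == pytest.approx(np.mean((pred - truth) ** 2))

    def test_direction_term_zero_when_signs_agree(self):
        ctrl = np.zeros(4)
        truth = np.array([[1.0, -1.0, 2.0, -2.0]])
        pred = np.array([[0.5, -0.1, 3.0, -0.2]])
        loss = pa.combined_loss(pred, truth, ctrl, gamma=1.0, lambda_dir=0.7)
        focus_only = pa.combined_loss(pred, truth, ctrl, gamma=1.0,
                                      lambda_dir=0.0)
        assert loss == pytest.approx(focus_only)


def test_checkpoint_round_trip(tmp_path, small_model, small_props, cond2):
    small_model.save(tmp_path / "ckpt")
    back = pa.Model.load(tmp_path / "ckpt")
    a = pa.predict_shift(cond2, small_model, *small_props)
    b = pa.predict_shift(cond2, back, *small_props)
    assert np.array_equal(a, b)
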