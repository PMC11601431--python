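"""Atom graphs and the attention regressor: geometry, gradients, training."""

import copy

import numpy as np
import pytest

from protpka.gat import (GATConfig, GATRegressor, build_graph,
                         graphs_for_records, predict_ensemble,
                         pretrain_finetune, train_ensemble)
from protpka.gat import nn
from protpka.gat.graph import NODE_WIDTH, ResidueGraph
from protpka.gat.model import load_gat, save_gat
from protpka.features import MODEL_PKA
from protpka.structure import (identify_titratable_sites, make_structure,
                               read_structure)
from protpka import _geometry


def _random_graph(rng, n, width=8):
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < 0.4]
    return ResidueGraph(
        node_features=rng.normal(size=(n, width)).astype(np.float32),
        edges=np.array(pairs, dtype=np.int64).reshape(-1, 2),
        label=float(rng.normal()), site_ref={"aa": "ASP"}, node_ids=[])


class TestBuildGraph:
    def test_node_membership_equals_brute_force(self, small_dataset):
        for pdb in list(small_dataset.structures.values())[:5]:
            st = read_structure(pdb)
            site = [s for s in identify_titratable_sites(st)
                    if s.residue_key[0] == "A"][0]
            graph = build_graph(st, site, radius=10.0)
            brute = sum(
                np.linalg.norm(a.coords - site.anchor_point) <= 10.0
                for _, a in st.iter_atoms())
            assert graph.n_nodes == brute
            assert graph.node_features.shape == (brute, NODE_WIDTH)

    def test_chain_of_atoms_has_nearest_neighbor_edges(self):
        atoms = {f"C{i}": [3.0 * i, 0.0, 0.0] for i in range(4)}
        st = make_structure([("A", 1, "", "CYS",
                              {"SG": [0, 0, 0], **atoms})])
        site = identify_titratable_sites(st)[0]
        graph = build_graph(st, site, radius=10.0, edge_cutoff=4.0)
        # nodes sorted by atom name: C0 C1 C2 C3 SG; SG sits on C0
        names = [ids[3] for ids in graph.node_ids]
        got = {frozenset((names[i], names[j])) for i, j in graph.edges}
        expected = {frozenset(p) for p in
                    (("C0", "C1"), ("C1", "C2"), ("C2", "C3"),
                     ("SG", "C0"), ("SG", "C1"))}
        assert got == expected

    def test_sparse_environment_rejected(self):
        st = make_structure([("A", 1, "", "CYS", {"SG": [0, 0, 0],
                                                  "CB": [1.8, 0, 0]})])
        site = identify_titratable_sites(st)[0]
        with pytest.raises(ValueError, match="sparse"):
            build_graph(st, site)

    def test_rigid_motion_gives_identical_graph(self, gly_asp_gly):
        site = identify_titratable_sites(gly_asp_gly)[0]
        ref = build_graph(gly_asp_gly, site)
        rot = _geometry.rotation_matrix([1.0, 1.0, 0.0], 120.0)
        specs = [(r.chain, r.resseq, r.icode, r.resname,
                  {a.name: rot @ a.coords + 7.0 for a in r.atoms})
                 for r in gly_asp_gly.residues]
        moved = make_structure(specs, source_id="gdg")
        got = build_graph(moved, identify_titratable_sites(moved)[0])
        assert np.allclose(got.node_features, ref.node_features, atol=1e-6)
        assert np.array_equal(got.edges, ref.edges)

    def test_label_is_pka_shift(self, small_dataset):
        graphs = graphs_for_records(small_dataset.records,
                                    small_dataset.structures)
        for rec, g in zip(small_dataset.records, graphs):
            assert g.label == pytest.approx(
                rec.pka_exp - MODEL_PKA[rec.aa])


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(42)
        graphs = [_random_graph(rng, n) for n in (5, 7, 4)]
        y = np.array([g.label for g in graphs])
        params = nn.init_params(8, channels=6, conv_layers=3, hidden=(5, 4),
                                rng=rng)
        batch = nn.assemble_batch(graphs)
        pred, cache = nn.forward(params, batch)
        mid, dpred = nn.mse_loss_grad(pred, y)
        grads = nn.backward(params, cache, dpred)
        eps = 1e-6
        for name, p in params.items():
            flat = rng.choice(p.size, size=min(4, p.size), replace=False)
            for k in flat:
                ix = tuple(np.unravel_index(k, p.shape))
                orig = p[ix]
                p[ix] = orig + eps
                up, _ = nn.mse_loss_grad(nn.forward(params, batch)[0], y)
                p[ix] = orig - eps
                dn, _ = nn.mse_loss_grad(nn.forward(params, batch)[0], y)
                p[ix] = orig
                an = grads[name][ix]
                # a perturbation that straddles a ReLU/LeakyReLU kink makes
                # the central difference average two slopes; the analytic
                # gradient then matches one of the one-sided differences
                candidates = ((up - dn) / (2 * eps), (up - mid) / eps,
                              (mid - dn) / eps)
                err = min(abs(fd - an) for fd in candidates)
                assert err <= 1e-5 * max(1.0, abs(an)), name

    def test_prediction_invariant_under_node_reordering(self):
        rng = np.random.default_rng(7)
        g = _random_graph(rng, 9)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        permuted = ResidueGraph(
            node_features=g.node_features[perm],
            edges=inv[g.edges], label=g.label, site_ref=g.site_ref,
            node_ids=[])
        params = nn.init_params(8, channels=6, conv_layers=3, hidden=(5, 4),
                                rng=rng)
        a, _ = nn.forward(params, nn.assemble_batch([g]))
        b, _ = nn.forward(params, nn.assemble_batch([permuted]))
        assert a[0] == pytest.approx(b[0], abs=1e-10)


class TestTraining:
    def test_loss_decreases_and_is_reproducible(self, overfit_graphs):
        a = GATRegressor(epochs=60, random_state=7).fit(overfit_graphs)
        b = GATRegressor(epochs=60, random_state=7).fit(overfit_graphs)
        assert a.history_[-1]["train_mse"] < a.history_[0]["train_mse"]
        for key in a.params_:
            assert np.array_equal(a.params_[key], b.params_[key])

    def test_constant_labels_learned(self, overfit_graphs):
        y = np.full(len(overfit_graphs), 1.5)
        m = GATRegressor(epochs=300, dropout=0.0, val_fraction=0.0,
                         random_state=0).fit(overfit_graphs, y)
        assert np.allclose(m.predict(overfit_graphs), 1.5, atol=0.1)

    def test_feature_width_mismatch_rejected(self, overfit_graphs):
        rng = np.random.default_rng(0)
        model = GATRegressor(epochs=2, random_state=0).fit(overfit_graphs)
        with pytest.raises(ValueError, match="width"):
            model.predict([_random_graph(rng, 6, width=8)])

    def test_save_load_round_trip(self, overfit_graphs, tmp_path):
        model = GATRegressor(epochs=20, random_state=1).fit(overfit_graphs)
        save_gat(model, tmp_path / "gat")
        back = load_gat(tmp_path / "gat")
        assert np.allclose(back.predict(overfit_graphs),
                           model.predict(overfit_graphs))


class TestEnsemble:
    def test_single_member_ensemble_equals_its_member(self, overfit_graphs):
        ens = train_ensemble(overfit_graphs, k=1,
                             config=GATConfig(epochs=40), seed=5)
        assert np.allclose(ens.predict(overfit_graphs),
                           ens.members_[0].predict(overfit_graphs))

    def test_same_master_seed_same_member_assignments(self, overfit_graphs):
        cfg = GATConfig(epochs=5)
        a = train_ensemble(overfit_graphs, k=3, config=cfg, seed=9)
        b = train_ensemble(overfit_graphs, k=3, config=cfg, seed=9)
        for ma, mb in zip(a.members_, b.members_):
            assert np.array_equal(ma.val_indices_, mb.val_indices_)
        # distinct members see distinct validation slices
        assert len({tuple(m.val_indices_) for m in a.members_}) > 1

    def test_prediction_is_model_pka_plus_mean_shift(self, overfit_graphs):
        ens = train_ensemble(overfit_graphs, k=2,
                             config=GATConfig(epochs=10), seed=2)
        g = overfit_graphs[0]
        member_shifts = [m.predict([g])[0] for m in ens.members_]
        expected = MODEL_PKA[g.aa] + np.mean(member_shifts)
        assert predict_ensemble(ens, g) == pytest.approx(expected)

    def test_shift_aggregation_arithmetic(self, overfit_graphs):
        ens = train_ensemble(overfit_graphs[:5] * 4, k=3,
                             config=GATConfig(epochs=2), seed=0)
        g = overfit_graphs[0]
        # force member outputs to known shifts via output-layer override
        for member, shift in zip(ens.members_, (1.0, 2.0, 3.0)):
            member.params_["mlp2_W"][:] = 0.0
            member.params_["mlp2_b"][:] = shift
        assert predict_ensemble(ens, g) == pytest.approx(
            MODEL_PKA[g.aa] + 2.0)

    def test_empty_ensemble_rejected(self, overfit_graphs):
        with pytest.raises(ValueError):
            train_ensemble(overfit_graphs, k=0)

    def test_averaging_more_members_does_not_hurt(self):
        """Held-out RMSE of the k-member average is non-increasing in k
        (averaged over seeds) — the rationale for ensembling."""
        from protpka.synth import SyntheticSpec, generate_dataset
        from protpka.gat import graphs_for_records
        ds = generate_dataset(SyntheticSpec(n_sites=30, seed=3,
                                            noise_sigma=0.0))
        graphs = graphs_for_records(ds.records, ds.structures)
        train, test = graphs[:20], graphs[20:]
        y_test = np.array([g.label for g in test])
        by_k = {1: [], 3: []}
        for seed in (0, 1):
            ens = train_ensemble(train, k=3, config=GATConfig(epochs=150),
                                 seed=seed)
            for k in by_k:
                pred = np.mean([m.predict(test)
                                for m in ens.members_[:k]], axis=0)
                by_k[k].append(np.sqrt(np.mean((pred - y_test) ** 2)))
        assert np.mean(by_k[3]) <= np.mean(by_k[1]) + 0.05


class TestPretrainFinetune:
    def test_freeze_contract_is_bitwise(self, overfit_graphs):
        pre = GATRegressor(epochs=40, random_state=2).fit(overfit_graphs)
        frozen_before = {k: v.copy() for k, v in pre.params_.items()}
        fine = GATRegressor(epochs=40, frozen_layers=2,
                            warm_start_params=pre.params_,
                            random_state=3).fit(overfit_graphs)
        for layer in (0, 1):
            for name in nn.conv_layer_names(layer):
                assert np.array_equal(fine.params_[name],
                                      frozen_before[name])
        assert not np.array_equal(fine.params_["conv2_W"],
                                  frozen_before["conv2_W"])

    def test_invalid_frozen_layer_count(self, overfit_graphs):
        with pytest.raises(ValueError):
            pretrain_finetune(overfit_graphs, overfit_graphs, 3)

    def test_zero_finetune_epochs_is_identity(self, overfit_graphs):
        cfg = GATConfig(epochs=30)
        tuned = pretrain_finetune(overfit_graphs, overfit_graphs, 0, cfg,
                                  seed=2, finetune_epochs=0)
        pre = GATRegressor(epochs=30, random_state=2).fit(overfit_graphs)
        for key in pre.params_:
            assert np.array_equal(tuned.params_[key], pre.params_[key])

    def test_releasing_all_layers_fits_better_than_freezing_two(
            self, overfit_graphs):
        """Scaled-down freeze study: fine-tuning with everything trainable
        reaches a lower fine-tune loss than with two conv layers frozen."""
        truth = np.array([g.label for g in overfit_graphs])
        biased = truth + 0.5
        pre = GATRegressor(epochs=150, dropout=0.0, val_fraction=0.0,
                           random_state=4).fit(overfit_graphs, biased)
        losses = {}
        for frozen in (0, 2):
            fine = GATRegressor(epochs=200, dropout=0.0, val_fraction=0.0,
                                frozen_layers=frozen,
                                warm_start_params=pre.params_,
                                random_state=5).fit(overfit_graphs, truth)
            losses[frozen] = fine.training_mse(overfit_graphs, truth)
        assert losses[0] <= losses[2]

    def test_finetuning_removes_systematic_pretraining_bias(
            self, overfit_graphs):
        """Pretraining labels carry a +0.5 bias; fine-tuning on unbiased
        labels must beat the pretrained model on held-out truth."""
        truth = np.array([g.label for g in overfit_graphs])
        biased = truth + 0.5
        train_idx = list(range(14))
        test_idx = list(range(14, 20))
        train_graphs = [overfit_graphs[i] for i in train_idx]
        test_graphs = [overfit_graphs[i] for i in test_idx]
        cfg = GATConfig(epochs=300, dropout=0.0, val_fraction=0.0)
        pre = GATRegressor(epochs=300, dropout=0.0, val_fraction=0.0,
                           random_state=4).fit(train_graphs,
                                               biased[train_idx])
        tuned = pretrain_finetune(
            train_graphs, train_graphs, 0, cfg, seed=4,
            pretrain_y=biased[train_idx], finetune_y=truth[train_idx],
            finetune_epochs=300)
        rmse_pre = np.sqrt(np.mean(
            (pre.predict(test_graphs) - truth[test_idx]) ** 2))
        rmse_tuned = np.sqrt(np.mean(
            (tuned.predict(test_graphs) - truth[test_idx]) ** 2))
        assert rmse_tuned < rmse_pre
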