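import numpy as np
import pandas as pd
import pytest

from oxhmc.core_io import EmptyInputError, ValidationError
from oxhmc import pathway_enrichment as pe
from oxhmc.pathway_enrichment import build_universe, group_redundant, read_gmt, write_gmt


def _ann_from_gene_probes(gene_probes: dict[str, int], test_genes=()):
    """Annotation with gene_probes[g] probes per gene; probes of test genes
    are returned separately as the test set."""
    rows, test_probes = [], []
    i = 0
    for g, k in gene_probes.items():
        for _ in range(k):
            pid = f"cg{i:05d}"
            rows.append((pid, frozenset({g})))
            if g in test_genes:
                test_probes.append(pid)
            i += 1
    ann = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(len(rows)) + 1,
            "cgi_feature": "outside",
            "gene_feature": "gene_body",
            "tfbs": False,
            "dhs": False,
            "alt_events": [frozenset()] * len(rows),
            "genes": [r[1] for r in rows],
            "is_snp_probe": False,
            "masked": False,
        },
        index=pd.Index([r[0] for r in rows], name="probe_id"),
    )
    return ann, test_probes


class TestBuildUniverse:
    def test_probe_counts_tallied(self):
        ann, _ = _ann_from_gene_probes({f"G{i}": i + 1 for i in range(12)})
        sets = {"P": frozenset(f"G{i}" for i in range(12))}
        u = build_universe(ann, sets, size_bounds=(1, 2000))
        assert u.genes.loc["G4", "n_probes"] == 5

    def test_parent_propagation_single_edge(self):
        ann, _ = _ann_from_gene_probes({f"G{i}": 1 for i in range(20)})
        sets = {"T": frozenset(f"G{i}" for i in range(10))}
        u = build_universe(ann, sets, ontology_parents=[("T", "P")], size_bounds=(1, 2000))
        assert u.pathways["P"] == u.pathways["T"]

    def test_three_level_chain_matches_dfs_oracle(self):
        ann, _ = _ann_from_gene_probes({f"G{i}": 1 for i in range(30)})
        sets = {
            "A": frozenset({"G0", "G1"}),
            "B": frozenset({"G2"}),
            "C": frozenset({"G3"}),
        }
        edges = [("A", "B"), ("B", "C")]
        u = build_universe(ann, sets, ontology_parents=edges, size_bounds=(1, 2000))

        # independent oracle: brute-force reachability over the edge list
        def reach(term):
            members = set(sets.get(term, set()))
            for child, parent in edges:
                if parent == term:
                    members |= reach(child)
            return members

        for term in ("A", "B", "C"):
            assert u.pathways[term] == frozenset(reach(term))

    def test_size_bounds_inclusive(self):
        ann, _ = _ann_from_gene_probes({f"G{i}": 1 for i in range(30)})
        sets = {
            "nine": frozenset(f"G{i}" for i in range(9)),
            "ten": frozenset(f"G{i}" for i in range(10)),
        }
        u = build_universe(ann, sets, size_bounds=(10, 2000))
        assert "nine" not in u.pathways
        assert "ten" in u.pathways

    def test_cycle_rejected(self):
        ann, _ = _ann_from_gene_probes({"G0": 1, "G1": 1})
        sets = {"A": frozenset({"G0"}), "B": frozenset({"G1"})}
        with pytest.raises(ValidationError, match="cycle"):
            build_universe(ann, sets, ontology_parents=[("A", "B"), ("B", "A")], size_bounds=(1, 10))

    def test_empty_gene_sets_rejected(self):
        ann, _ = _ann_from_gene_probes({"G0": 1})
        with pytest.raises(EmptyInputError):
            build_universe(ann, {})


def _irls_logit_oracle(y, X, max_iter=100):
    """Plain IRLS logistic regression, independent of statsmodels."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        z = eta + (y - p) / np.maximum(W, 1e-10)
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    cov = np.linalg.inv(X.T @ (X * (p * (1 - p))[:, None]))
    return beta, cov


class TestTestPathway:
    def test_balanced_null_coefficient_near_zero(self):
        # 100 genes, 50 in pathway, 50 in list, overlap exactly 25,
        # equal probe counts: exact independence.
        genes = {f"G{i:03d}": 1 for i in range(100)}
        in_path = [f"G{i:03d}" for i in range(50)]
        in_list = [f"G{i:03d}" for i in range(25)] + [f"G{i:03d}" for i in range(50, 75)]
        ann, test_probes = _ann_from_gene_probes(genes, test_genes=in_list)
        sets = {"P": frozenset(in_path), "ALL": frozenset(genes)}
        u = build_universe(ann, sets, test_probes=test_probes, size_bounds=(1, 2000))
        res = pe.test_pathway(u, "P")
        assert abs(res.coefficient) < 1e-6
        assert res.p_value > 0.99
        assert not res.significant

    def test_confounded_design_fixed_by_covariate(self, rng):
        # membership and the test list are both driven purely by probe
        # count; adjusting for it removes the spurious association.
        n = 600
        n_probes = rng.integers(1, 30, n)
        p_conf = 1 / (1 + np.exp(-(n_probes - 15) / 4))
        member = rng.random(n) < p_conf
        listed = rng.random(n) < p_conf
        genes = {f"G{i:04d}": int(k) for i, k in enumerate(n_probes)}
        in_list = [g for g, m in zip(genes, listed) if m]
        ann, test_probes = _ann_from_gene_probes(genes, test_genes=in_list)
        pw = frozenset(g for g, m in zip(genes, member) if m)
        u = build_universe(ann, {"P": pw, "ALL": frozenset(genes)}, test_probes=test_probes, size_bounds=(1, 5000))

        naive = pe.test_pathway(u, "P", adjust=False)
        adjusted = pe.test_pathway(u, "P", adjust=True)
        assert naive.p_value < 0.05
        assert adjusted.p_value > 0.05

        # verify the adjusted fit against an independent IRLS oracle
        y = u.membership("P")
        X = np.column_stack(
            [np.ones(len(u.genes)), u.genes["in_test_list"].to_numpy(float), u.genes["n_probes"].to_numpy(float)]
        )
        beta, cov = _irls_logit_oracle(y, X)
        assert adjusted.coefficient == pytest.approx(beta[1], abs=1e-5)
        from scipy.stats import norm

        p_oracle = 2 * norm.sf(abs(beta[1] / np.sqrt(cov[1, 1])))
        assert adjusted.p_value == pytest.approx(p_oracle, rel=1e-3)

    def test_unknown_pathway(self):
        ann, _ = _ann_from_gene_probes({f"G{i}": 1 for i in range(20)})
        u = build_universe(ann, {"P": frozenset(f"G{i}" for i in range(12)), "ALL": frozenset(f"G{i}" for i in range(20))}, size_bounds=(1, 2000))
        with pytest.raises(ValidationError):
            pe.test_pathway(u, "missing")


def _signal_universe(rng, n=400, overlap_boost=6.0, dup=False, disjoint=False):
    genes = {f"G{i:04d}": int(rng.integers(1, 6)) for i in range(n)}
    gids = list(genes)
    pw_a = frozenset(gids[:80])
    pw_b = frozenset(gids[:80]) if dup else frozenset(gids[80:160] if disjoint else gids[40:120])
    # test list enriched inside both pathways
    p = np.full(n, 0.15)
    for i, g in enumerate(gids):
        if g in pw_a or g in pw_b:
            p[i] = min(0.15 * overlap_boost, 0.9)
    in_list = [g for g, hit in zip(gids, rng.random(n) < p) if hit]
    ann, test_probes = _ann_from_gene_probes(genes, test_genes=in_list)
    u = build_universe(ann, {"A": pw_a, "B": pw_b, "ALL": frozenset(gids)}, test_probes=test_probes, size_bounds=(1, 5000))
    return u


class TestGroupRedundant:
    def test_single_significant_pathway_is_its_own_leader(self, rng):
        u = _signal_universe(rng, disjoint=True)
        results = [r for r in pe.test_all_pathways(u) if r.pathway_id == "A"]
        grouped = group_redundant(results, u)
        assert grouped[0].group_leader == "A"
        assert grouped[0].explained_by is None

    def test_duplicate_pathway_collapses_to_better_leader(self, rng):
        u = _signal_universe(rng, dup=True)
        results = [r for r in pe.test_all_pathways(u) if r.pathway_id in ("A", "B")]
        assert all(r.significant for r in results)
        grouped = group_redundant(results, u)
        leader, follower = grouped[0], grouped[1]
        assert follower.explained_by == leader.pathway_id
        assert leader.explained_by is None

    def test_disjoint_independent_signals_stay_leaders(self, rng):
        u = _signal_universe(rng, disjoint=True)
        results = [r for r in pe.test_all_pathways(u) if r.pathway_id in ("A", "B")]
        assert all(r.significant for r in results)
        grouped = group_redundant(results, u)
        assert all(r.explained_by is None for r in grouped)
        assert all(r.group_leader == r.pathway_id for r in grouped)

    def test_grouping_is_a_partition(self, rng):
        u = _signal_universe(rng)
        grouped = group_redundant(pe.test_all_pathways(u), u)
        for r in grouped:
            if r.significant:
                assert r.group_leader is not None
                if r.explained_by is not None:
                    assert r.explained_by == r.group_leader

    def test_output_order_deterministic(self, rng):
        u = _signal_universe(rng)
        a = [r.pathway_id for r in group_redundant(pe.test_all_pathways(u), u)]
        b = [r.pathway_id for r in group_redundant(pe.test_all_pathways(u), u)]
        assert a == b


def test_gmt_round_trip(tmp_path):
    sets = {"P1": frozenset({"A", "B"}), "P2": frozenset({"C"})}
    write_gmt(sets, tmp_path / "x.gmt")
    assert read_gmt(tmp_path / "x.gmt") == sets
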