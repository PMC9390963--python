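"""Promoter-window geometry, pruning against a brute-force interval scan,
TF→ISG matrices and the hive-quadrant statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from onoffgrn.direct import (
    DirectNetwork,
    classify_nodes,
    hive_quadrant_stats,
    promoter_window,
    prune_direct,
    tf_to_isg_matrix,
)
from onoffgrn.grn import ImportanceNetwork
from ._oracles import prune_reference


def make_net(rows):
    return ImportanceNetwork(
        edges=pd.DataFrame(rows, columns=["regulator", "target", "importance"]),
        candidate_regulators=tuple({r for r, _, _ in rows}),
        n_trees=1, k_mode="sqrt", seed=0,
    )


class TestPromoterWindow:
    def test_plus_strand(self):
        assert promoter_window(10_000, "+") == (9_600, 10_300)

    def test_minus_strand_mirrors(self):
        assert promoter_window(10_000, "-") == (9_700, 10_400)

    def test_clipped_at_zero(self):
        assert promoter_window(200, "+") == (0, 500)

    def test_ignore_strand_uses_plus_orientation(self):
        assert promoter_window(10_000, "-", ignore_strand=True) == (9_600, 10_300)

    @given(st.integers(0, 10**6), st.sampled_from("+-"), st.integers(0, 2000), st.integers(0, 2000))
    def test_window_length_and_monotonicity(self, tss, strand, up, down):
        s, e = promoter_window(tss, strand, up, down)
        assert 0 <= s <= e
        s2, e2 = promoter_window(tss, strand, up + 100, down + 100)
        assert s2 <= s and e2 >= e  # enlarging the window only grows it


class TestPruneDirect:
    @pytest.fixture()
    def annotations(self):
        tss = pd.DataFrame(
            {"gene": ["G1", "G2"], "chrom": ["chr1", "chr1"], "tss": [10_000, 60_000], "strand": ["+", "-"]}
        )
        tfbs = pd.DataFrame(
            {
                "tf": ["T1", "T2", "T1"],
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [9_650, 10_500, 59_800],
                "end": [9_661, 10_511, 59_810],
            }
        )
        return tss, tfbs

    def test_in_window_site_retained(self, annotations):
        tss, tfbs = annotations
        net = make_net([("T1", "G1", 0.9)])
        d = prune_direct(net, tss, tfbs, de_genes=["G1"], tf_list=["T1"])
        assert len(d.edges) == 1

    def test_out_of_window_site_dropped(self, annotations):
        tss, tfbs = annotations
        net = make_net([("T2", "G1", 0.9)])
        d = prune_direct(net, tss, tfbs, de_genes=["G1"], tf_list=["T2"])
        assert len(d.edges) == 0

    def test_minus_strand_window(self, annotations):
        tss, tfbs = annotations
        # G2 at 60,000 on -: window [59,700, 60,400); site [59,800, 59,810) inside
        net = make_net([("T1", "G2", 0.5)])
        d = prune_direct(net, tss, tfbs, de_genes=["G2"], tf_list=["T1"])
        assert len(d.edges) == 1

    def test_non_de_target_dropped(self, annotations):
        tss, tfbs = annotations
        net = make_net([("T1", "G1", 0.9)])
        d = prune_direct(net, tss, tfbs, de_genes=["G2"], tf_list=["T1"])
        assert len(d.edges) == 0

    def test_missing_tss_warned(self, annotations):
        _, tfbs = annotations
        tss = pd.DataFrame({"gene": ["G2"], "chrom": ["chr1"], "tss": [60_000], "strand": ["-"]})
        net = make_net([("T1", "G1", 0.9)])
        with pytest.warns(UserWarning, match="lacked a TSS"):
            d = prune_direct(net, tss, tfbs, de_genes=["G1"], tf_list=["T1"])
        assert d.n_dropped_no_tss == 1

    def test_tf_without_any_site_warned(self, annotations):
        tss, tfbs = annotations
        net = make_net([("T9", "G1", 0.9)])
        with pytest.warns(UserWarning, match="no binding site"):
            d = prune_direct(net, tss, tfbs, de_genes=["G1"], tf_list=["T9"])
        assert len(d.edges) == 0

    def test_matches_brute_force_scan_on_random_instances(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(12)]
        tfs = ["T1", "T2", "T3"]
        for trial in range(10):
            tss = pd.DataFrame(
                {
                    "gene": genes,
                    "chrom": rng.choice(["chr1", "chr2"], size=len(genes)),
                    "tss": rng.integers(0, 5_000, size=len(genes)),
                    "strand": rng.choice(["+", "-"], size=len(genes)),
                }
            )
            starts = rng.integers(0, 5_500, size=30)
            tfbs = pd.DataFrame(
                {
                    "tf": rng.choice(tfs, size=30),
                    "chrom": rng.choice(["chr1", "chr2"], size=30),
                    "start": starts,
                    "end": starts + rng.integers(5, 30, size=30),
                }
            )
            rows = [(r, t, float(rng.uniform())) for r in tfs for t in genes]
            net = make_net(rows)
            de = list(rng.choice(genes, size=6, replace=False))
            got = prune_direct(net, tss, tfbs, de_genes=de, tf_list=tfs)
            expected = prune_reference(net.edges, tss, tfbs, de, tfs)
            assert set(zip(got.edges["regulator"], got.edges["target"])) == expected, trial

    def test_record_order_invariance(self, annotations):
        tss, tfbs = annotations
        rows = [("T1", "G1", 0.9), ("T1", "G2", 0.5), ("T2", "G1", 0.2)]
        net_fwd = make_net(rows)
        net_rev = make_net(rows[::-1])
        tfbs_rev = tfbs.iloc[::-1].reset_index(drop=True)
        a = prune_direct(net_fwd, tss, tfbs, de_genes=["G1", "G2"], tf_list=["T1", "T2"])
        b = prune_direct(net_rev, tss, tfbs_rev, de_genes=["G1", "G2"], tf_list=["T1", "T2"])
        assert set(map(tuple, a.edges.to_numpy())) == set(map(tuple, b.edges.to_numpy()))

    def test_window_enlargement_is_monotone(self, annotations):
        tss, tfbs = annotations
        net = make_net([("T1", "G1", 0.9), ("T2", "G1", 0.8), ("T1", "G2", 0.5)])
        kept_small = prune_direct(net, tss, tfbs, de_genes=["G1", "G2"], tf_list=["T1", "T2"], up=50, down=50)
        kept_big = prune_direct(net, tss, tfbs, de_genes=["G1", "G2"], tf_list=["T1", "T2"], up=900, down=900)
        small = set(zip(kept_small.edges["regulator"], kept_small.edges["target"]))
        big = set(zip(kept_big.edges["regulator"], kept_big.edges["target"]))
        assert small <= big


def make_direct(rows, node_class):
    return DirectNetwork(
        edges=pd.DataFrame(rows, columns=["regulator", "target", "importance"]),
        node_class=node_class, window_up=400, window_down=300, strand_aware=True,
    )


class TestTfToIsgMatrix:
    def test_absent_pairs_zero(self):
        d = make_direct([], {})
        mat = tf_to_isg_matrix(d, ["Irf1"], ["IsgA"])
        assert (mat.to_numpy() == 0).all()

    def test_single_edge(self):
        d = make_direct([("Irf1", "IsgA", 0.7)], {})
        mat = tf_to_isg_matrix(d, ["Irf1", "Stat1"], ["IsgA", "IsgB"])
        assert mat.loc["Irf1", "IsgA"] == 0.7
        assert mat.to_numpy().sum() == pytest.approx(0.7)

    def test_row_sums_equal_outgoing_importance_to_isgs(self):
        rng = np.random.default_rng(1)
        tfs, isgs = ["T1", "T2"], ["I1", "I2", "I3"]
        rows = [(t, i, float(rng.uniform())) for t in tfs for i in isgs[:2]]
        rows.append(("T1", "other", 5.0))  # outside the ISG set
        d = make_direct(rows, {})
        mat = tf_to_isg_matrix(d, tfs, isgs)
        for t in tfs:
            direct_sum = sum(w for r, g, w in rows if r == t and g in isgs)
            assert mat.loc[t].sum() == pytest.approx(direct_sum)


class TestHiveQuadrant:
    def _nodes(self):
        return {"Irf1": "ifn_tf", "T2": "other_tf", "IsgA": "fast_isg", "X": "other"}

    def test_unique_max_in_quadrant_gives_fraction_one(self):
        rows = [("T2", "X", float(i)) for i in range(9)] + [("Irf1", "IsgA", 100.0)]
        stats = hive_quadrant_stats(make_direct(rows, self._nodes()), quantile=0.9)
        assert stats["fraction_in_tf_to_isg_quadrant"] == 1.0
        assert stats["n_top_edges"] == 1

    def test_max_outside_quadrant_gives_zero(self):
        rows = [("Irf1", "IsgA", float(i)) for i in range(9)] + [("T2", "X", 100.0)]
        stats = hive_quadrant_stats(make_direct(rows, self._nodes()), quantile=0.9)
        assert stats["fraction_in_tf_to_isg_quadrant"] == 0.0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(2)
        classes = ["ifn_tf", "other_tf", "fast_isg", "other"]
        for trial in range(10):
            nodes = {f"n{i}": classes[i % 4] for i in range(8)}
            names = list(nodes)
            rows = [
                (names[rng.integers(0, 8)], names[rng.integers(0, 8)], float(rng.uniform()))
                for _ in range(25)
            ]
            rows = [(r, t, w) for r, t, w in rows if r != t]
            if len(rows) < 10:
                continue
            d = make_direct(rows, nodes)
            got = hive_quadrant_stats(d, quantile=0.9)
            thr = np.quantile([w for _, _, w in rows], 0.9)
            top = [(r, t) for r, t, w in rows if w > thr]
            frac = (
                sum(nodes[r] == "ifn_tf" and nodes[t] == "fast_isg" for r, t in top) / len(top)
                if top else 0.0
            )
            assert got["fraction_in_tf_to_isg_quadrant"] == pytest.approx(frac)
            assert 0.0 <= got["fraction_in_tf_to_isg_quadrant"] <= 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        nodes = self._nodes()
        rows = [("Irf1", "IsgA", float(rng.uniform())) for _ in range(6)]
        rows += [("T2", "X", float(rng.uniform())) for _ in range(6)]
        a = hive_quadrant_stats(make_direct(rows, nodes))
        scaled = [(r, t, w * 123.0) for r, t, w in rows]
        b = hive_quadrant_stats(make_direct(scaled, nodes))
        assert a["fraction_in_tf_to_isg_quadrant"] == b["fraction_in_tf_to_isg_quadrant"]
        assert a["n_top_edges"] == b["n_top_edges"]

    def test_all_equal_importances_warn_zero_top(self):
        rows = [("Irf1", "IsgA", 1.0)] * 10
        with pytest.warns(UserWarning, match="above the quantile"):
            stats = hive_quadrant_stats(make_direct(rows, self._nodes()))
        assert stats["n_top_edges"] == 0
        assert stats["threshold"] == 1.0

    def test_too_few_edges_rejected(self):
        with pytest.raises(ValueError, match=">= 10 edges"):
            hive_quadrant_stats(make_direct([("Irf1", "IsgA", 1.0)], self._nodes()))


def test_classify_nodes_precedence():
    classes = classify_nodes(
        ["Irf1", "Tf06", "IsgF001", "G0001"],
        tf_list=["Irf1", "Tf06"],
        ifn_tfs=["Irf1"],
        fast_isgs=["IsgF001", "Irf1"],  # TF class wins over fast-ISG
    )
    assert classes == {"Irf1": "ifn_tf", "Tf06": "other_tf", "IsgF001": "fast_isg", "G0001": "other"}
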