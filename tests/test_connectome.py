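"""Connectome filtering, similarity, classification and valence prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvanet import connectome as cn
from larvanet.core import PairedAdjacency


def toy_adjacency(connections, classes, extra_pairs=()):
    """Build a PairedAdjacency from pair-level specs.

    ``connections``: {(pre_pair, post_pair): (syn_left, syn_right)} where each
    side's synapses go from that presynaptic hemisphere neuron onto the
    ipsilateral postsynaptic neuron. ``classes``: {pair: (class, transmitter,
    valence)}.
    """
    pair_ids = sorted(
        {p for conn in connections for p in conn} | set(classes) | set(extra_pairs)
    )
    neuron_ids = [f"{p} {h}" for p in pair_ids for h in ("L", "R")]
    counts = pd.DataFrame(0, index=neuron_ids, columns=neuron_ids)
    for (pre, post), (sl, sr) in connections.items():
        counts.loc[f"{pre} L", f"{post} L"] += sl
        counts.loc[f"{pre} R", f"{post} R"] += sr
    rows = []
    for p in pair_ids:
        cls, tx, val = classes.get(p, ("other", "ACh", "none"))
        for h in ("L", "R"):
            rows.append(
                {
                    "id": f"{p} {h}",
                    "hemisphere": h,
                    "homolog_id": f"{p} {'R' if h == 'L' else 'L'}",
                    "class": cls,
                    "transmitter": tx,
                    "valence": val,
                }
            )
    return PairedAdjacency(counts, pd.DataFrame(rows))


class TestLoadValidate:
    def test_roundtrip_through_csv(self, tmp_path):
        adj = toy_adjacency({("A", "B"): (3, 7)}, {"A": ("MBON", "ACh", "positive")})
        adj.to_csv(tmp_path / "adj.csv", tmp_path / "ann.csv")
        loaded = cn.load_paired_adjacency(tmp_path / "adj.csv", tmp_path / "ann.csv")
        assert loaded.counts.equals(adj.counts)
        assert loaded.counts.loc["A L", "B L"] == 3

    def test_negative_counts_rejected(self):
        adj = toy_adjacency({("A", "B"): (3, 7)}, {})
        counts = adj.counts.copy()
        counts.iloc[0, 1] = -1
        with pytest.raises(ValueError, match="negative"):
            PairedAdjacency(counts, adj.annotations)

    def test_self_pairing_rejected(self):
        adj = toy_adjacency({("A", "B"): (1, 1)}, {})
        ann = adj.annotations.copy()
        ann.loc["A L", "homolog_id"] = "A L"
        with pytest.raises(ValueError, match="itself"):
            PairedAdjacency(adj.counts, ann.reset_index(names="id"))

    def test_duplicate_ids_rejected(self):
        counts = pd.DataFrame(
            np.zeros((2, 2), dtype=int), index=["X", "X"], columns=["X", "X"]
        )
        ann = pd.DataFrame(
            [{"id": "X", "hemisphere": "L", "homolog_id": "", "class": "other",
              "transmitter": "ACh", "valence": "none"}]
        )
        with pytest.raises(ValueError, match="duplicate|square"):
            PairedAdjacency(counts, ann)

    def test_unpaired_neurons_flagged_not_dropped(self):
        adj = toy_adjacency({("A", "B"): (5, 5)}, {})
        counts = adj.counts.copy()
        counts["solo"] = 0
        counts.loc["solo"] = 0
        ann = adj.annotations.reset_index(names="id")
        ann = pd.concat(
            [ann, pd.DataFrame([{"id": "solo", "hemisphere": "L", "homolog_id": "",
                                 "class": "other", "transmitter": "ACh", "valence": "none"}])]
        )
        pa = PairedAdjacency(counts, ann)
        assert pa.unpaired_ids() == ["solo"]
        assert "solo" not in pa.pairs().index


class TestStrongConnections:
    @pytest.mark.parametrize(
        "sl,sr,expected",
        [
            (3, 7, True),   # boundary: sum exactly 10, both sides >= 3
            (2, 10, False),  # per-side minimum violated
            (5, 4, False),   # sum below 10
            (0, 0, False),
            (10, 10, True),
        ],
    )
    def test_rule_boundaries(self, sl, sr, expected):
        if sl + sr == 0:
            adj = toy_adjacency({}, {}, extra_pairs=("A", "B"))
        else:
            adj = toy_adjacency({("A", "B"): (sl, sr)}, {})
        strong = cn.strong_connections(adj)
        flagged = strong[strong["strong"]]
        assert (len(flagged) == 1) == expected

    def test_contralateral_synapses_count(self):
        # 2 ipsi + 1 contra per side still gives 3 per side
        adj = toy_adjacency({("A", "B"): (2, 2)}, {})
        counts = adj.counts.copy()
        counts.loc["A L", "B R"] = 3
        counts.loc["A R", "B L"] = 3
        strong = cn.strong_connections(
            PairedAdjacency(counts, adj.annotations.reset_index(names="id"))
        )
        row = strong.iloc[0]
        assert row["syn_left"] == 5 and row["syn_right"] == 5 and row["strong"]

    def test_adding_synapses_never_demotes(self):
        rng = np.random.default_rng(7)
        conns = {("A", "B"): (4, 6), ("B", "C"): (1, 2), ("C", "A"): (3, 3)}
        adj = toy_adjacency(conns, {})
        before = cn.strong_connections(adj)
        counts = adj.counts + rng.integers(0, 3, adj.counts.shape)
        np.fill_diagonal(counts.values, 0)
        after = cn.strong_connections(
            PairedAdjacency(counts, adj.annotations.reset_index(names="id"))
        )
        merged = before.merge(after, on=["pre_pair", "post_pair"], suffixes=("_b", "_a"))
        assert not ((merged["strong_b"]) & (~merged["strong_a"])).any()


class TestFalsePositiveModel:
    def test_two_contact_values(self):
        prob, recip = cn.false_positive_probability(2)
        assert round(prob, 5) == 0.00028
        assert round(recip) == 3586

    def test_boundary_cases(self):
        assert cn.false_positive_probability(0)[0] == 1.0
        assert cn.false_positive_probability(1)[0] == 0.0167
        with pytest.raises(ValueError):
            cn.false_positive_probability(-1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(0, 20), m=st.integers(0, 20))
    def test_multiplicative_in_contact_count(self, n, m):
        f = lambda k: cn.false_positive_probability(k)[0]
        assert f(n + m) == pytest.approx(f(n) * f(m), rel=1e-12)
        if m > 0:
            assert f(n + m) < f(n)


class TestSimilarity:
    def test_hand_counts(self):
        mat = pd.DataFrame(
            [[1, 1, 0], [1, 0, 0], [0, 0, 1]],
            index=list("ABC"), columns=list("XYZ"),
        )
        s = cn.similarity(mat, axis="rows")
        assert s.loc["A", "B"] == pytest.approx(0.5)  # 1 match, 1 mismatch
        assert s.loc["A", "C"] == 0.0  # disjoint supports
        assert s.loc["A", "A"] == 1.0
        assert np.allclose(s.to_numpy(), s.to_numpy().T)

    def test_empty_rows_are_null_on_diagonal(self):
        # a pair with no strong outputs has undefined self-similarity but
        # plain dissimilarity (0) to any pair that does have outputs
        mat = pd.DataFrame([[0, 0], [1, 0]], index=["A", "B"], columns=["X", "Y"])
        s = cn.similarity(mat)
        assert np.isnan(s.loc["A", "A"])
        assert s.loc["A", "B"] == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1))
    def test_matches_set_oracle(self, abits, bbits):
        a = np.array([(abits >> i) & 1 for i in range(12)])
        b = np.array([(bbits >> i) & 1 for i in range(12)])
        mat = pd.DataFrame([a, b], index=["A", "B"])
        s = cn.similarity(mat).loc["A", "B"]
        sa, sb = {i for i in range(12) if a[i]}, {i for i in range(12) if b[i]}
        if not sa and not sb:
            assert np.isnan(s)
        else:
            assert s == pytest.approx(len(sa & sb) / len(sa | sb))


class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        mat = pd.DataFrame(
            [[1, 1, 0], [1, 1, 0], [0, 0, 1]], index=list("ABC"), columns=list("XYZ")
        )
        order, Z, newick = cn.cluster_similarity(cn.similarity(mat))
        assert Z[0, 2] == 0.0  # first merge at distance 0
        assert abs(order.index("A") - order.index("B")) == 1  # adjacent leaves
        assert newick.count(",") == 2 and newick.endswith(";")

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(9)
        base1 = (rng.random(20) < 0.5).astype(int)
        base2 = (rng.random(20) < 0.5).astype(int)
        rows, ids = [], []
        for i in range(4):
            rows.append(base1 ^ (rng.random(20) < 0.05))
            ids.append(f"a{i}")
        for i in range(4):
            rows.append(base2 ^ (rng.random(20) < 0.05))
            ids.append(f"b{i}")
        mat = pd.DataFrame(np.array(rows, dtype=int), index=ids)
        order, _, _ = cn.cluster_similarity(cn.similarity(mat))
        groups = ["a" if o.startswith("a") else "b" for o in order]
        assert groups == sorted(groups) or groups == sorted(groups, reverse=True)

    def test_permutation_invariance(self):
        mat = pd.DataFrame(
            np.array([[1, 1, 0, 0], [1, 1, 1, 0], [0, 0, 1, 1], [0, 1, 1, 1]]),
            index=list("ABCD"),
        )
        s = cn.similarity(mat)
        perm = ["C", "A", "D", "B"]
        _, Z1, _ = cn.cluster_similarity(s)
        _, Z2, _ = cn.cluster_similarity(s.loc[perm, perm])
        assert np.allclose(np.sort(Z1[:, 2]), np.sort(Z2[:, 2]))

    def test_too_few_items_error(self):
        mat = pd.DataFrame([[1]], index=["A"], columns=["X"])
        with pytest.raises(ValueError):
            cn.cluster_similarity(cn.similarity(mat))


class TestInputFractions:
    def test_single_source(self):
        adj = toy_adjacency({("A", "B"): (5, 5)}, {"A": ("MBON", "ACh", "positive")})
        frac = cn.input_fractions(adj, "B")
        assert frac["MBON"] == pytest.approx(1.0)

    def test_hand_arithmetic_and_sum(self):
        adj = toy_adjacency(
            {("A", "C"): (3, 2), ("B", "C"): (50, 45)},
            {"A": ("MBON", "ACh", "positive"), "B": ("LHN", "ACh", "none")},
        )
        frac = cn.input_fractions(adj, "C")
        assert frac["MBON"] == pytest.approx(0.05)  # 5 of 100 input synapses
        assert frac.sum() == pytest.approx(1.0)

    def test_zero_input_errors(self):
        adj = toy_adjacency({("A", "B"): (5, 5)}, {})
        with pytest.raises(ValueError, match="zero input"):
            cn.input_fractions(adj, "A")


class TestClassification:
    def test_convergence_neuron_definition(self):
        adj = toy_adjacency(
            {("M", "C"): (5, 5), ("L", "C"): (6, 6), ("M", "D"): (5, 7)},
            {"M": ("MBON", "ACh", "positive"), "L": ("LHN", "ACh", "none")},
        )
        cls = cn.classify_neurons(adj)
        assert cls.loc["C", "is_cn"] and cls.loc["C", "is_mb2on"]
        assert cls.loc["D", "is_mb2on"] and not cls.loc["D", "is_cn"]

    def test_weak_symmetric_kc_input_disregarded(self):
        adj = toy_adjacency(
            {("K", "C"): (2, 2), ("M", "C"): (5, 5)},
            {"K": ("KC", "ACh", "none"), "M": ("MBON", "ACh", "positive")},
        )
        cls = cn.classify_neurons(adj)
        assert not cls.loc["C", "kc_input_reliable"]

    def test_asymmetric_kc_input_disregarded(self):
        adj = toy_adjacency(
            {("K", "C"): (8, 2)}, {"K": ("KC", "ACh", "none")}
        )
        cls = cn.classify_neurons(adj)
        assert not cls.loc["C", "kc_input_reliable"]

    def test_reliable_kc_input_flagged(self):
        adj = toy_adjacency({("K", "C"): (5, 6)}, {"K": ("KC", "ACh", "none")})
        assert cn.classify_neurons(adj).loc["C", "kc_input_reliable"]

    def test_fbn_flag_for_dan_targets(self):
        adj = toy_adjacency(
            {("C", "D"): (5, 5)}, {"D": ("DAN", "unknown", "none")}
        )
        assert cn.classify_neurons(adj).loc["C", "fbn_flag"]

    def test_missing_class_annotation_errors(self):
        adj = toy_adjacency({("A", "B"): (5, 5)}, {})
        ann = adj.annotations.copy()
        ann["class"] = ""
        pa = PairedAdjacency(adj.counts, ann.reset_index(names="id"))
        with pytest.raises(ValueError, match="class"):
            cn.classify_neurons(pa)


class TestValencePrediction:
    def test_excitatory_positive_plus_inhibitory_negative(self):
        # 6% excitatory input from a positive MBON + 6% inhibitory from a
        # negative MBON -> predicted positive
        adj = toy_adjacency(
            {("MP", "C"): (3, 3), ("MN", "C"): (3, 3), ("X", "C"): (44, 44)},
            {"MP": ("MBON", "ACh", "positive"), "MN": ("MBON", "GABA", "negative")},
        )
        pred = cn.predict_valence(adj, min_sum=5)
        assert pred.loc["C", "predicted_valence"] == "positive"

    def test_multiple_inhibitory_positive_mbons_predict_negative(self):
        adj = toy_adjacency(
            {("M1", "C"): (5, 5), ("M2", "C"): (5, 5), ("X", "C"): (90, 90)},
            {"M1": ("MBON", "GABA", "positive"), "M2": ("MBON", "Glu", "positive")},
        )
        pred = cn.predict_valence(adj)
        assert pred.loc["C", "predicted_valence"] == "negative"

    def test_below_threshold_input_predicts_none(self):
        adj = toy_adjacency(
            {("MP", "C"): (2, 2), ("MN", "C"): (3, 3), ("X", "C"): (120, 120)},
            {"MP": ("MBON", "ACh", "positive"), "MN": ("MBON", "GABA", "negative")},
        )
        pred = cn.predict_valence(adj, min_side=2, min_sum=4)
        # qualifying fraction 10/250 = 4% < 5% floor
        assert pred.loc["C", "predicted_valence"] == "none"

    def test_unknown_transmitter_excluded_with_warning(self):
        adj = toy_adjacency(
            {("M", "C"): (30, 30)}, {"M": ("MBON", "unknown", "positive")}
        )
        with pytest.warns(UserWarning, match="unknown transmitter"):
            pred = cn.predict_valence(adj)
        assert pred.loc["C", "predicted_valence"] == "none"
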