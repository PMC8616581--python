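"""Connectivity post-processing over hemilateral neuron pairs.

The reconstruction-validation logic operates on homolog (left/right) pairs:
a connection between two pairs is *strong/reliable* when each presynaptic
homolog contributes at least ``min_side`` (3) synapses onto the postsynaptic
pair (ipsi- plus contralateral) and the sum is at least ``min_sum`` (10).
Under a per-contact false-positive rate p, an entirely spurious n-contact
connection occurs at rate p^n, which is what makes the 3/3/10 rule safe.

Downstream of the filter: binary pair-level matrices, a matches-over-
(matches+mismatches) similarity score (Jaccard on the supports),
hierarchical clustering, input fractions by source class, convergence-neuron
classification, and valence prediction from MBON input composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import PairedAdjacency

DEFAULT_FP_RATE = 0.0167
MIN_SIDE = 3
MIN_SUM = 10
VALENCE_THRESHOLD = 0.05
EXCITATORY = {"ACh"}
INHIBITORY = {"GABA", "Glu"}

__all__ = [
    "load_paired_adjacency",
    "strong_connections",
    "false_positive_probability",
    "binary_matrix",
    "similarity",
    "cluster_similarity",
    "input_fractions",
    "classify_neurons",
    "predict_valence",
]


def load_paired_adjacency(adjacency_csv: str | Path, annotations_csv: str | Path) -> PairedAdjacency:
    """Read and validate an adjacency CSV plus a neuron-annotation CSV.

    The adjacency CSV is square (rows presynaptic, columns postsynaptic,
    integer synapse counts); annotations carry id, hemisphere, homolog_id,
    class, transmitter, valence. Unpaired neurons are retained but flagged.
    """
    counts = pd.read_csv(adjacency_csv, index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    annotations = pd.read_csv(annotations_csv, dtype=str).fillna("")
    return PairedAdjacency(counts, annotations)


def _pair_side_counts(adj: PairedAdjacency) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per ordered pair-of-pairs: synapses from the pre-left and pre-right
    neuron onto both postsynaptic homologs (ipsi + contra)."""
    pairs = adj.pairs()
    left_ids = pairs["left"].tolist()
    right_ids = pairs["right"].tolist()
    c = adj.counts
    post = c[left_ids].to_numpy() + c[right_ids].to_numpy()  # onto both homologs
    post = pd.DataFrame(post, index=c.index, columns=pairs.index)
    syn_left = post.loc[left_ids].set_axis(pairs.index, axis=0)
    syn_right = post.loc[right_ids].set_axis(pairs.index, axis=0)
    return pairs, syn_left, syn_right


def strong_connections(
    adj: PairedAdjacency, min_side: int = MIN_SIDE, min_sum: int = MIN_SUM
) -> pd.DataFrame:
    """Pair-level connectivity table with the strong/reliable flag.

    A connection is strong iff the left and right presynaptic homologs each
    contribute >= ``min_side`` synapses (onto both postsynaptic homologs,
    ipsi- and contralateral counted) and the total is >= ``min_sum``.
    Unpaired neurons are excluded (the rule is defined on homolog pairs).
    """
    pairs, syn_left, syn_right = _pair_side_counts(adj)
    rows = []
    for pre in pairs.index:
        sl = syn_left.loc[pre]
        sr = syn_right.loc[pre]
        for post in pairs.index:
            if pre == post:
                continue
            left, right = int(sl[post]), int(sr[post])
            total = left + right
            if total == 0:
                continue
            rows.append(
                {
                    "pre_pair": pre,
                    "post_pair": post,
                    "syn_left": left,
                    "syn_right": right,
                    "total": total,
                    "strong": left >= min_side and right >= min_side and total >= min_sum,
                }
            )
    return pd.DataFrame(
        rows, columns=["pre_pair", "post_pair", "syn_left", "syn_right", "total", "strong"]
    )


def false_positive_probability(n: int, p: float = DEFAULT_FP_RATE) -> tuple[float, float]:
    """Probability that an n-contact connection is entirely spurious: p^n.

    Returns ``(p**n, 1/p**n)``; the reciprocal is the expected number of
    n-contact connections per spurious one.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 0):
        raise ValueError("n must be a non-negative integer")
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    prob = float(p) ** int(n)
    return prob, (np.inf if prob == 0 else 1.0 / prob)


def binary_matrix(strong: pd.DataFrame, pair_ids=None) -> pd.DataFrame:
    """Pair-level 0/1 matrix of strong connections (rows presynaptic)."""
    if pair_ids is None:
        pair_ids = sorted(set(strong["pre_pair"]) | set(strong["post_pair"]))
    mat = pd.DataFrame(0, index=pd.Index(pair_ids), columns=pd.Index(pair_ids), dtype=int)
    for _, row in strong.iterrows():
        if row["strong"]:
            mat.loc[row["pre_pair"], row["post_pair"]] = 1
    return mat


def similarity(binary: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Connectivity-similarity score between pairs: matches / (matches + mismatches).

    A match is a common 1 at the same location in both rows (outputs) or
    columns (inputs); a mismatch a 1 present in only one of them — i.e. the
    Jaccard similarity of the supports. Pairs with empty supports on both
    sides get NaN (undefined).
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    M = binary.to_numpy().astype(bool)
    if axis == "columns":
        M = M.T
    ids = binary.index if axis == "rows" else binary.columns
    inter = (M.astype(int) @ M.astype(int).T).astype(float)
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    return pd.DataFrame(score, index=ids, columns=ids)


def cluster_similarity(sim: pd.DataFrame, linkage: str = "average"):
    """Agglomerative clustering on distance 1 - similarity.

    Rows that are entirely NaN (empty supports) are dropped with a warning.
    Returns ``(leaf_order, linkage_matrix, newick)`` where ``leaf_order`` is
    the list of pair ids in dendrogram order.
    """
    valid = ~sim.isna().all(axis=1)
    if (~valid).any():
        warnings.warn(f"dropping {int((~valid).sum())} pairs with undefined similarity")
    sim = sim.loc[valid, valid]
    if len(sim) < 2:
        raise ValueError("need at least two pairs to cluster")
    dist = 1.0 - sim.to_numpy()
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    order = [sim.index[i] for i in hierarchy.leaves_list(Z)]
    newick = _to_newick(hierarchy.to_tree(Z), list(sim.index))
    return order, Z, newick


def _to_newick(node, labels: list[str]) -> str:
    def rec(nd, parent_dist):
        length = max(parent_dist - nd.dist, 0.0)
        if nd.is_leaf():
            return f"{labels[nd.id]}:{length:.6g}"
        return f"({rec(nd.left, nd.dist)},{rec(nd.right, nd.dist)}):{length:.6g}"

    return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)});"


def input_fractions(adj: PairedAdjacency, pair_id: str, grouping: str = "class") -> pd.Series:
    """Fraction of synaptic input a pair receives from each source group.

    Inputs onto both homologs are summed; ``grouping`` is an annotation
    column ("class" or "transmitter") or "pair" for per-pair fractions.
    Unpaired presynaptic neurons are retained in the totals.
    """
    pairs = adj.pairs()
    if pair_id not in pairs.index:
        raise KeyError(f"unknown pair {pair_id!r}")
    members = [pairs.loc[pair_id, "left"], pairs.loc[pair_id, "right"]]
    incoming = adj.counts[members].sum(axis=1)  # per presynaptic neuron
    total = incoming.sum()
    if total == 0:
        raise ValueError(f"pair {pair_id!r} receives zero input synapses")
    if grouping == "pair":
        ann = adj.annotations
        keys = [
            _pair_key(nid, ann) for nid in incoming.index
        ]
    else:
        keys = adj.annotations.loc[incoming.index, grouping].tolist()
    frac = incoming.groupby(keys).sum() / total
    return frac[frac > 0].sort_values(ascending=False)


def _pair_key(nid: str, ann: pd.DataFrame) -> str:
    mate = ann.loc[nid, "homolog_id"]
    if mate in ("", None):
        return nid
    stem_a, stem_b = nid.rsplit(" ", 1)[0], str(mate).rsplit(" ", 1)[0]
    return stem_a if stem_a == stem_b else min(nid, str(mate))


def classify_neurons(
    adj: PairedAdjacency,
    strong: pd.DataFrame | None = None,
    min_side: int = MIN_SIDE,
    min_sum: int = MIN_SUM,
) -> pd.DataFrame:
    """Classify pairs by their reliable inputs: MB2ON, CN, FBN flag.

    MB2ON: strong connection from >= 1 MBON pair. LHN membership is read
    from the annotations (pathway membership is an input, not computed).
    CN (convergence neuron): reliable MBON input AND reliable LHN input.
    ``kc_input_reliable`` records whether any single KC pair connects with
    >= ``min_side`` synapses from each side — weak (< 3) or asymmetric KC
    input is disregarded and does not make a neuron MBON-like. The FBN flag
    marks pairs with a strong connection onto a dopaminergic (DAN) pair.
    """
    ann = adj.annotations
    if ann["class"].isna().any() or (ann["class"] == "").any():
        raise ValueError("missing class annotations")
    pairs = adj.pairs()
    if strong is None:
        strong = strong_connections(adj, min_side, min_sum)
    strong_only = strong[strong["strong"]]
    cls_of = pairs["class"].to_dict()
    rows = []
    for pid in pairs.index:
        inputs = strong_only[strong_only["post_pair"] == pid]
        outputs = strong_only[strong_only["pre_pair"] == pid]
        in_classes = {cls_of.get(p) for p in inputs["pre_pair"]}
        mb2on = "MBON" in in_classes
        is_lhn = pairs.loc[pid, "class"] == "LHN"
        lhn_input = "LHN" in in_classes
        cn = mb2on and lhn_input
        fbn = any(cls_of.get(p) == "DAN" for p in outputs["post_pair"])
        kc_in = strong.loc[strong["post_pair"] == pid]
        is_kc = np.array([cls_of.get(p) == "KC" for p in kc_in["pre_pair"]], dtype=bool)
        kc_in = kc_in.loc[is_kc]
        kc_reliable = bool(
            ((kc_in["syn_left"] >= min_side) & (kc_in["syn_right"] >= min_side)).any()
        )
        labels = set()
        if mb2on:
            labels.add("MB2ON")
        if is_lhn:
            labels.add("LHN")
        if cn:
            labels.add("CN")
        if fbn:
            labels.add("FBN")
        rows.append(
            {
                "pair_id": pid,
                "class": pairs.loc[pid, "class"],
                "is_mb2on": mb2on,
                "is_lhn": is_lhn,
                "is_cn": cn,
                "fbn_flag": fbn,
                "kc_input_reliable": kc_reliable,
                "labels": ",".join(sorted(labels)),
            }
        )
    return pd.DataFrame(rows).set_index("pair_id")


def predict_valence(
    adj: PairedAdjacency,
    strong: pd.DataFrame | None = None,
    threshold: float = VALENCE_THRESHOLD,
    min_side: int = MIN_SIDE,
    min_sum: int = MIN_SUM,
) -> pd.DataFrame:
    """Predict the valence each pair encodes from its MBON input composition.

    Per pair, the fraction of total input arriving through strong
    connections from MBONs is split by MBON valence x transmitter sign
    (ACh excitatory; GABA/Glu inhibitory). A pair is predicted positive if
    it combines excitatory input from positive-valence MBON(s) with
    inhibitory input from negative-valence MBON(s), or receives inhibitory
    input from >= 2 negative-valence MBONs; predicted negative if it
    receives inhibitory input from >= 2 positive-valence MBONs. The
    qualifying combined input fraction must reach ``threshold`` (5%).
    MBON inputs of unknown transmitter are excluded with a warning.
    """
    pairs = adj.pairs()
    if strong is None:
        strong = strong_connections(adj, min_side, min_sum)
    strong_only = strong[strong["strong"]]
    members = {pid: [pairs.loc[pid, "left"], pairs.loc[pid, "right"]] for pid in pairs.index}
    rows = []
    for pid in pairs.index:
        total_in = int(adj.counts[members[pid]].to_numpy().sum())
        frac = {"exc_pos": 0.0, "inh_pos": 0.0, "exc_neg": 0.0, "inh_neg": 0.0}
        n_mbons = {"exc_pos": 0, "inh_pos": 0, "exc_neg": 0, "inh_neg": 0}
        if total_in > 0:
            inputs = strong_only[strong_only["post_pair"] == pid]
            for _, row in inputs.iterrows():
                src = row["pre_pair"]
                if pairs.loc[src, "class"] != "MBON":
                    continue
                tx = pairs.loc[src, "transmitter"]
                val = pairs.loc[src, "valence"]
                if tx in EXCITATORY:
                    sign = "exc"
                elif tx in INHIBITORY:
                    sign = "inh"
                else:
                    warnings.warn(
                        f"MBON pair {src!r} has unknown transmitter; excluded from valence prediction"
                    )
                    continue
                if val not in ("positive", "negative"):
                    continue
                key = f"{sign}_{'pos' if val == 'positive' else 'neg'}"
                frac[key] += row["total"] / total_in
                n_mbons[key] += 1
        pos_combo = (
            frac["exc_pos"] > 0
            and frac["inh_neg"] > 0
            and (frac["exc_pos"] + frac["inh_neg"]) >= threshold
        )
        pos_multi_inh = n_mbons["inh_neg"] >= 2 and frac["inh_neg"] >= threshold
        neg_multi_inh = n_mbons["inh_pos"] >= 2 and frac["inh_pos"] >= threshold
        positive = pos_combo or pos_multi_inh
        negative = neg_multi_inh
        if positive and negative:
            warnings.warn(f"pair {pid!r} satisfies both valence rules; predicting none")
            pred = "none"
        elif positive:
            pred = "positive"
        elif negative:
            pred = "negative"
        else:
            pred = "none"
        rows.append(
            {
                "pair_id": pid,
                "predicted_valence": pred,
                "frac_exc_pos": frac["exc_pos"],
                "frac_inh_pos": frac["inh_pos"],
                "frac_exc_neg": frac["exc_neg"],
                "frac_inh_neg": frac["inh_neg"],
                "n_inh_pos_mbons": n_mbons["inh_pos"],
                "n_inh_neg_mbons": n_mbons["inh_neg"],
            }
        )
    return pd.DataFrame(rows).set_index("pair_id")
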