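"""Meet/Min crosstalk scoring of cross-context miRNA pairs and the crosstalk
network.

For a miRNA i active in context 1 and a miRNA j active in context 2, each of
five feature dimensions (DE target genes, associated small-molecule drugs,
associated chemicals, enriched pathways, enriched biological processes) is
compared with the Meet/Min (overlap) coefficient

    score(i, j) = |set_i & set_j| / min(|set_i|, |set_j|)

which is 1 for identical sets and 0 for disjoint ones.  A dimension where
either miRNA has an empty set is *undefined* ("no common features") and is
reported with a sentinel, distinct from a genuine zero overlap.  Pairs whose
target-dimension score is zero/undefined, or which have no positive dimension
at all, are filtered out; the surviving pairs form the crosstalk network whose
both-sided miRNAs are the bridging molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a Meet/Min dimension where either set is empty (undefined),
#: deliberately distinct from a genuine 0.0 (nonempty sets, zero overlap).
NO_COMMON_FEATURES = None

DIMENSIONS = ("target", "molecular", "chemical", "pathway", "bp")

SCORE_COLUMNS = [f"score_{d}" for d in DIMENSIONS]


@dataclass
class FeatureSetCollection:
    """Per (miRNA, context) feature sets across the five crosstalk dimensions.

    sets[(mirna, context)] maps dimension name -> frozenset of feature ids.
    A miRNA registered in a context always carries all five dimensions
    (possibly empty).
    """

    sets: dict[tuple[str, str], dict[str, frozenset[str]]] = field(
        default_factory=dict
    )

    def add(
        self,
        mirna: str,
        context: str,
        targets: Iterable[str] = (),
        molecules: Iterable[str] = (),
        chemicals: Iterable[str] = (),
        pathways: Iterable[str] = (),
        bps: Iterable[str] = (),
    ) -> None:
        self.sets[(mirna, context)] = {
            "target": frozenset(targets),
            "molecular": frozenset(molecules),
            "chemical": frozenset(chemicals),
            "pathway": frozenset(pathways),
            "bp": frozenset(bps),
        }

    def mirnas(self, context: str) -> list[str]:
        return sorted(m for m, c in self.sets if c == context)


def meet_min(set_i: Iterable[str], set_j: Iterable[str]):
    """Meet/Min overlap coefficient; NO_COMMON_FEATURES sentinel if a set is empty."""
    a, b = frozenset(set_i), frozenset(set_j)
    if not a or not b:
        logger.debug("meet_min on an empty set: no common features")
        return NO_COMMON_FEATURES
    return len(a & b) / min(len(a), len(b))


def score_all_pairs(
    collection: FeatureSetCollection, ctx1: str = "ctx1", ctx2: str = "ctx2"
) -> pd.DataFrame:
    """Meet/Min scores for every (miRNA in ctx1) x (miRNA in ctx2) pair.

    One row per pair with the five dimension scores (sentinel dimensions are
    NaN in the frame but tracked in matching ``defined_*`` boolean columns);
    sorted descending by score_target, then by the pair ids.
    """
    rows = []
    for m1 in collection.mirnas(ctx1):
        s1 = collection.sets[(m1, ctx1)]
        for m2 in collection.mirnas(ctx2):
            s2 = collection.sets[(m2, ctx2)]
            row: dict[str, object] = {"mirna_ctx1": m1, "mirna_ctx2": m2}
            for dim in DIMENSIONS:
                score = meet_min(s1[dim], s2[dim])
                row[f"score_{dim}"] = (
                    float("nan") if score is NO_COMMON_FEATURES else score
                )
                row[f"defined_{dim}"] = score is not NO_COMMON_FEATURES
            rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["_sort"] = out["score_target"].fillna(-1.0)
        out = (
            out.sort_values(
                ["_sort", "mirna_ctx1", "mirna_ctx2"],
                ascending=[False, True, True],
                kind="mergesort",
            )
            .drop(columns="_sort")
            .reset_index(drop=True)
        )
    return out


def _row_retained(row: pd.Series) -> bool:
    """Filter rule: drop if score_target is 0/undefined or no dimension is > 0."""
    target_ok = bool(row["defined_target"]) and row["score_target"] > 0.0
    any_positive = any(
        bool(row[f"defined_{d}"]) and row[f"score_{d}"] > 0.0 for d in DIMENSIONS
    )
    return target_ok and any_positive


def build_crosstalk_network(rows: pd.DataFrame) -> nx.Graph:
    """Crosstalk network from scored pairs after filtering.

    Nodes are context-namespaced ("ctx1:<mirna>" / "ctx2:<mirna>") with
    ``mirna`` and ``context`` attributes, so a miRNA active in both contexts
    contributes two nodes and its self-pair a proper (non-loop) edge.  Edge
    attributes carry the five scores.
    """
    g = nx.Graph()
    if not len(rows):
        return g
    for _, row in rows.iterrows():
        if not _row_retained(row):
            continue
        u = f"ctx1:{row['mirna_ctx1']}"
        v = f"ctx2:{row['mirna_ctx2']}"
        g.add_node(u, mirna=row["mirna_ctx1"], context="ctx1")
        g.add_node(v, mirna=row["mirna_ctx2"], context="ctx2")
        g.add_edge(u, v, **{c: row[c] for c in SCORE_COLUMNS})
    return g


def identify_bridging(network: nx.Graph) -> list[str]:
    """miRNAs appearing on both context sides of retained crosstalk edges.

    Ordered by descending summed score_target over incident edges (both
    sides), ties broken by miRNA id.
    """
    side: dict[str, set[str]] = {"ctx1": set(), "ctx2": set()}
    weight: dict[str, float] = {}
    for u, v, data in network.edges(data=True):
        for node in (u, v):
            mirna = network.nodes[node]["mirna"]
            side[network.nodes[node]["context"]].add(mirna)
            st = data.get("score_target")
            if st == st:  # not NaN
                weight[mirna] = weight.get(mirna, 0.0) + float(st)
    bridging = side["ctx1"] & side["ctx2"]
    return sorted(bridging, key=lambda m: (-weight.get(m, 0.0), m))


def format_scores(rows: pd.DataFrame, precision: int = 6) -> pd.DataFrame:
    """Report layout: pair ids plus the five scores, fixed decimal format,
    undefined dimensions rendered as 'NA'."""
    out = rows[["mirna_ctx1", "mirna_ctx2"]].copy()
    for col in SCORE_COLUMNS:
        dim = col.removeprefix("score_")
        out[col] = [
            f"{val:.{precision}f}" if defined else "NA"
            for val, defined in zip(rows[col], rows[f"defined_{dim}"])
        ]
    return out
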