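"""Hypergeometric machinery: pmf/upper tail, over-representation analysis, and
miRNA-chemical association screening.

The hypergeometric probability

    P(k; N, M, n) = C(M, k) * C(N - M, n - k) / C(N, n)

is the probability of drawing exactly ``k`` members of a marked subpopulation of
size ``M`` in a draw of ``n`` from a universe of ``N``.  Over-representation of a
term (or a chemical's gene set) in a query set is scored by the upper tail
P(X >= k).  Both are computed in log space via gammaln for numerical stability;
scipy's hypergeom is deliberately not used here (it serves as an independent
cross-check in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from mircrosstalk.diffexpr import bh_adjust
from mircrosstalk.errors import InputError

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's (or one miRNA-chemical pair's) over-representation result.

    N: universe size; M: term members in the universe; n: query size;
    k: overlap; p: upper-tail probability P(X >= k); adjP: BH-adjusted p.
    """

    term_id: str
    N: int
    M: int
    n: int
    k: int
    p: float
    adjP: float = float("nan")


def _check_args(k: int, N: int, M: int, n: int) -> None:
    if not all(int(x) == x for x in (k, N, M, n)):
        raise InputError("hypergeometric arguments must be integers")
    if N < 0 or M < 0 or n < 0:
        raise InputError(f"N, M, n must be nonnegative (got N={N}, M={M}, n={n})")
    if M > N or n > N:
        raise InputError(f"require M <= N and n <= N (got N={N}, M={M}, n={n})")


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def hypergeom_pmf(k: int, N: int, M: int, n: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, M, n), in log space.

    Out-of-support k returns 0.0 rather than raising: the support is
    max(0, n - (N - M)) <= k <= min(M, n).
    """
    _check_args(k, N, M, n)
    if k < max(0, n - (N - M)) or k > min(M, n):
        return 0.0
    return float(
        np.exp(_log_comb(M, k) + _log_comb(N - M, n - k) - _log_comb(N, n))
    )


def hypergeom_tail(k: int, N: int, M: int, n: int) -> float:
    """Upper tail P(X >= k); equals 1 for k at or below the support minimum."""
    _check_args(k, N, M, n)
    lo = max(0, n - (N - M))
    hi = min(M, n)
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    total = sum(hypergeom_pmf(j, N, M, n) for j in range(k, hi + 1))
    return float(min(1.0, total))


def ora(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term's member set in the query.

    Term members and the query are intersected with the universe first; only
    terms overlapping the query (k >= 1) are reported.  BH adjustment is
    applied across the tested terms.  Rows sorted by ascending p then term id.
    """
    universe = frozenset(universe)
    if not universe:
        raise InputError("empty universe")
    query = frozenset(query) & universe
    N, n = len(universe), len(query)
    rows = []
    for term, members in collection.items():
        members = frozenset(members) & universe
        k = len(members & query)
        if k < 1:
            continue
        M = len(members)
        rows.append((term, N, M, n, k, hypergeom_tail(k, N, M, n)))
    out = pd.DataFrame(rows, columns=["term_id", "N", "M", "n", "k", "p"])
    if len(out):
        out["adjP"] = bh_adjust(out["p"].to_numpy())
    else:
        out["adjP"] = pd.Series(dtype=float)
    out = out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    out["significant"] = out["p"] < ALPHA
    return out


def mirna_chemical_assoc(
    chemical_genes: Mapping[str, Iterable[str]],
    mirna_targets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Screen every (miRNA, chemical) pair for target/gene-set over-representation.

    For each pair: k = |targets(miRNA) & genes(chemical)|, M = |targets(miRNA)|,
    n = |genes(chemical)|, N = |universe|; p is the upper hypergeometric tail.
    Pairs with raw p < alpha are flagged ``retained`` (the network edges).
    miRNAs with no targets in the universe are skipped with a log message.
    """
    universe = frozenset(universe)
    if not universe:
        raise InputError("empty universe")
    chem_sets = {c: frozenset(g) & universe for c, g in chemical_genes.items()}
    rows = []
    for mirna, targets in mirna_targets.items():
        tset = frozenset(targets) & universe
        if not tset:
            logger.info("miRNA %s has no targets in the universe; skipped", mirna)
            continue
        for chem, cset in chem_sets.items():
            if not cset:
                continue
            k = len(tset & cset)
            p = hypergeom_tail(k, len(universe), len(tset), len(cset))
            rows.append((mirna, chem, len(universe), len(tset), len(cset), k, p))
    out = pd.DataFrame(
        rows, columns=["mirna", "chemical", "N", "M", "n", "k", "p"]
    )
    if len(out):
        out["adjP"] = bh_adjust(out["p"].to_numpy())
    else:
        out["adjP"] = pd.Series(dtype=float)
    out["retained"] = out["p"] < alpha
    return out.sort_values(["p", "mirna", "chemical"], kind="mergesort").reset_index(
        drop=True
    )
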