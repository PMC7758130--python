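"""Kolmogorov-Smirnov connectivity scoring of tag sets against ranked drug
signatures, and the cross-context drug concordance screen.

A reference signature ranks N features from most up- to most down-regulated
under a drug.  For a tag set of size t with ascending signature positions
V(1..t):

    a  = max_j ( j/t - V(j)/N )
    b  = max_j ( V(j)/N - (j-1)/t )
    KS = a if a > b else -b          (ties resolved to the a branch)

KS is positive when tags cluster near the signature top, negative near the
bottom.  The integrated score S combines the up-tag and down-tag statistics:
S = 0 when KS_up and KS_down share a sign (both nonzero), otherwise
S = KS_up - KS_down; S_norm = S/2 lies in [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mircrosstalk.errors import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedSignature:
    """A drug's ordered feature list (rank 1 = most up-regulated) in one context."""

    drug_id: str
    context_id: str
    ordered_features: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ordered_features) < 2:
            raise InputError("signature must contain at least 2 features")
        if len(set(self.ordered_features)) != len(self.ordered_features):
            raise InputError(f"duplicate features in signature {self.drug_id}")

    @property
    def N(self) -> int:
        return len(self.ordered_features)

    def positions(self, features: Iterable[str]) -> list[int]:
        """1-based signature ranks of the given features, ascending."""
        index = {f: i + 1 for i, f in enumerate(self.ordered_features)}
        out = []
        for f in features:
            if f not in index:
                raise InputError(f"tag feature {f!r} not in signature")
            out.append(index[f])
        return sorted(out)


@dataclass(frozen=True)
class TagSet:
    """An unordered query set of features with an up/down polarity label."""

    features: frozenset[str]
    polarity: str = "up"

    def __post_init__(self) -> None:
        if not self.features:
            raise InputError("empty tag set")
        if self.polarity not in ("up", "down"):
            raise InputError(f"polarity must be 'up' or 'down', got {self.polarity!r}")

    @property
    def t(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class KSResult:
    tag_positions: tuple[int, ...]
    a: float
    b: float
    KS: float


@dataclass(frozen=True)
class ConnectivityResult:
    drug_id: str
    context_id: str
    KS_up: float
    KS_down: float
    S: float

    @property
    def S_norm(self) -> float:
        return self.S / 2.0


def ks_statistic(tags: TagSet, signature: RankedSignature) -> KSResult:
    """Running-maximum KS statistic of a tag set within a ranked signature."""
    v = signature.positions(tags.features)
    t, n = len(v), signature.N
    j = np.arange(1, t + 1)
    varr = np.asarray(v, dtype=float)
    a = float(np.max(j / t - varr / n))
    b = float(np.max(varr / n - (j - 1) / t))
    ks = a if a > b else -b if b > a else a
    return KSResult(tag_positions=tuple(v), a=a, b=b, KS=ks)


def integrate_s(ks_up: float, ks_down: float) -> float:
    """S = 0 when KS_up and KS_down share sign (both nonzero), else KS_up - KS_down."""
    if ks_up * ks_down > 0:
        return 0.0
    return ks_up - ks_down


def connectivity_score(
    up_tags: TagSet, down_tags: TagSet, signature: RankedSignature
) -> ConnectivityResult:
    """Integrated connectivity of disjoint up/down tag sets against one signature."""
    if up_tags.features & down_tags.features:
        raise InputError("up and down tag sets overlap")
    ks_up = ks_statistic(up_tags, signature).KS
    ks_down = ks_statistic(down_tags, signature).KS
    return ConnectivityResult(
        drug_id=signature.drug_id,
        context_id=signature.context_id,
        KS_up=ks_up,
        KS_down=ks_down,
        S=integrate_s(ks_up, ks_down),
    )


def classify_concordance(s_ctx1: float, s_ctx2: float) -> str:
    """'concordant' if both context scores share a nonzero sign, 'discordant'
    if signs oppose, 'null' when either is zero."""
    if s_ctx1 == 0.0 or s_ctx2 == 0.0:
        return "null"
    return "concordant" if (s_ctx1 > 0) == (s_ctx2 > 0) else "discordant"


def screen_drugs(
    tags_by_context: Mapping[str, tuple[TagSet, TagSet]],
    signatures: Sequence[RankedSignature],
) -> pd.DataFrame:
    """Cross-context drug screen.

    tags_by_context maps context id -> (up TagSet, down TagSet).  Drugs with a
    signature in every context are scored per context (S_norm reported as the
    'enrichment') and classified by sign concordance across the two contexts;
    drugs missing a context are excluded with a log message.
    """
    contexts = list(tags_by_context)
    if len(contexts) != 2:
        raise InputError("drug screen requires exactly two contexts")
    by_drug: dict[str, dict[str, RankedSignature]] = {}
    for sig in signatures:
        by_drug.setdefault(sig.drug_id, {})[sig.context_id] = sig
    rows = []
    for drug in sorted(by_drug):
        sigs = by_drug[drug]
        if set(sigs) != set(contexts):
            logger.info("drug %s lacks a signature in some context; excluded", drug)
            continue
        res = {
            ctx: connectivity_score(*tags_by_context[ctx], sigs[ctx])
            for ctx in contexts
        }
        r1, r2 = res[contexts[0]], res[contexts[1]]
        rows.append(
            {
                "drug": drug,
                "enrichment_ctx1": r1.S_norm,
                "enrichment_ctx2": r2.S_norm,
                "KS_up_ctx1": r1.KS_up,
                "KS_down_ctx1": r1.KS_down,
                "KS_up_ctx2": r2.KS_up,
                "KS_down_ctx2": r2.KS_down,
                "concordance": classify_concordance(r1.S_norm, r2.S_norm),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug",
            "enrichment_ctx1",
            "enrichment_ctx2",
            "KS_up_ctx1",
            "KS_down_ctx1",
            "KS_up_ctx2",
            "KS_down_ctx2",
            "concordance",
        ],
    )
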