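"""Degree-gated rank-threshold classification of essential lncRNAs.

Every scoreable lncRNA (non-dummy) is ranked, descending, by each of the
four centralities and by the sequence score; ranks are 1-based over the
scoreable-lncRNA universe of size N (protein nodes and dummy lncRNAs are
never ranked or called). A lncRNA whose raw degree s_i on the full
heterogeneous graph reaches the gate z is judged on the centrality branch:
it is called essential iff every configured centrality's indicator fires,
where an indicator fires iff rank/N < k/100 (strict). Below the gate the
sequence branch applies the same rank test with threshold t to the GIC
ranking. An empty centrality subset routes every lncRNA to the sequence
branch (pure GIC mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import pandas as pd

from .errors import ConfigError, MissingScoreError
from .gic import GICResult
from .network import LPPINetwork

#: Centrality measure names, in canonical order.
MEASURES = ("BC", "CC", "DC", "EC")

_MEASURE_COLUMN = {"BC": "bc", "CC": "cc", "DC": "dc", "EC": "ec"}


@dataclass(frozen=True)
class SGIIParams:
    """Decision-rule parameters.

    z : degree gate (raw degree, full graph); k, t : rank thresholds in
    percent for the centrality and GIC branches; centrality_subset : which
    indicator products form the centrality-branch rule (empty = GIC-only).
    """

    z: int = 15
    k: float = 5.0
    t: float = 9.0
    centrality_subset: tuple[str, ...] = MEASURES
    species: str = "mouse"

    def __post_init__(self):
        if self.z < 0:
            raise ConfigError(f"degree gate z must be >= 0, got {self.z}")
        for name, val in (("k", self.k), ("t", self.t)):
            if not (0 < val <= 100):
                raise ConfigError(f"threshold {name} must be in (0, 100], got {val}")
        bad = [m for m in self.centrality_subset if m not in MEASURES]
        if bad:
            raise ConfigError(f"unknown centrality measure(s): {bad}")


#: Published parameter presets.
MOUSE_PARAMS = SGIIParams(z=15, k=5.0, t=9.0, species="mouse")
HUMAN_PARAMS = SGIIParams(z=5, k=20.0, t=5.0, species="human")


def configure_subset(params: SGIIParams, names) -> SGIIParams:
    """Return params updated to use only the named centrality indicators.

    Names are deduplicated and put in canonical (BC, CC, DC, EC) order; an
    empty list selects pure-GIC mode, in which every scoreable lncRNA is
    judged on the GIC branch regardless of degree.
    """
    names = list(names)
    bad = [m for m in names if m not in MEASURES]
    if bad:
        raise ConfigError(f"unknown centrality measure(s): {bad}; valid: {MEASURES}")
    subset = tuple(m for m in MEASURES if m in names)
    return replace(params, centrality_subset=subset)


def rank_descending(scores: Mapping[str, float]) -> dict[str, int]:
    """1-based descending ranks; ties broken by lexicographic id."""
    if not scores:
        raise ConfigError("cannot rank an empty score map")
    for node, value in scores.items():
        if not math.isfinite(value):
            raise ConfigError(f"non-finite score for {node!r}: {value!r}")
    ordered = sorted(scores, key=lambda v: (-scores[v], v))
    return {node: i for i, node in enumerate(ordered, start=1)}


def indicator(rank: int, n: int, threshold_percent: float) -> int:
    """1 iff rank/N < threshold%/100, strictly; else 0."""
    return int(rank / n < threshold_percent / 100.0)


@dataclass
class RankTable:
    """Per-lncRNA ranks r_b, r_c, r_d, r_e, r_g over the scoreable universe."""

    ranks: pd.DataFrame  # columns r_b, r_c, r_d, r_e, r_g, indexed by lncRNA id
    n: int = field(default=0)

    def __post_init__(self):
        if self.n == 0:
            self.n = len(self.ranks)


def build_rank_table(
    centralities: pd.DataFrame,
    gic_results: Mapping[str, GICResult],
    scoreable: list[str],
) -> RankTable:
    """Rank the scoreable lncRNAs by each centrality and by the GIC logit.

    The GIC ranking uses theta rather than g: the logistic is monotone so
    the order is identical, but theta keeps resolution where g saturates
    at 1.0 in floating point.
    """
    missing_c = [v for v in scoreable if v not in centralities.index]
    if missing_c:
        raise MissingScoreError(f"no centrality scores for: {missing_c[:5]}")
    missing_g = [v for v in scoreable if v not in gic_results]
    if missing_g:
        raise MissingScoreError(f"no GIC score for: {missing_g[:5]}")

    frame = pd.DataFrame(index=pd.Index(sorted(scoreable), name="node"))
    for measure, col in _MEASURE_COLUMN.items():
        values = {v: float(centralities.at[v, col]) for v in scoreable}
        ranks = rank_descending(values)
        frame[f"r_{measure[0].lower()}"] = [ranks[v] for v in frame.index]
    gic_values = {v: gic_results[v].theta for v in scoreable}
    gic_ranks = rank_descending(gic_values)
    frame["r_g"] = [gic_ranks[v] for v in frame.index]
    return RankTable(ranks=frame)


@dataclass(frozen=True)
class SGIICall:
    """One lncRNA's essentiality call and the evidence behind it."""

    node: str
    degree: int
    branch: str  # "centrality" or "GIC"
    indicators: dict  # I_b, I_c, I_d, I_e, I_g (all five, for reporting)
    essential: bool


def classify(
    network: LPPINetwork,
    centralities: pd.DataFrame,
    gic_results: Mapping[str, GICResult],
    params: SGIIParams,
) -> dict[str, SGIICall]:
    """Apply the degree-gated decision rule to every scoreable lncRNA."""
    scoreable = network.scoreable_lncrnas
    if not scoreable:
        raise MissingScoreError("network has no scoreable lncRNAs")
    table = build_rank_table(centralities, gic_results, scoreable)
    n = table.n
    calls: dict[str, SGIICall] = {}
    for node in table.ranks.index:
        row = table.ranks.loc[node]
        inds = {
            f"I_{m[0].lower()}": indicator(int(row[f"r_{m[0].lower()}"]), n, params.k)
            for m in MEASURES
        }
        inds["I_g"] = indicator(int(row["r_g"]), n, params.t)
        degree = network.degree(node)
        if params.centrality_subset and degree >= params.z:
            branch = "centrality"
            product = 1
            for m in params.centrality_subset:
                product *= inds[f"I_{m[0].lower()}"]
            essential = product == 1
        else:
            branch = "GIC"
            essential = inds["I_g"] == 1
        calls[node] = SGIICall(
            node=node, degree=degree, branch=branch, indicators=inds,
            essential=essential,
        )
    return calls


def calls_frame(calls: Mapping[str, SGIICall], table: RankTable | None = None) -> pd.DataFrame:
    """Tabulate calls for TSV export."""
    rows = []
    for node in sorted(calls):
        c = calls[node]
        row = {"node": node, "degree": c.degree, "branch": c.branch}
        row.update(c.indicators)
        row["essential"] = int(c.essential)
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("node")
    if table is not None:
        frame = table.ranks.join(frame, how="right")
    return frame
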