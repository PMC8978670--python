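"""Evaluation statistics and parameter calibration.

Predictions are summarized by three statistics: sensitivity s = n_t / n_+
(known essentials called essential over all known essentials), false
positive rate r = n_f / n_- (unknown-status lncRNAs called essential over
all unknown-status lncRNAs), and the Fisher's-exact-test score f = -log10 p,
where p is the one-sided (enrichment, upper-tail hypergeometric) p-value of
the 2x2 table [[n_t, n_+ - n_t], [n_f, n_- - n_f]]. Because the known
essential set is tiny, s and r are descriptive; f is the headline quality
measure and the calibration objective.

Calibration grid-searches (z, k, t), maximizing f; ties break toward the
smallest z, then k, then t.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigError
from .gic import GICResult
from .network import LPPINetwork
from .sgii_core import SGIICall, SGIIParams, classify

logger = logging.getLogger(__name__)


def fisher_score(n_t: int, n_plus: int, n_f: int, n_minus: int) -> tuple[float, float]:
    """One-sided Fisher's exact p for enrichment of essentials among calls.

    The p-value is the upper tail of the hypergeometric distribution: the
    probability of drawing >= n_t known essentials when n_t + n_f calls are
    drawn from a universe of n_+ + n_- lncRNAs containing n_+ essentials.
    Returns ``(p, f)`` with f = -log10 p.
    """
    if not (0 <= n_t <= n_plus):
        raise ConfigError(f"need 0 <= n_t <= n_plus, got n_t={n_t}, n_plus={n_plus}")
    if not (0 <= n_f <= n_minus):
        raise ConfigError(f"need 0 <= n_f <= n_minus, got n_f={n_f}, n_minus={n_minus}")
    if n_plus + n_minus == 0:
        raise ConfigError("empty universe: n_plus + n_minus must be positive")
    total = n_plus + n_minus
    drawn = n_t + n_f
    p = float(hypergeom.sf(n_t - 1, total, n_plus, drawn))
    p = min(max(p, 5e-324), 1.0)  # guard the log against rounding overshoot
    return p, -math.log10(p)


@dataclass(frozen=True)
class EvaluationResult:
    """Counts and the three summary statistics for one parameter setting."""

    n_t: int
    n_plus: int
    n_f: int
    n_minus: int
    sensitivity: float
    fpr: float
    p_value: float
    fisher: float


def evaluate_calls(
    calls: Mapping[str, SGIICall],
    labels: Iterable[str],
    universe: Iterable[str],
) -> EvaluationResult:
    """Score a set of calls against known-essential labels.

    ``universe`` is the scoreable-lncRNA set; labels outside it are dropped
    with a warning (they were unscoreable, so no call exists for them).
    """
    universe = set(universe)
    if not universe:
        raise ConfigError("empty evaluation universe")
    labels = set(labels)
    dropped = labels - universe
    if dropped:
        logger.warning(
            "%d label(s) are not in the scoreable universe and were dropped: %s",
            len(dropped), sorted(dropped)[:5],
        )
        labels &= universe
    called = {v for v, c in calls.items() if c.essential and v in universe}
    n_plus = len(labels)
    n_minus = len(universe) - n_plus
    n_t = len(called & labels)
    n_f = len(called - labels)
    sensitivity = n_t / n_plus if n_plus else 0.0
    fpr = n_f / n_minus if n_minus else 0.0
    p, f = fisher_score(n_t, n_plus, n_f, n_minus)
    return EvaluationResult(
        n_t=n_t, n_plus=n_plus, n_f=n_f, n_minus=n_minus,
        sensitivity=sensitivity, fpr=fpr, p_value=p, fisher=f,
    )


@dataclass
class CalibrationGrid:
    """Full grid-search record and the f-maximizing combination."""

    table: pd.DataFrame  # columns z, k, t, n_t, n_f, sensitivity, fpr, p, fisher
    best_params: SGIIParams
    best_result: EvaluationResult


def calibrate(
    network: LPPINetwork,
    centralities: pd.DataFrame,
    gic_results: Mapping[str, GICResult],
    labels: Iterable[str],
    z_values: Sequence[int],
    k_values: Sequence[float],
    t_values: Sequence[float],
    subset: tuple[str, ...] = ("BC", "CC", "DC", "EC"),
    species: str = "mouse",
) -> CalibrationGrid:
    """Evaluate every (z, k, t) cell and report the f-maximizing one.

    Ties on f break deterministically toward the smallest z, then k, then t
    (the iteration order below, combined with a strict improvement test).
    """
    if not (z_values and k_values and t_values):
        raise ConfigError("all three calibration grids must be non-empty")
    labels = set(labels)
    universe = set(network.scoreable_lncrnas)
    rows = []
    best: tuple[SGIIParams, EvaluationResult] | None = None
    for z in sorted(z_values):
        for k in sorted(k_values):
            for t in sorted(t_values):
                params = SGIIParams(
                    z=int(z), k=float(k), t=float(t),
                    centrality_subset=subset, species=species,
                )
                calls = classify(network, centralities, gic_results, params)
                res = evaluate_calls(calls, labels, universe)
                rows.append({
                    "z": int(z), "k": float(k), "t": float(t),
                    "n_t": res.n_t, "n_f": res.n_f,
                    "sensitivity": res.sensitivity, "fpr": res.fpr,
                    "p": res.p_value, "fisher": res.fisher,
                })
                if best is None or res.fisher > best[1].fisher:
                    best = (params, res)
    table = pd.DataFrame(rows)
    logger.info(
        "calibration over %d cells: best f=%.4f at z=%d k=%g t=%g",
        len(rows), best[1].fisher, best[0].z, best[0].k, best[0].t,
    )
    return CalibrationGrid(table=table, best_params=best[0], best_result=best[1])


def read_labels(path) -> set[str]:
    """Read a known-essential label file: one id per line, ``#`` comments."""
    labels: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped and not stripped.startswith("#"):
                labels.add(stripped)
    return labels
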