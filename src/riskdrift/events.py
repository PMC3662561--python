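"""Maximum-likelihood inference of independent differentiation events.

A risk shift arising *de novo* on one branch is inherited by every branch
below it, so a single ancestral event "explains" its whole subtree.  Given
the vector ``P`` of per-branch drift-null probabilities, the likelihood of
a candidate event set is the product of ``P`` over the branches the events
do *not* explain (explained branches contribute nothing: their deviations
are accounted for).  The best set of ``y`` events maximises

    l_y = sum over unexplained branches of ln P(branch)

over all admissible y-subsets (no event nested inside another event's
subtree).  The number of events is chosen by nested likelihood-ratio
tests: ``2 (l_n - l_{n-1}) ~ chi-square(1)``, stepping up from n = 2 and
stopping at the first non-significant improvement.

The search is an exhaustive enumeration — exact, and fast for the tree
sizes this package targets (tens of branches, a handful of events); the
cost grows combinatorially in ``max_events``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .tree import PopulationTree

__all__ = [
    "explained_set",
    "model_log_likelihood",
    "best_event_set",
    "lrt_event_count",
    "infer_events",
    "EventModel",
    "EventInferenceResults",
]


def explained_set(tree: PopulationTree, events: Sequence[str]) -> frozenset[str]:
    """Branches whose deviation the events account for.

    An event explains its own branch and, through inheritance, every branch
    descending from it.
    """
    out: set[str] = set()
    for z in events:
        out.add(z)
        out |= tree.descendant_branches(z)
    return frozenset(out)


def model_log_likelihood(
    p_vector: Mapping[str, float], tree: PopulationTree, events: Sequence[str]
) -> float:
    """Log-likelihood of an event set: sum of ln P over unexplained branches."""
    for z in events:
        if z not in tree:
            raise KeyError(f"event branch {z!r} not in tree")
    explained = explained_set(tree, events)
    total = 0.0
    for branch, p in p_vector.items():
        if branch in explained:
            continue
        if not 0 < p <= 1:
            raise ValueError(f"branch probability out of (0, 1] for {branch!r}")
        total += float(np.log(p))
    return total


def _admissible(tree: PopulationTree, events: tuple[str, ...]) -> bool:
    return not any(
        a != b and tree.is_descendant(a, of=b) for a in events for b in events
    )


def best_event_set(
    p_vector: Mapping[str, float],
    tree: PopulationTree,
    y: int,
    allow_nested: bool = False,
) -> "EventModel":
    """Exhaustively find the y-event set maximising the log-likelihood.

    Candidate branches are the keys of ``p_vector``.  Unless
    ``allow_nested`` is set, sets placing one event inside another event's
    subtree are inadmissible (a nested event explains nothing extra).
    Ties are broken toward the set explaining fewer branches, then
    lexicographically.
    """
    if y < 0:
        raise ValueError("y must be >= 0")
    candidates = sorted(p_vector)
    best: tuple[float, int, tuple[str, ...]] | None = None
    found = False
    for events in combinations(candidates, y):
        if not allow_nested and not _admissible(tree, events):
            continue
        found = True
        ll = model_log_likelihood(p_vector, tree, events)
        n_explained = len(explained_set(tree, events))
        key = (-ll, n_explained, events)
        if best is None or key < best:
            best = key
    if not found:
        raise ValueError(
            f"no admissible set of {y} events among {len(candidates)} branches"
        )
    ll, n_explained, events = -best[0], best[1], best[2]
    return EventModel(events=events, y=y, log_likelihood=ll)


@dataclass(frozen=True)
class EventModel:
    """One candidate event configuration and its log-likelihood."""

    events: tuple[str, ...]
    y: int
    log_likelihood: float


def lrt_event_count(
    log_likelihoods: Sequence[float], alpha: float = 0.05
) -> tuple[int, dict[int, float]]:
    """Choose the number of events by nested chi-square(1) LRTs.

    ``log_likelihoods[n-1]`` is the best l_n for n = 1..max.  For each n >=
    2 the statistic ``2 (l_n - l_{n-1})`` is referred to the upper tail of
    chi-square with one degree of freedom.  Stepping up from n = 2, the
    chosen count is the last n whose improvement is significant at
    ``alpha``; the first non-significant step stops the search.
    """
    ll = list(log_likelihoods)
    if not ll:
        raise ValueError("need at least l_1")
    pvals: dict[int, float] = {}
    chosen = 1
    stopped = False
    for n in range(2, len(ll) + 1):
        if ll[n - 1] < ll[n - 2] - 1e-9:
            raise ValueError(
                f"log-likelihood decreased from {n - 1} to {n} events; "
                "the search is broken"
            )
        stat = 2.0 * (ll[n - 1] - ll[n - 2])
        pvals[n] = float(stats.chi2.sf(stat, df=1))
        if not stopped and pvals[n] < alpha:
            chosen = n
        else:
            stopped = True
    return chosen, pvals


@dataclass
class EventInferenceResults:
    """Fitted event models for y = 1..max and the LRT-selected count."""

    models: dict[int, EventModel]
    lrt_pvalues: dict[int, float]
    chosen_n: int
    alpha: float

    @property
    def chosen_model(self) -> EventModel:
        return self.models[self.chosen_n]

    @property
    def events(self) -> tuple[str, ...]:
        return self.chosen_model.events

    def log_likelihoods(self) -> list[float]:
        return [self.models[n].log_likelihood for n in sorted(self.models)]

    def summary(self) -> str:
        lines = [
            "Independent differentiation events (maximum likelihood)",
            f"chosen number of events: {self.chosen_n} "
            f"(LRT threshold alpha = {self.alpha})",
            "",
            f"{'n':>3} {'log-likelihood':>15} {'p (n vs n-1)':>14}  events",
        ]
        for n in sorted(self.models):
            m = self.models[n]
            p = self.lrt_pvalues.get(n)
            p_str = f"{p:.3g}" if p is not None else "-"
            ev = "; ".join(e if len(e) <= 30 else e[:27] + "..." for e in m.events)
            lines.append(f"{n:>3} {m.log_likelihood:>15.4f} {p_str:>14}  {ev}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "chosen_n": self.chosen_n,
            "alpha": self.alpha,
            "events": list(self.events),
            "log_likelihoods": {
                n: self.models[n].log_likelihood for n in sorted(self.models)
            },
            "lrt_pvalues": {n: p for n, p in sorted(self.lrt_pvalues.items())},
            "models": {
                n: list(self.models[n].events) for n in sorted(self.models)
            },
        }


def infer_events(
    p_vector: Mapping[str, float],
    tree: PopulationTree,
    max_events: int = 8,
    alpha: float = 0.05,
    allow_nested: bool = False,
) -> EventInferenceResults:
    """Fit best event sets for y = 1..max_events and select y by LRT.

    Stops enumerating early once the LRT improvement is non-significant
    (one extra model is fitted past the chosen count to establish the
    stopping p-value).
    """
    models: dict[int, EventModel] = {}
    lls: list[float] = []
    pvals: dict[int, float] = {}
    for y in range(1, max_events + 1):
        try:
            m = best_event_set(p_vector, tree, y, allow_nested=allow_nested)
        except ValueError:
            break  # no admissible set that large
        if lls and m.log_likelihood < lls[-1] - 1e-9:
            # happens when the best smaller set already explains every
            # branch and no admissible superset keeps it: no improvement
            # is possible, so the step is maximally non-significant
            pvals[y] = 1.0
            break
        models[y] = m
        lls.append(m.log_likelihood)
        if y >= 2:
            stat = 2.0 * (lls[-1] - lls[-2])
            pvals[y] = float(stats.chi2.sf(stat, df=1))
            if pvals[y] >= alpha:
                break
    if not models:
        raise ValueError("no admissible single-event model on this tree")
    chosen = 1
    for n in range(2, max(models) + 1):
        if pvals.get(n, 1.0) < alpha:
            chosen = n
        else:
            break
    return EventInferenceResults(
        models=models, lrt_pvalues=pvals, chosen_n=chosen, alpha=alpha
    )
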