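"""Greedy incremental signal-selection driver.

Round I trains single-signal detectors on the physiologically
self-sufficient candidates {Thor, DHR, Snore} (position and wake/sleep
carry no arousal signature on their own).  Every later round augments
the best combination so far with each unused signal, trains one model
per candidate, ranks them by mean recordwise event-based F1, and keeps
the winner.  Two schedules are provided: ``greedy`` (pure best-first,
run to pool exhaustion or an optional no-improvement stop) and ``paper``
(the published study path: round III jointly advances the three best
pairs and explores the 2-subsets of their partners plus Pos, and rounds
IV–V add one signal each, never Pos_chg — 16 combinations in total).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

__all__ = [
    "SIGNAL_POOL",
    "ROUND_ONE_CANDIDATES",
    "SelectionState",
    "propose_candidates",
    "replicate_round3_schedule",
    "run_round",
    "run_incremental",
    "stub_train_eval",
]

SIGNAL_POOL = ("Thor", "DHR", "Snore", "Pos", "Pos_chg", "WS")
ROUND_ONE_CANDIDATES = ("Thor", "DHR", "Snore")


@dataclass
class SelectionState:
    """Progress of one incremental run."""

    signal_pool: tuple[str, ...] = SIGNAL_POOL
    round_index: int = 0
    best_combo: frozenset[str] | None = None
    best_score: float = float("-inf")
    evaluated: dict[frozenset, float] = field(default_factory=dict)
    reports: dict[frozenset, object] = field(default_factory=dict)
    failures: dict[frozenset, str] = field(default_factory=dict)
    selection_path: list[frozenset] = field(default_factory=list)
    # combos flagged as jointly advancing out of the last round (paper mode)
    advancing: list[frozenset] = field(default_factory=list)

    def unused_signals(self) -> list[str]:
        used = self.best_combo or frozenset()
        return [s for s in self.signal_pool if s not in used]


def combo_seed(combo: frozenset[str], master_seed: int) -> int:
    """Stable per-candidate seed: master seed mixed with a combo hash."""
    key = ",".join(sorted(combo)).encode()
    return (master_seed * 1_000_003 + zlib.crc32(key)) % (2**31)


def propose_candidates(state: SelectionState) -> list[frozenset]:
    """Candidate combinations for the next round.

    Round I: the single-signal candidates present in the pool.  Later
    rounds: the best combination plus each unused pool signal.  Combos
    already evaluated are never proposed again; an empty list signals
    termination.
    """
    if state.round_index == 0:
        cands = [
            frozenset([s]) for s in ROUND_ONE_CANDIDATES if s in state.signal_pool
        ]
    else:
        if state.best_combo is None:
            raise ValueError("best_combo undefined after round I")
        cands = [
            state.best_combo | {s} for s in state.unused_signals()
        ]
    return [c for c in cands if c not in state.evaluated]


def replicate_round3_schedule(state: SelectionState) -> list[frozenset]:
    """Round-III candidates when several round-II pairs jointly advance.

    The base signal is the round-I winner; the candidate triples are the
    base joined with every 2-subset of the advancing pairs' partner
    signals plus Pos.  With three advancing partners this yields the six
    triples of the published schedule.
    """
    if not state.advancing:
        raise ValueError("no advancing combos recorded for the multi-advance round")
    base = state.selection_path[0]
    partners = set()
    for combo in state.advancing:
        partners |= combo - base
    if not partners:
        raise ValueError("advancing combos contribute no partner signals")
    partners.add("Pos")
    cands = [
        base | set(pair) for pair in itertools.combinations(sorted(partners), 2)
    ]
    return [c for c in cands if c not in state.evaluated]


def _call_train_eval(train_eval_fn, combo: frozenset, seed: int):
    out = train_eval_fn(combo, seed)
    if isinstance(out, tuple):
        return float(out[0]), out[1]
    return float(out), None


def run_round(
    candidates: list[frozenset],
    train_eval_fn,
    state: SelectionState,
    master_seed: int = 0,
) -> tuple[frozenset | None, dict[frozenset, float]]:
    """Train/evaluate one candidate per combination; rank by score.

    ``train_eval_fn(combo, seed)`` returns a score (mean recordwise
    event-based F1) or a ``(score, report)`` tuple.  A candidate whose
    training raises is recorded in ``state.failures`` and skipped.
    Candidates are processed in a canonical order so the winner does not
    depend on the caller's list ordering; exact score ties break toward
    the smaller combination in lexicographic order.
    """
    if not candidates:
        raise ValueError("run_round needs at least one candidate")
    scores: dict[frozenset, float] = {}
    for combo in sorted(candidates, key=lambda c: sorted(c)):
        seed = combo_seed(combo, master_seed)
        try:
            score, report = _call_train_eval(train_eval_fn, combo, seed)
        except Exception as exc:  # candidate failure must not kill the run
            state.failures[combo] = repr(exc)
            continue
        scores[combo] = score
        state.evaluated[combo] = score
        if report is not None:
            state.reports[combo] = report
    if not scores:
        return None, scores
    best = max(sorted(scores, key=lambda c: sorted(c)), key=lambda c: scores[c])
    return best, scores


def run_incremental(
    train_eval_fn,
    schedule: str = "greedy",
    seed: int = 0,
    signal_pool: tuple[str, ...] = SIGNAL_POOL,
    stop_on_no_improvement: bool = False,
    n_advance: int = 3,
    max_rounds: int | None = None,
) -> SelectionState:
    """Execute the incremental analysis until exhaustion (or no improvement).

    ``schedule="paper"`` reproduces the published 16-combination path:
    the three best round-II pairs advance jointly into the multi-advance
    round III, and rounds IV and V add one signal each from the priority
    order Snore, DHR, WS, Pos (Pos_chg is never added after round II).
    """
    if schedule not in ("greedy", "paper"):
        raise ValueError("schedule must be 'greedy' or 'paper'")
    state = SelectionState(signal_pool=tuple(signal_pool))
    prev_best = float("-inf")

    while True:
        if max_rounds is not None and state.round_index >= max_rounds:
            break
        if schedule == "paper" and state.round_index == 2:
            candidates = replicate_round3_schedule(state)
        elif schedule == "paper" and state.round_index >= 3:
            order = [s for s in ("Snore", "DHR", "WS", "Pos") if s in state.signal_pool]
            unused = [s for s in order if s not in state.best_combo]
            candidates = (
                [state.best_combo | {unused[0]}] if unused else []
            )
            candidates = [c for c in candidates if c not in state.evaluated]
        else:
            candidates = propose_candidates(state)
        if not candidates:
            break

        best, scores = run_round(candidates, train_eval_fn, state, master_seed=seed)
        if best is None:
            break
        state.round_index += 1
        round_best_score = scores[best]
        if schedule == "paper" and state.round_index == 2:
            ranked = sorted(scores, key=lambda c: (-scores[c], sorted(c)))
            state.advancing = ranked[:n_advance]
        if stop_on_no_improvement and round_best_score <= prev_best:
            break
        state.best_combo = best
        state.best_score = round_best_score
        state.selection_path.append(best)
        prev_best = max(prev_best, round_best_score)

    return state


def stub_train_eval(score_table: dict[frozenset, float] | None = None):
    """A deterministic training stub for schedule enumeration and dry runs.

    Scores come from ``score_table`` when given; otherwise from a stable
    hash of the combination, so runs are reproducible without training.
    """

    def fn(combo: frozenset, seed: int) -> float:
        if score_table is not None and combo in score_table:
            return score_table[combo]
        key = ",".join(sorted(combo)).encode()
        return (zlib.crc32(key) % 10_000) / 10_000.0

    return fn
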