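"""Microstate syntax: observed vs occurrence-expected transition proportions.

Transitions are events between successive runs (splice boundaries break
adjacency, so no transition is counted across a splice). For each ordered
class pair (a, b), a != b:

* observed(a, b)  = count(a -> b) / count(a -> anything)
* expected(a, b)  = n_b / (N - n_a)

where n_c is the total run count of class c and N the total number of
runs — the proportion expected if successors were drawn purely according
to class occurrence frequencies (ignoring only the impossibility of
self-succession). The deviation matrix observed - expected is the
occurrence-corrected transition statistic; its C->D and D->C cells are the
quantities of primary interest.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    DegenerateDataError,
    ParameterError,
    Segmentation,
    TransitionStats,
)
from .backfitting import extract_runs


def run_sequence(seg: Segmentation) -> list[np.ndarray]:
    """Per spliced block, the temporally ordered run classes.

    Returns one integer array per block; adjacency (hence transitions) only
    exists within a block. Raises if fewer than 2 runs exist overall.
    """
    runs = extract_runs(seg)
    if len(runs) < 2:
        raise DegenerateDataError("need at least 2 runs for a transition")
    bounds = [0] + sorted(seg.splice_boundaries) + [seg.n_samples]
    blocks = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        in_block = (runs["start"] >= lo) & (runs["start"] < hi)
        seq = runs.loc[in_block].sort_values("start")["class_index"].to_numpy()
        if seq.size:
            blocks.append(seq)
    return blocks


def transition_counts(blocks: list[np.ndarray], k: int) -> np.ndarray:
    """k x k matrix of a->b adjacency counts (diagonal structurally zero)."""
    counts = np.zeros((k, k), dtype=int)
    for seq in blocks:
        if seq.size >= 2:
            np.add.at(counts, (seq[:-1], seq[1:]), 1)
    return counts


def observed_matrix(counts: np.ndarray) -> np.ndarray:
    """Row-normalized transition proportions; rows with no exits are NaN."""
    exits = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = counts / exits
    obs[exits.ravel() == 0, :] = np.nan
    return obs


def expected_matrix(blocks: list[np.ndarray], k: int) -> np.ndarray:
    """Occurrence-based expected proportions: expected(a,b) = n_b / (N - n_a)."""
    n_runs = np.zeros(k)
    for seq in blocks:
        for c in seq:
            n_runs[c] += 1
    total = n_runs.sum()
    exp = np.empty((k, k))
    for a in range(k):
        denom = total - n_runs[a]
        if denom <= 0:
            exp[a, :] = np.nan
            continue
        exp[a, :] = n_runs / denom
        exp[a, a] = 0.0
    return exp


def transition_stats(seg: Segmentation) -> TransitionStats:
    """Observed, expected and deviation matrices for one segmentation."""
    k = len(seg.class_names)
    blocks = run_sequence(seg)
    counts = transition_counts(blocks, k)
    obs = observed_matrix(counts)
    exp = expected_matrix(blocks, k)
    dev = obs - exp
    return TransitionStats(classes=list(seg.class_names), counts=counts,
                           observed=obs, expected=exp, deviation=dev)


def transition_stats_from_runs(run_classes, k: int,
                               class_names: list[str]) -> TransitionStats:
    """Same computation starting from explicit run-class sequences.

    ``run_classes`` is a single sequence or a list of per-block sequences.
    """
    if len(run_classes) and np.isscalar(run_classes[0]):
        blocks = [np.asarray(run_classes, dtype=int)]
    else:
        blocks = [np.asarray(b, dtype=int) for b in run_classes]
    if sum(b.size for b in blocks) < 2:
        raise DegenerateDataError("need at least 2 runs for a transition")
    if len(class_names) != k:
        raise ParameterError("class_names length must equal k")
    counts = transition_counts(blocks, k)
    obs = observed_matrix(counts)
    exp = expected_matrix(blocks, k)
    return TransitionStats(classes=list(class_names), counts=counts,
                           observed=obs, expected=exp, deviation=obs - exp)


def expected_matrix_coverage(seg: Segmentation) -> np.ndarray:
    """Alternative expectation using time coverage instead of run counts.

    expected(a,b) = coverage_b / (sum_{c != a} coverage_c). Provided for
    comparison with the count-based default; not used by the pipeline.
    """
    k = len(seg.class_names)
    runs = extract_runs(seg)
    cov = np.zeros(k)
    for c in range(k):
        cov[c] = runs.loc[runs["class_index"] == c, "length"].sum()
    exp = np.empty((k, k))
    for a in range(k):
        denom = cov.sum() - cov[a]
        if denom <= 0:
            exp[a, :] = np.nan
            continue
        exp[a, :] = cov / denom
        exp[a, a] = 0.0
    return exp
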