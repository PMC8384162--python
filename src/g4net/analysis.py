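"""Downstream characterisation of extracted motifs.

Covers four questions about the motifs the network learned: how predictive
each cluster motif is of G4 activity (out-of-bag permutation importance
from a bagged-tree ensemble), how the motifs relate to one another
(classical MDS of the motif correlation matrix), how G-rich they are
(GG+ stretch statistics of consensus sequences), and where they sit
relative to active G4 regions (positional enrichment profiles).
"""

from __future__ import annotations

import logging
import re
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .io import BASES, GenomicRegion, fetch_sequence
from .motifs import PWM

logger = logging.getLogger(__name__)

_BASE_TO_COL = {b: i for i, b in enumerate(BASES)}


def _index_sequence(seq: str) -> np.ndarray:
    """Base -> column index, 4 for anything outside ACGT."""
    return np.fromiter(
        (_BASE_TO_COL.get(b, 4) for b in seq.upper()), dtype=np.int64, count=len(seq)
    )


def _padded(pwm_matrix: np.ndarray) -> np.ndarray:
    """Append a zero column so ambiguous bases score the background (0)."""
    return np.hstack([pwm_matrix, np.zeros((pwm_matrix.shape[0], 1))])


def _window_scores(idx: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Score of the motif at every start position of one indexed sequence."""
    w = matrix.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    padded = _padded(matrix)
    return padded[np.arange(w)[None, :], windows].sum(axis=1)


def pwm_position_scores(sequence: str, pwm: PWM) -> np.ndarray:
    """Per-start-position score, max over strands, for one sequence."""
    if len(sequence) < pwm.width:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than motif width {pwm.width}"
        )
    idx = _index_sequence(sequence)
    fwd = _window_scores(idx, pwm.matrix)
    rev = _window_scores(idx, pwm.matrix[::-1, ::-1])
    return np.maximum(fwd, rev)


def best_pwm_score(sequence: str, pwm: PWM) -> float:
    """Maximum log-odds hit score over all positions and both strands."""
    return float(pwm_position_scores(sequence, pwm).max())


def build_feature_table(
    sequences: Sequence[str],
    labels: Sequence[int],
    motifs: Sequence[PWM],
) -> pd.DataFrame:
    """Best-hit score of every motif in every sequence, plus the label."""
    data = {}
    for m, pwm in enumerate(motifs):
        name = pwm.name or f"motif_{m + 1}"
        data[name] = [best_pwm_score(s, pwm) for s in sequences]
    table = pd.DataFrame(data)
    table["label"] = np.asarray(labels, dtype=np.int64)
    return table


def variable_importance(
    table: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-bag permutation importance of each motif column.

    A bagging ensemble of sqrt-feature decision trees (a random forest) is
    fitted on the motif score table; for every tree, accuracy on its
    out-of-bag samples is compared before and after permuting one column,
    and drops are averaged over trees. Deterministic given ``seed``.
    """
    y = table["label"].to_numpy()
    X = table.drop(columns="label").to_numpy()
    names = [c for c in table.columns if c != "label"]
    if np.unique(y).size < 2:
        raise ValueError("both labels must be present")
    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt", random_state=seed),
        n_estimators=n_trees,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    drops = np.zeros((n_trees, X.shape[1]))
    counts = np.zeros(X.shape[1])
    for t, (tree, sampled) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.setdiff1d(np.arange(n), sampled)
        if oob.size == 0:
            continue
        base = np.mean(tree.predict(X[oob]) == y[oob])
        for f in range(X.shape[1]):
            Xp = X[oob].copy()
            Xp[:, f] = Xp[rng.permutation(oob.size), f]
            drops[t, f] = base - np.mean(tree.predict(Xp) == y[oob])
        counts += 1
    importance = drops.sum(axis=0) / np.maximum(counts, 1)
    out = pd.DataFrame({"motif": names, "importance": importance})
    out = out.sort_values("importance", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# consensus and G-stretch statistics


def consensus(pwm: PWM) -> str:
    """Per-column argmax letter; ties resolved by the fixed order A<C<G<T."""
    return "".join(BASES[int(np.argmax(col))] for col in pwm.matrix)


def count_g_stretches(seq: str, min_len: int = 2) -> tuple[int, list[int]]:
    """Maximal runs of G of length >= ``min_len`` in a consensus string."""
    lengths: list[int] = []
    run = 0
    for b in seq.upper() + "$":
        if b == "G":
            run += 1
        else:
            if run >= min_len:
                lengths.append(run)
            run = 0
    return len(lengths), lengths


CANONICAL_G4 = re.compile(r"G{3,}(?:[ACGTN]{1,7}G{3,}){3}")
CANONICAL_C4 = re.compile(r"C{3,}(?:[ACGTN]{1,7}C{3,}){3}")


def find_canonical_g4(sequence: str) -> list[tuple[int, int, str]]:
    """Non-overlapping leftmost matches of the canonical G4 pattern.

    The canonical pattern is four runs of >= 3 guanines separated by loops
    of 1-7 arbitrary bases; the C-rich complement marks a G4 on the other
    strand. Returns (start, end, strand) with '+' for G-rich and '-' for
    C-rich matches.
    """
    seq = sequence.upper()
    out = [(m.start(), m.end(), "+") for m in CANONICAL_G4.finditer(seq)]
    out += [(m.start(), m.end(), "-") for m in CANONICAL_C4.finditer(seq)]
    return sorted(out)


# ---------------------------------------------------------------------------
# positional enrichment


def enrichment_profile(
    pwm: PWM,
    anchor_regions: Sequence[GenomicRegion],
    genome,
    flank: int = 1000,
    hit_threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of anchors with a motif hit covering each offset.

    For each anchor (centred on its summit or midpoint), PWM hits with
    score >= ``hit_threshold`` (default 80% of the motif's maximum
    achievable score) are located on both strands and their footprints
    accumulated over the offset axis [-flank, +flank]. Anchors too close
    to a chromosome edge are dropped (count logged).
    """
    if hit_threshold is None:
        hit_threshold = 0.8 * pwm.max_score
    w = pwm.width
    offsets = np.arange(-flank, flank + 1)
    covered_total = np.zeros(offsets.size, dtype=np.float64)
    n_used = 0
    n_dropped = 0
    for anchor in anchor_regions:
        center = anchor.summit
        lo = center - flank - (w - 1)
        hi = center + flank + w
        chrom_len = len(genome[anchor.chrom])
        if lo < 0 or hi > chrom_len:
            n_dropped += 1
            continue
        seq = fetch_sequence(GenomicRegion(anchor.chrom, lo, hi), genome)
        scores = pwm_position_scores(seq, pwm)
        covered = np.zeros(offsets.size, dtype=bool)
        for p in np.nonzero(scores >= hit_threshold)[0]:
            # hit footprint in offset coordinates
            start = p - (flank + w - 1) + flank  # index into offsets array
            covered[max(0, start) : min(offsets.size, start + w)] = True
        covered_total += covered
        n_used += 1
    if n_dropped:
        logger.info("dropped %d anchors too close to a chromosome edge", n_dropped)
    if n_used == 0:
        raise ValueError("no usable anchors")
    return offsets, covered_total / n_used


# ---------------------------------------------------------------------------
# motif-space embedding


def embed_motifs(similarity_matrix: np.ndarray) -> np.ndarray:
    """Classical (metric) MDS of motifs from their correlation matrix.

    Distances are 1 - correlation; the embedding is the top-2 eigenspace
    of the double-centred squared-distance matrix, with a fixed sign
    convention (largest-magnitude loading positive per axis).
    """
    S = np.asarray(similarity_matrix, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    D = 1.0 - S
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:2]
    coords = np.zeros((n, 2))
    for axis, k in enumerate(order):
        lam = max(eigval[k], 0.0)
        v = eigvec[:, k] * np.sqrt(lam)
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, axis] = v
    return coords
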