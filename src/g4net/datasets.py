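"""Construction of active-G4 training sets.

Positives are fixed-width windows centred on in-vivo (ChIP-seq) peak
summits, retained only when the peak also forms a G4 in vitro (G4-seq
overlap). Negatives are drawn at random from the genome, matched to the
positives in window length, GC content and repeat content, and never
overlapping a positive window — the matched-null construction that keeps
the classifier from learning base composition instead of G4 grammar.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io import GenomicRegion, SignalTrack, encode_batch, fetch_sequence

logger = logging.getLogger(__name__)

SPLITS = ("train", "validation", "test")


@dataclass
class LabeledExample:
    sequence: str
    accessibility: float
    label: int
    origin: GenomicRegion | str = "synthetic"

    def __post_init__(self) -> None:
        if not math.isfinite(self.accessibility) or self.accessibility < 0:
            raise ValueError(f"invalid accessibility {self.accessibility}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class LabeledDataset:
    """Labelled (sequence, accessibility) examples with a train/val/test split."""

    examples: list[LabeledExample]
    split: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.examples) != len(self.split):
            raise ValueError("split assignment length mismatch")
        bad = set(self.split) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split names {bad}")

    def __len__(self) -> int:
        return len(self.examples)

    def subset(self, split: str) -> list[LabeledExample]:
        return [ex for ex, s in zip(self.examples, self.split) if s == split]

    def arrays(self, split: str | None = None):
        """(X one-hot, accessibility, labels) for a split (or everything)."""
        exs = self.examples if split is None else self.subset(split)
        if not exs:
            raise ValueError(f"no examples in split {split!r}")
        X = encode_batch([ex.sequence for ex in exs])
        acc = np.array([ex.accessibility for ex in exs], dtype=np.float32)
        y = np.array([ex.label for ex in exs], dtype=np.float32)
        return X, acc, y

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            fh.write("id\tchrom\tstart\tend\tlabel\taccessibility\tsplit\tsequence\n")
            for i, (ex, sp) in enumerate(zip(self.examples, self.split)):
                if isinstance(ex.origin, GenomicRegion):
                    chrom, start, end = ex.origin.chrom, ex.origin.start, ex.origin.end
                else:
                    chrom, start, end = str(ex.origin), -1, -1
                fh.write(
                    f"ex{i}\t{chrom}\t{start}\t{end}\t{ex.label}\t"
                    f"{ex.accessibility:.6g}\t{sp}\t{ex.sequence}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, seed: int = 0) -> "LabeledDataset":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        examples, split = [], []
        with opener(path, "rt") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            col = {name: i for i, name in enumerate(header)}
            for line in fh:
                f = line.rstrip("\n").split("\t")
                start, end = int(f[col["start"]]), int(f[col["end"]])
                if start >= 0:
                    origin: GenomicRegion | str = GenomicRegion(
                        f[col["chrom"]], start, end
                    )
                else:
                    origin = f[col["chrom"]]
                examples.append(
                    LabeledExample(
                        f[col["sequence"]],
                        float(f[col["accessibility"]]),
                        int(f[col["label"]]),
                        origin,
                    )
                )
                split.append(f[col["split"]])
        return cls(examples, split, seed=seed)


# ---------------------------------------------------------------------------
# positive windows


def _trees(regions: Iterable[GenomicRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    return trees


def define_active_regions(
    chip_peaks: Sequence[GenomicRegion],
    invitro_peaks: Sequence[GenomicRegion],
    window: int = 201,
) -> list[GenomicRegion]:
    """Summit-centred windows for in-vivo peaks confirmed in vitro.

    A ChIP peak is retained when the original peak interval overlaps any
    in-vitro peak by >= 1 bp; the emitted window is
    ``[summit - (window-1)/2, summit + (window-1)/2 + 1)``. Peaks without
    a recorded summit fall back to the interval midpoint. Windows that
    would run past the chromosome start are dropped with a warning.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    half = (window - 1) // 2
    trees = _trees(invitro_peaks)
    out: list[GenomicRegion] = []
    n_clipped = 0
    for peak in chip_peaks:
        tree = trees.get(peak.chrom)
        if tree is None or not tree.overlap(peak.start, peak.end):
            continue
        start = peak.summit - half
        if start < 0:
            n_clipped += 1
            continue
        out.append(
            GenomicRegion(peak.chrom, start, start + window, summit_offset=half,
                          score=peak.score, name=peak.name)
        )
    if n_clipped:
        logger.warning("dropped %d windows extending past a chromosome start", n_clipped)
    return out


def dedupe_replicates(
    peaks: Sequence[GenomicRegion], min_reciprocal: float = 0.5
) -> list[GenomicRegion]:
    """Concatenate replicate peak lists and drop near-duplicates.

    A peak is dropped when it overlaps an already-kept peak by at least
    ``min_reciprocal`` of both lengths (50% reciprocal overlap).
    """
    kept: list[GenomicRegion] = []
    trees: dict[str, IntervalTree] = {}
    for peak in peaks:
        tree = trees.setdefault(peak.chrom, IntervalTree())
        duplicate = False
        for hit in tree.overlap(peak.start, peak.end):
            ov = min(peak.end, hit.end) - max(peak.start, hit.begin)
            if (ov >= min_reciprocal * peak.length
                    and ov >= min_reciprocal * (hit.end - hit.begin)):
                duplicate = True
                break
        if not duplicate:
            kept.append(peak)
            tree.addi(peak.start, peak.end)
    return kept


# ---------------------------------------------------------------------------
# matched negatives


def gc_fraction(sequence: str) -> float:
    if not sequence:
        return 0.0
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / len(sequence)


def repeat_fraction(
    sequence: str, repeat_annotation: Sequence[tuple[int, int]] | None = None
) -> float:
    """Fraction of bases flagged as repeat.

    With an explicit mask (half-open intervals in sequence-local
    coordinates, e.g. a Tandem Repeat Finder track) the fraction of masked
    bases is returned; otherwise soft-masking (lowercase) in the raw
    reference slice is used as the proxy, which keeps the negative sampler
    self-contained on genomes without a repeat annotation.
    """
    if not sequence:
        return 0.0
    if repeat_annotation is not None:
        covered = np.zeros(len(sequence), dtype=bool)
        for start, end in repeat_annotation:
            covered[max(0, start) : min(len(sequence), end)] = True
        return float(covered.mean())
    return sum(1 for b in sequence if b.islower()) / len(sequence)


def non_acgt_fraction(sequence: str) -> float:
    s = sequence.upper()
    return sum(1 for b in s if b not in "ACGT") / max(len(s), 1)


def sample_matched_negatives(
    positives: Sequence[tuple[GenomicRegion, str]],
    genome,
    n_per_positive: int = 1,
    gc_tolerance: float = 0.02,
    repeat_tolerance: float = 0.05,
    max_attempts: int = 5000,
    seed: int = 0,
) -> list[GenomicRegion]:
    """Rejection-sample GC- and repeat-matched control windows.

    For every positive (region, raw reference sequence) pair, windows of
    the same length are drawn uniformly from the genome until one matches
    the positive's GC fraction within ``gc_tolerance`` and repeat fraction
    within ``repeat_tolerance`` while overlapping no positive window. If
    ``max_attempts`` draws all fail, the non-overlapping candidate with the
    closest GC is used and a warning logged. Deterministic given ``seed``.
    """
    if not positives:
        raise ValueError("need at least one positive to match against")
    rng = np.random.default_rng(seed)
    chroms = list(genome.keys()) if hasattr(genome, "keys") else [r.name for r in genome]
    lengths = np.array([len(genome[c]) for c in chroms], dtype=np.float64)
    weights = lengths / lengths.sum()
    pos_trees = _trees([r for r, _ in positives])
    negatives: list[GenomicRegion] = []
    n_fallback = 0
    for region, seq in positives:
        width = region.length
        gc_target = gc_fraction(seq)
        rep_target = repeat_fraction(seq)
        for _ in range(n_per_positive):
            best = None  # (gc distance, region)
            accepted = None
            for _attempt in range(max_attempts):
                ci = int(rng.choice(len(chroms), p=weights))
                chrom = chroms[ci]
                limit = int(lengths[ci]) - width
                if limit <= 0:
                    continue
                start = int(rng.integers(0, limit + 1))
                cand = GenomicRegion(chrom, start, start + width)
                tree = pos_trees.get(chrom)
                if tree is not None and tree.overlap(cand.start, cand.end):
                    continue
                cand_seq = fetch_raw(genome, cand)
                if non_acgt_fraction(cand_seq) > 0.1:
                    continue
                gc_d = abs(gc_fraction(cand_seq) - gc_target)
                if best is None or gc_d < best[0]:
                    best = (gc_d, cand)
                if (gc_d <= gc_tolerance
                        and abs(repeat_fraction(cand_seq) - rep_target) <= repeat_tolerance):
                    accepted = cand
                    break
            if accepted is None:
                if best is None:
                    raise RuntimeError(
                        f"could not place any candidate for positive {region}"
                    )
                accepted = best[1]
                n_fallback += 1
            negatives.append(accepted)
    if n_fallback:
        logger.warning(
            "%d/%d negatives fell back to the closest-GC candidate",
            n_fallback, len(negatives),
        )
    return negatives


def fetch_raw(genome, region: GenomicRegion) -> str:
    """Reference slice preserving case (soft-masking carries repeat info)."""
    rec = genome[region.chrom]
    seq = rec[region.start : region.end]
    return seq if isinstance(seq, str) else str(seq)


# ---------------------------------------------------------------------------
# assembly


def split_assignment(n: int, fractions: tuple[float, float, float], rng) -> list[str]:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    labels = (["train"] * n_train + ["validation"] * n_val
              + ["test"] * (n - n_train - n_val))
    order = rng.permutation(n)
    out = [""] * n
    for slot, i in zip(labels, order):
        out[i] = slot
    return out


def assemble_dataset(
    pos_regions: Sequence[GenomicRegion],
    neg_regions: Sequence[GenomicRegion],
    genome,
    track: SignalTrack | None = None,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    max_non_acgt: float = 0.1,
) -> LabeledDataset:
    """Fetch sequences and accessibility for labelled windows and split them.

    Windows with more than ``max_non_acgt`` ambiguous bases are excluded
    (count logged). Examples are shuffled with ``seed`` before the split so
    positives and negatives mix across train/validation/test.
    """
    rng = np.random.default_rng(seed)
    examples: list[LabeledExample] = []
    n_dropped = 0
    for label, regions in ((1, pos_regions), (0, neg_regions)):
        for region in regions:
            seq = fetch_sequence(region, genome)
            if non_acgt_fraction(seq) > max_non_acgt:
                n_dropped += 1
                continue
            acc = track.mean_signal(region) if track is not None else 0.0
            examples.append(LabeledExample(seq, acc, label, region))
    if n_dropped:
        logger.info("excluded %d windows with >%.0f%% ambiguous bases",
                    n_dropped, 100 * max_non_acgt)
    order = rng.permutation(len(examples))
    examples = [examples[i] for i in order]
    split = split_assignment(len(examples), fractions, rng)
    return LabeledDataset(examples, split, seed=seed)
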