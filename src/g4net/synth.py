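"""Synthetic data with the statistical structure of active-G4 experiments.

Positive sequences carry a planted canonical-G4-like pattern (four runs of
3-4 guanines separated by 1-7 base loops) and high chromatin
accessibility; negatives are GC-matched background with low
accessibility. An interaction mode makes the positive label require BOTH
the motif and high accessibility, which is the regime where the
accessibility input demonstrably helps and the sequence-only ablation
falls behind. A toy-genome generator emits the full file set (FASTA,
in-vivo narrowPeak, in-vitro BED, accessibility bedGraph) with planted
ground truth, so the peak-overlap and negative-sampling machinery can be
exercised end to end without any download.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .datasets import LabeledDataset, LabeledExample, split_assignment
from .io import GenomicRegion, SignalTrack, write_fasta, write_regions

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

CANONICAL_G4_PATTERN = "G{3,4}N{1,7}G{3,4}N{1,7}G{3,4}N{1,7}G{3,4}"

_TOKEN = re.compile(r"([A-Z])(?:\{(\d+)(?:,(\d+))?\})?")


def _parse_pattern(pattern: str) -> list[tuple[str, int, int]]:
    tokens = []
    pos = 0
    for m in _TOKEN.finditer(pattern):
        if m.start() != pos:
            raise ValueError(f"cannot parse pattern {pattern!r} at offset {pos}")
        letter, lo, hi = m.group(1), m.group(2), m.group(3)
        if letter not in IUPAC:
            raise ValueError(f"unknown IUPAC letter {letter!r} in {pattern!r}")
        lo_n = int(lo) if lo else 1
        hi_n = int(hi) if hi else lo_n
        if lo_n < 0 or hi_n < lo_n:
            raise ValueError(f"bad run range in {pattern!r}")
        tokens.append((letter, lo_n, hi_n))
        pos = m.end()
    if pos != len(pattern) or not tokens:
        raise ValueError(f"cannot parse pattern {pattern!r}")
    return tokens


def max_pattern_length(pattern: str) -> int:
    return sum(hi for _, _, hi in _parse_pattern(pattern))


def realize_pattern(pattern: str, rng: np.random.Generator) -> str:
    """Sample one concrete DNA string from an IUPAC/run-length pattern."""
    out = []
    for letter, lo, hi in _parse_pattern(pattern):
        n = int(rng.integers(lo, hi + 1))
        choices = IUPAC[letter]
        if len(choices) == 1:
            out.append(choices * n)
        else:
            out.append("".join(rng.choice(list(choices), size=n)))
    return "".join(out)


@dataclass(frozen=True)
class PlantedMotif:
    """A motif pattern with its insertion probability and positional law.

    ``placement`` is ``"center"`` (exact window centre), ``"uniform"``
    (uniform over valid starts), ``"flank"`` (uniform outside the middle
    third) or ``("normal", sd)`` for a Gaussian around the centre.
    """

    pattern: str = CANONICAL_G4_PATTERN
    probability: float = 1.0
    placement: object = "center"

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("insertion probability must be in [0, 1]")
        _parse_pattern(self.pattern)


@dataclass(frozen=True)
class AccessibilityModel:
    """Truncated-normal accessibility per class, optionally interacting.

    With ``interaction`` set, the positive label requires both the motif
    and high accessibility; the negative class then mixes motif/low,
    no-motif/high and no-motif/low examples in equal parts.
    """

    mean_pos: float = 0.8
    mean_neg: float = 0.2
    noise_sd: float = 0.15
    interaction: bool = False


@dataclass
class SyntheticConfig:
    n_pos: int = 1000
    n_neg: int = 1000
    seq_len: int = 201
    gc_background: float = 0.41
    planted_motifs: list[PlantedMotif] = field(
        default_factory=lambda: [PlantedMotif()]
    )
    accessory_motifs: list[PlantedMotif] = field(default_factory=list)
    accessibility_model: AccessibilityModel = field(default_factory=AccessibilityModel)
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_background < 1.0:
            raise ValueError("gc_background must be in (0, 1)")
        for motif in list(self.planted_motifs) + list(self.accessory_motifs):
            if max_pattern_length(motif.pattern) > self.seq_len:
                raise ValueError(
                    f"pattern {motif.pattern!r} cannot fit in seq_len={self.seq_len}"
                )


def _random_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _sample_start(placement, seq_len: int, motif_len: int, rng) -> int:
    limit = seq_len - motif_len
    if isinstance(placement, tuple) and placement[0] == "normal":
        sd = placement[1]
        start = int(round(rng.normal((seq_len - motif_len) / 2, sd)))
        return int(np.clip(start, 0, limit))
    if placement == "center":
        return limit // 2
    if placement == "uniform":
        return int(rng.integers(0, limit + 1))
    if placement == "flank":
        third = seq_len // 3
        left_hi = max(third - motif_len, 0)
        right_lo = min(2 * third, limit)
        if rng.random() < 0.5 and left_hi > 0:
            return int(rng.integers(0, left_hi + 1))
        return int(rng.integers(right_lo, limit + 1))
    raise ValueError(f"unknown placement {placement!r}")


def _truncated_normal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _make_sequence(
    config: SyntheticConfig,
    rng: np.random.Generator,
    with_motif: bool,
) -> tuple[str, list[tuple[int, int, str]]]:
    seq = _random_background(rng, config.seq_len, config.gc_background)
    annotation: list[tuple[int, int, str]] = []
    motifs = list(config.planted_motifs) if with_motif else []
    motifs += list(config.accessory_motifs)
    for motif in motifs:
        if rng.random() > motif.probability:
            continue
        realization = realize_pattern(motif.pattern, rng)
        start = _sample_start(motif.placement, config.seq_len, len(realization), rng)
        seq[start : start + len(realization)] = list(realization)
        annotation.append((start, start + len(realization), motif.pattern))
    return "".join(seq), annotation


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[LabeledDataset, list[list[tuple[int, int, str]]]]:
    """Sample a labelled dataset plus per-example planted-motif annotations.

    Every positive carries at least one realisation of each planted motif
    with probability 1 (the default insertion probability); when the
    accessibility interaction is on, the negative class mixes
    motif-without-accessibility and accessibility-without-motif examples
    so the label is only predictable from both inputs jointly.
    """
    rng = np.random.default_rng(config.seed)
    am = config.accessibility_model
    records: list[tuple[str, float, int, list]] = []

    pos_acc = _truncated_normal(rng, am.mean_pos, am.noise_sd, config.n_pos)
    for i in range(config.n_pos):
        seq, ann = _make_sequence(config, rng, with_motif=True)
        records.append((seq, float(pos_acc[i]), 1, ann))

    if am.interaction:
        groups = np.array_split(np.arange(config.n_neg), 3)
        specs = [(True, am.mean_neg), (False, am.mean_pos), (False, am.mean_neg)]
        for group, (with_motif, mean) in zip(groups, specs):
            accs = _truncated_normal(rng, mean, am.noise_sd, len(group))
            for a in accs:
                seq, ann = _make_sequence(config, rng, with_motif=with_motif)
                records.append((seq, float(a), 0, ann))
    else:
        neg_acc = _truncated_normal(rng, am.mean_neg, am.noise_sd, config.n_neg)
        for i in range(config.n_neg):
            seq, ann = _make_sequence(config, rng, with_motif=False)
            records.append((seq, float(neg_acc[i]), 0, ann))

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    examples = [
        LabeledExample(seq, acc, label, "synthetic") for seq, acc, label, _ in records
    ]
    annotations = [ann for _, _, _, ann in records]
    split = split_assignment(len(examples), config.fractions, rng)
    return LabeledDataset(examples, split, seed=config.seed), annotations


def planted_motif_pwm(
    pattern: str = CANONICAL_G4_PATTERN,
    width: int = 20,
    n_samples: int = 2000,
    seed: int = 0,
):
    """Reference PWM of a planted pattern at a fixed width.

    Realisations of the pattern are sampled until ``n_samples`` of exactly
    ``width`` bases are collected, and their position frequencies give the
    pattern's PWM at that width — the natural ground truth to compare a
    kernel-derived motif of the same width against.
    """
    from .motifs import build_pfm, pfm_to_pwm

    lo = sum(lo for _, lo, _ in _parse_pattern(pattern))
    hi = max_pattern_length(pattern)
    if not lo <= width <= hi:
        raise ValueError(f"pattern realisations span [{lo}, {hi}], not {width}")
    rng = np.random.default_rng(seed)
    reals: list[str] = []
    while len(reals) < n_samples:
        r = realize_pattern(pattern, rng)
        if len(r) == width:
            reals.append(r)
    pfm = build_pfm(reals)
    pfm.name = "planted_reference"
    return pfm_to_pwm(pfm)


# ---------------------------------------------------------------------------
# toy genome with planted peaks


@dataclass
class ToyGenome:
    genome: dict
    chip_peaks: list[GenomicRegion]
    invitro_peaks: list[GenomicRegion]
    track: SignalTrack
    active_sites: list[GenomicRegion]
    decoy_sites: list[GenomicRegion]
    paths: dict = field(default_factory=dict)


def generate_toy_genome(
    out_dir: str | Path | None = None,
    n_chroms: int = 2,
    chrom_length: int = 150_000,
    n_active: int = 40,
    n_decoy: int = 20,
    gc_background: float = 0.41,
    accessibility_high: float = 0.8,
    accessibility_low: float = 0.1,
    seed: int = 7,
) -> ToyGenome:
    """Build a small multi-chromosome genome with planted G4 sites.

    Active sites get a canonical-G4 motif insertion, an in-vivo
    (narrowPeak, summit on the motif) peak, an in-vitro peak and elevated
    accessibility; decoy sites get the motif and an in-vitro peak only, so
    the in-vivo/in-vitro intersection has true negatives to reject. When
    ``out_dir`` is given the FASTA/narrowPeak/BED/bedGraph file set is
    written there (byte-identical across runs with the same seed).
    """
    rng = np.random.default_rng(seed)
    total_sites = n_active + n_decoy
    per_chrom = np.full(n_chroms, total_sites // n_chroms)
    per_chrom[: total_sites % n_chroms] += 1

    genome: dict[str, str] = {}
    site_list: list[tuple[GenomicRegion, bool]] = []  # (site, is_active)
    site_id = 0
    is_active_flags = np.array([True] * n_active + [False] * n_decoy)
    rng.shuffle(is_active_flags)

    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        seq = _random_background(rng, chrom_length, gc_background)
        n_sites = int(per_chrom[ci])
        spacing = chrom_length // (n_sites + 1)
        for si in range(n_sites):
            center = (si + 1) * spacing + int(rng.integers(-spacing // 4, spacing // 4))
            motif = realize_pattern(CANONICAL_G4_PATTERN, rng)
            start = center - len(motif) // 2
            seq[start : start + len(motif)] = list(motif)
            site = GenomicRegion(chrom, start, start + len(motif), name=f"site{site_id}")
            site_list.append((site, bool(is_active_flags[site_id])))
            site_id += 1
        genome[chrom] = "".join(seq)

    chip_peaks, invitro_peaks = [], []
    active_sites, decoy_sites = [], []
    for site, active in site_list:
        mid = (site.start + site.end) // 2
        iv_lo = mid - int(rng.integers(60, 140))
        iv_hi = mid + int(rng.integers(60, 140))
        invitro_peaks.append(GenomicRegion(site.chrom, iv_lo, iv_hi, name=site.name))
        if active:
            ch_lo = mid - int(rng.integers(80, 160))
            ch_hi = mid + int(rng.integers(80, 160))
            chip_peaks.append(
                GenomicRegion(
                    site.chrom, ch_lo, ch_hi,
                    summit_offset=mid - ch_lo,
                    score=float(rng.integers(50, 1000)),
                    name=site.name,
                )
            )
            active_sites.append(site)
        else:
            decoy_sites.append(site)

    # piecewise-constant accessibility: low background, high over active sites
    bin_size = 100
    records = []
    active_by_chrom: dict[str, list[GenomicRegion]] = {}
    for s in active_sites:
        active_by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in genome:
        n_bins = (len(genome[chrom]) + bin_size - 1) // bin_size
        values = np.clip(
            rng.normal(accessibility_low, accessibility_low / 3, n_bins), 0.0, None
        )
        for s in active_by_chrom.get(chrom, []):
            lo_bin = max((s.start - 100) // bin_size, 0)
            hi_bin = min((s.end + 100) // bin_size + 1, n_bins)
            values[lo_bin:hi_bin] = np.clip(
                rng.normal(accessibility_high, 0.1, hi_bin - lo_bin), 0.0, None
            )
        for b in range(n_bins):
            records.append(
                (chrom, b * bin_size, min((b + 1) * bin_size, len(genome[chrom])),
                 round(float(values[b]), 4))
            )
    track = SignalTrack.from_records(records)

    toy = ToyGenome(genome, chip_peaks, invitro_peaks, track,
                    active_sites, decoy_sites)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out_dir / "genome.fa",
            "chip": out_dir / "g4_chip.narrowPeak",
            "invitro": out_dir / "g4_invitro.bed",
            "signal": out_dir / "accessibility.bedGraph",
            "truth": out_dir / "planted_sites.bed",
        }
        write_fasta(genome, paths["fasta"])
        write_regions(chip_peaks, paths["chip"], format="narrowPeak")
        write_regions(invitro_peaks, paths["invitro"], format="bed")
        track.write_bedgraph(paths["signal"])
        truth = [
            GenomicRegion(s.chrom, s.start, s.end, name=f"{s.name}_active")
            for s in active_sites
        ] + [
            GenomicRegion(s.chrom, s.start, s.end, name=f"{s.name}_decoy")
            for s in decoy_sites
        ]
        write_regions(sorted(truth, key=lambda r: (r.chrom, r.start)), paths["truth"])
        toy.paths = {k: str(v) for k, v in paths.items()}
    return toy
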