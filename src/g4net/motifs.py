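"""From convolution kernels to DNA motifs.

Each first-layer kernel is turned into a position frequency matrix by
collecting, over the positive sequences, the kernel-width subsequence with
the highest (positive) activation per sequence. PFMs are trimmed at the
flanks by information content, converted to log-odds PWMs against a
uniform 0.25 background, and clustered to remove the heavy redundancy
among kernels (complementary and shifted variants of the same motif).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import BASES

logger = logging.getLogger(__name__)

_BASE_TO_COL = {b: i for i, b in enumerate(BASES)}


@dataclass
class PFM:
    """Column-stochastic W x 4 base-frequency matrix with provenance."""

    matrix: np.ndarray
    n_hits: int
    kernel_id: int = -1
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError(f"PFM matrix must be W x 4, got {self.matrix.shape}")
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PFM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PWM:
    """Log2-odds weight matrix against a uniform 0.25 background."""

    matrix: np.ndarray
    name: str = ""
    pfm: PFM | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM matrix must be W x 4, got {self.matrix.shape}")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        # reversing both axes maps position i -> W-1-i and base b -> complement
        return PWM(self.matrix[::-1, ::-1].copy(), name=self.name + "_rc")

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())


@dataclass
class MotifCluster:
    """A group of redundant PWMs with a representative centre motif.

    The centre is the cluster medoid — the member with the highest median
    ncor to its co-members — because G-rich motifs differ mainly in loop
    phase, and averaging members across incompatible phases produces a
    degenerate all-G matrix that no longer represents any of them. The
    ungapped alignment-average PFM is kept as ``average_pfm``.
    """

    members: list[str]
    center: PWM
    label: str
    center_pfm: PFM | None = None
    average_pfm: PFM | None = None


# ---------------------------------------------------------------------------
# activation harvesting


def kernel_activations(model, X: np.ndarray) -> np.ndarray:
    """Post-ReLU first-layer outputs, shape (n_seq, n_positions, n_kernels).

    ``model`` is a TrainedModel; sequences must be pre-encoded to
    (n, input_length, 4).
    """
    if not getattr(model, "training_history", None):
        raise ValueError("model has not been trained")
    return model.net.conv_activations(X)


def best_hit_subsequences(
    activations: np.ndarray,
    sequences: Sequence[str],
    kernel_id: int,
    kernel_size: int | None = None,
) -> list[str]:
    """Per sequence, the kernel-width subsequence of maximum activation.

    Sequences whose activations for this kernel are all <= 0 contribute
    nothing; ties at the maximum take the leftmost position.
    """
    if activations.shape[0] != len(sequences):
        raise ValueError("activation/sequence count mismatch")
    if kernel_size is None:
        kernel_size = len(sequences[0]) - activations.shape[1] + 1
    acts = activations[:, :, kernel_id]
    out: list[str] = []
    for i, seq in enumerate(sequences):
        row = acts[i]
        best = row.max()
        if best <= 0:
            continue
        pos = int(np.argmax(row))  # leftmost on ties
        out.append(seq[pos : pos + kernel_size].upper())
    return out


def build_pfm(subsequences: Sequence[str], kernel_id: int = -1) -> PFM:
    """Base frequencies per column over equal-length hit subsequences.

    Non-ACGT letters are excluded from both numerator and denominator of
    their column; a column with no ACGT observation falls back to uniform.
    """
    if not subsequences:
        raise ValueError("cannot build a PFM from zero subsequences")
    width = len(subsequences[0])
    if any(len(s) != width for s in subsequences):
        raise ValueError("subsequences must have equal length")
    counts = np.zeros((width, 4), dtype=np.float64)
    for s in subsequences:
        for j, b in enumerate(s.upper()):
            col = _BASE_TO_COL.get(b)
            if col is not None:
                counts[j, col] += 1
    totals = counts.sum(axis=1, keepdims=True)
    matrix = np.where(totals > 0, counts / np.maximum(totals, 1), 0.25)
    return PFM(matrix, n_hits=len(subsequences), kernel_id=kernel_id,
               name=f"kernel_{kernel_id}" if kernel_id >= 0 else "")


# ---------------------------------------------------------------------------
# trimming and log-odds


def information_content(column: np.ndarray) -> float:
    """Column IC in bits: 2 + sum p log2 p, with 0 log 0 := 0."""
    p = np.asarray(column, dtype=np.float64)
    nz = p[p > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


def trim_pfm(pfm: PFM, ic_threshold: float = 0.9, min_width: int = 5) -> PFM | None:
    """Strip low-information flank columns; reject over-trimmed motifs.

    Columns are removed from each side inward while their IC is <=
    ``ic_threshold`` bits; interior columns are never touched. Returns
    ``None`` when fewer than ``min_width`` columns survive.
    """
    ic = np.array([information_content(col) for col in pfm.matrix])
    lo, hi = 0, pfm.width
    while lo < hi and ic[lo] <= ic_threshold:
        lo += 1
    while hi > lo and ic[hi - 1] <= ic_threshold:
        hi -= 1
    if hi - lo < min_width:
        return None
    return PFM(pfm.matrix[lo:hi].copy(), n_hits=pfm.n_hits,
               kernel_id=pfm.kernel_id, name=pfm.name)


def pfm_to_pwm(pfm: PFM, pseudocount: float = 0.01) -> PWM:
    """log2((f + pseudocount) / (0.25 + pseudocount)) per cell."""
    with np.errstate(divide="ignore"):  # pseudocount 0 and f=0 -> -inf, valid
        weights = np.log2((pfm.matrix + pseudocount) / (0.25 + pseudocount))
    return PWM(weights, name=pfm.name, pfm=pfm)


# ---------------------------------------------------------------------------
# similarity and clustering


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        return 0.0
    return float((x * y).sum() / (nx * ny))


def motif_similarity(a: PWM, b: PWM) -> tuple[float, float, int, str]:
    """Best ungapped-alignment correlation between two PWMs.

    All relative offsets and both orientations of ``b`` are scanned;
    ``cor`` is the maximum Pearson correlation of the flattened aligned
    columns, and ``ncor`` the maximum of correlation x (aligned width /
    max(width_a, width_b)). The reported offset (of b's first column
    relative to a's) and strand belong to the ncor-maximising alignment.
    """
    wa, wb = a.width, b.width
    denom = max(wa, wb)
    best_cor = -np.inf
    best = (-np.inf, 0, "+", -np.inf)  # (ncor, offset, strand, tiebreak)
    for strand, bm in (("+", b.matrix), ("-", b.matrix[::-1, ::-1])):
        for offset in range(-(wb - 1), wa):
            a_lo, a_hi = max(0, offset), min(wa, offset + wb)
            width = a_hi - a_lo
            if width < 1:
                continue
            seg_a = a.matrix[a_lo:a_hi].ravel()
            seg_b = bm[a_lo - offset : a_hi - offset].ravel()
            r = _pearson(seg_a, seg_b)
            best_cor = max(best_cor, r)
            ncor = r * width / denom
            key = (ncor, -abs(offset), 1 if strand == "+" else 0)
            if key > (best[0], -abs(best[1]), 1 if best[2] == "+" else 0):
                best = (ncor, offset, strand, 0.0)
    return float(best_cor), float(best[0]), int(best[1]), best[2]


def _pairwise_similarity(pwms: Sequence[PWM]):
    n = len(pwms)
    cor = np.eye(n)
    ncor = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            c, nc, _, _ = motif_similarity(pwms[i], pwms[j])
            cor[i, j] = cor[j, i] = c
            ncor[i, j] = ncor[j, i] = nc
    return cor, ncor


def cluster_motifs(
    pwms: Sequence[PWM],
    cor_min: float = 0.6,
    ncor_min: float = 0.6,
) -> list[MotifCluster]:
    """Merge redundant PWMs by median-linkage agglomeration on 1 - ncor.

    Cluster pairs merge greedily in decreasing median ncor as long as the
    pair satisfies both gates (median pairwise cor >= ``cor_min`` and
    median pairwise ncor >= ``ncor_min``). Each cluster's centre is its
    medoid member (see :class:`MotifCluster`); the aligned member-frequency
    average over the widest member's frame is attached as ``average_pfm``.
    """
    if not pwms:
        raise ValueError("need at least one PWM")
    n = len(pwms)
    cor, ncor = _pairwise_similarity(pwms)
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best_pair = None
        best_val = (-np.inf, 0, 0)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pairs_c = [cor[a, b] for a in clusters[i] for b in clusters[j]]
                pairs_n = [ncor[a, b] for a in clusters[i] for b in clusters[j]]
                med_c, med_n = float(np.median(pairs_c)), float(np.median(pairs_n))
                if med_c >= cor_min and med_n >= ncor_min:
                    # tie-break deterministically by member indices
                    val = (med_n, -clusters[i][0], -clusters[j][0])
                    if val > best_val:
                        best_val = val
                        best_pair = (i, j)
        if best_pair is None:
            break
        i, j = best_pair
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
    clusters.sort(key=lambda m: (-len(m), m[0]))
    out = []
    for k, members in enumerate(clusters, start=1):
        member_pwms = [pwms[m] for m in members]
        medoid = _medoid(member_pwms, ncor[np.ix_(members, members)])
        center_pfm = PFM(
            medoid.pfm.matrix.copy(), n_hits=medoid.pfm.n_hits,
            kernel_id=medoid.pfm.kernel_id,
        ) if medoid.pfm is not None else None
        center = PWM(medoid.matrix.copy(), pfm=center_pfm)
        average_pfm = _aligned_average(member_pwms)
        center.name = f"cluster_{k}"
        if center_pfm is not None:
            center_pfm.name = f"cluster_{k}"
        average_pfm.name = f"cluster_{k}_avg"
        out.append(
            MotifCluster(
                members=[pwms[m].name or f"pwm_{m}" for m in members],
                center=center,
                label=f"cluster_{k}",
                center_pfm=center_pfm,
                average_pfm=average_pfm,
            )
        )
    return out


def _medoid(members: Sequence[PWM], ncor_sub: np.ndarray) -> PWM:
    """Member with the highest median ncor to its co-members.

    Ties break towards more supporting hits, then lower kernel id, so the
    choice is deterministic and permutation-invariant.
    """
    if len(members) == 1:
        return members[0]
    scores = np.median(ncor_sub, axis=1)
    keys = [
        (
            scores[i],
            members[i].pfm.n_hits if members[i].pfm else 0,
            -(members[i].pfm.kernel_id if members[i].pfm else i),
        )
        for i in range(len(members))
    ]
    return members[max(range(len(members)), key=lambda i: keys[i])]


def _aligned_average(members: Sequence[PWM]) -> PFM:
    """Average member frequencies over the widest member's frame."""
    ref = max(members, key=lambda p: (p.width, -(p.pfm.kernel_id if p.pfm else 0)))
    width = ref.width
    total = np.zeros((width, 4))
    coverage = np.zeros((width, 1))
    n_hits = 0
    for m in members:
        freq = m.pfm.matrix if m.pfm is not None else _pwm_to_freq(m)
        n_hits += m.pfm.n_hits if m.pfm is not None else 1
        if m is ref:
            offset, strand = 0, "+"
        else:
            _, _, offset, strand = motif_similarity(ref, m)
        if strand == "-":
            freq = freq[::-1, ::-1]
        lo, hi = max(0, offset), min(width, offset + m.width)
        if hi <= lo:
            lo, hi = 0, min(width, m.width)
            offset = 0
        total[lo:hi] += freq[lo - offset : hi - offset]
        coverage[lo:hi] += 1
    avg = np.where(coverage > 0, total / np.maximum(coverage, 1), 0.25)
    avg = avg / avg.sum(axis=1, keepdims=True)
    return PFM(avg, n_hits=max(n_hits, 1))


def _pwm_to_freq(pwm: PWM, pseudocount: float = 0.01) -> np.ndarray:
    freq = (0.25 + pseudocount) * np.exp2(pwm.matrix) - pseudocount
    freq = np.clip(freq, 1e-9, None)
    return freq / freq.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# motif file formats


def write_motifs(motifs: Sequence[PFM], path: str | Path, format: str = "MEME") -> None:
    """Write PFMs as MEME minimal (v4) or JASPAR raw-count text."""
    path = Path(path)
    if format == "MEME":
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
            for i, pfm in enumerate(motifs):
                name = pfm.name or f"motif_{i + 1}"
                fh.write(f"MOTIF {name}\n")
                fh.write(
                    f"letter-probability matrix: alength= 4 w= {pfm.width} "
                    f"nsites= {pfm.n_hits} E= 0\n"
                )
                for row in pfm.matrix:
                    fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
                fh.write("\n")
    elif format == "JASPAR":
        with open(path, "w") as fh:
            for i, pfm in enumerate(motifs):
                name = pfm.name or f"motif_{i + 1}"
                fh.write(f">{name}\n")
                counts = pfm.matrix * pfm.n_hits
                for bi, base in enumerate(BASES):
                    row = " ".join(f"{counts[j, bi]:.4f}" for j in range(pfm.width))
                    fh.write(f"{base} [ {row} ]\n")
    else:
        raise ValueError(f"unknown motif format {format!r}")


def read_motifs(path: str | Path, format: str = "MEME") -> list[PFM]:
    path = Path(path)
    motifs: list[PFM] = []
    if format == "MEME":
        with open(path) as fh:
            lines = fh.read().splitlines()
        i = 0
        while i < len(lines):
            if lines[i].startswith("MOTIF"):
                name = lines[i].split()[1] if len(lines[i].split()) > 1 else ""
                i += 1
                while i < len(lines) and not lines[i].startswith("letter-probability"):
                    i += 1
                header = dict(
                    zip(lines[i].split()[2::2], lines[i].split()[3::2])
                ) if i < len(lines) else {}
                width = int(header.get("w=", 0)) or int(
                    lines[i].split("w=")[1].split()[0]
                )
                nsites = int(float(lines[i].split("nsites=")[1].split()[0])) \
                    if "nsites=" in lines[i] else 1
                rows = []
                for j in range(width):
                    rows.append([float(v) for v in lines[i + 1 + j].split()])
                motifs.append(PFM(np.array(rows), n_hits=max(nsites, 1), name=name))
                i += width + 1
            else:
                i += 1
    elif format == "JASPAR":
        with open(path) as fh:
            content = fh.read()
        for block in content.split(">"):
            block = block.strip()
            if not block:
                continue
            lines = block.splitlines()
            name = lines[0].split()[0]
            counts = {}
            for line in lines[1:]:
                base = line.split()[0]
                inner = line[line.index("[") + 1 : line.index("]")]
                counts[base] = [float(v) for v in inner.split()]
            matrix = np.array([counts[b] for b in BASES]).T
            totals = matrix.sum(axis=1, keepdims=True)
            n_hits = int(round(totals.max())) or 1
            motifs.append(
                PFM(matrix / np.maximum(totals, 1e-12), n_hits=n_hits, name=name)
            )
    else:
        raise ValueError(f"unknown motif format {format!r}")
    return motifs


# ---------------------------------------------------------------------------
# end-to-end extraction


def extract_motifs(
    model,
    sequences: Sequence[str],
    ic_threshold: float = 0.9,
    min_width: int = 5,
    pseudocount: float = 0.01,
    min_hits: int = 10,
    cluster: bool = True,
    cor_min: float = 0.6,
    ncor_min: float = 0.6,
) -> dict:
    """Kernel -> PFM -> trim -> PWM -> cluster pipeline on positive sequences.

    Returns a dict with the per-kernel PFMs/PWMs that survive trimming and
    (optionally) the clusters of the retained PWMs.
    """
    from .io import encode_batch

    X = encode_batch(sequences)
    acts = kernel_activations(model, X)
    k = model.spec.kernel_size
    pfms, pwms = [], []
    for kernel_id in range(model.spec.n_kernels):
        hits = best_hit_subsequences(acts, sequences, kernel_id, kernel_size=k)
        if len(hits) < min_hits:
            continue
        pfm = build_pfm(hits, kernel_id=kernel_id)
        trimmed = trim_pfm(pfm, ic_threshold=ic_threshold, min_width=min_width)
        if trimmed is None:
            continue
        pfms.append(trimmed)
        pwms.append(pfm_to_pwm(trimmed, pseudocount=pseudocount))
    result = {"pfms": pfms, "pwms": pwms, "clusters": None}
    if cluster and pwms:
        result["clusters"] = cluster_motifs(pwms, cor_min=cor_min, ncor_min=ncor_min)
    return result
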