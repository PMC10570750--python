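"""Promoter/enhancer chromatin-state analysis around ATAC summits.

Enhancers are ATAC peaks whose summit falls outside every promoter window
and which overlap an H3K4me1 peak.  Signal matrices are built from
bedGraph-derived step functions in a fixed window centered at each summit
(default 6 kb, 100 bp bins), library-normalized to counts-per-million of
track mass and log2(1 + x) transformed.  K-means (k = 3, best of several
restarts) on the column-standardized matrix separates enhancer states,
which are then renamed by descending mean H3K27ac window signal into
``active_high``, ``active_low`` and ``poised``.

Differential known-motif enrichment replaces de novo discovery: each PWM is
scanned over both strands of fixed windows around foreground and background
summits, a region counts as containing the motif when any position reaches
the PWM's log-odds threshold, and per-PWM 2x2 Fisher tests are BH-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .annotation import (
    GenomicInterval,
    Peak,
    PeakSet,
    TranscriptModel,
    nearest_tss,
)

__all__ = [
    "CoverageTrack",
    "SignalMatrix",
    "EnhancerRecord",
    "PWM",
    "read_bedgraph",
    "classify_promoter_state",
    "call_enhancers",
    "build_signal_matrix",
    "cluster_enhancer_states",
    "aggregate_profile",
    "assign_enhancers_to_genes",
    "read_jaspar",
    "scan_contains",
    "differential_motif_enrichment",
]

STATE_NAMES = ("active_high", "active_low", "poised")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Coverage as a step function
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Non-negative step-function coverage per chromosome.

    Stored as sorted, non-overlapping (starts, ends, values) arrays plus a
    cumulative integral, which makes exact window means O(log n).
    """

    mark: str
    steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    _cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def add_chrom(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        order = np.argsort(starts)
        starts, ends, values = starts[order], ends[order], values[order]
        if (values < 0).any():
            raise ValueError(f"{self.mark}/{chrom}: negative coverage")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"{self.mark}/{chrom}: overlapping bedGraph steps")
        self.steps[chrom] = (starts, ends, values)
        self._cum[chrom] = np.concatenate(
            [[0.0], np.cumsum((ends - starts) * values)]
        )

    def total_mass(self) -> float:
        """Integral of coverage over the whole track (value x span)."""
        return float(sum(c[-1] for c in self._cum.values()))

    def scale_factor(self) -> float:
        """Library normalization: 1e6 / total mass (1.0 for an empty track)."""
        mass = self.total_mass()
        return 1e6 / mass if mass > 0 else 1.0

    def _integral_to(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        starts, ends, values = self.steps[chrom]
        cum = self._cum[chrom]
        i = np.searchsorted(ends, pos, side="right")
        out = cum[np.minimum(i, len(starts))]
        inside = i < len(starts)
        idx = np.where(inside, i, 0)
        partial = np.clip(pos - starts[idx], 0, ends[idx] - starts[idx]) * values[idx]
        return out + np.where(inside, partial, 0.0)

    def window_means(self, chrom: str, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """Mean coverage over [lo, hi); windows outside the track read as 0."""
        lo = np.asarray(lo, dtype=np.int64)
        hi = np.asarray(hi, dtype=np.int64)
        if chrom not in self.steps:
            return np.zeros(len(lo))
        lo_c = np.maximum(lo, 0)
        return (self._integral_to(chrom, hi) - self._integral_to(chrom, lo_c)) / (
            hi - lo
        )


def read_bedgraph(path, mark: str) -> CoverageTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    track = CoverageTrack(mark)
    for chrom, sub in df.groupby("chrom", sort=True):
        track.add_chrom(str(chrom), sub["start"].values, sub["end"].values,
                        sub["value"].values)
    return track


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.steps):
            starts, ends, values = track.steps[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Promoters and enhancers
# ---------------------------------------------------------------------------

@dataclass
class EnhancerRecord:
    interval: GenomicInterval
    summit: int
    state: str | None = None
    assigned_gene: str | None = None
    distance: int | None = None


def classify_promoter_state(
    promoter: GenomicInterval, k4me3: PeakSet, k27ac: PeakSet
) -> str:
    """H3K4me3 gates promoter marking; H3K27ac upgrades it to active."""
    has_k4 = k4me3.overlaps(promoter)
    if not has_k4:
        return "unmarked"
    return "active" if k27ac.overlaps(promoter) else "marked_only"


def call_enhancers(
    atac: PeakSet, k4me1: PeakSet, promoters: list[GenomicInterval]
) -> list[EnhancerRecord]:
    """ATAC peaks with summits outside all promoters and H3K4me1 support."""
    prom_set = PeakSet("promoters", [
        Peak(p, p.start + (len(p) - 1) // 2) for p in promoters
    ])
    out = []
    for peak in atac.records:
        summit_iv = GenomicInterval(
            peak.interval.chrom, peak.summit, peak.summit + 1
        )
        if prom_set.overlaps(summit_iv):
            continue
        if not k4me1.overlaps(peak.interval):
            continue
        out.append(EnhancerRecord(peak.interval, peak.summit))
    return out


# ---------------------------------------------------------------------------
# Signal matrices
# ---------------------------------------------------------------------------

@dataclass
class SignalMatrix:
    regions: list[EnhancerRecord]
    marks: list[str]
    window: int
    n_bins: int
    matrix: np.ndarray  # regions x (mark * bin), log2(1 + scaled coverage)
    raw: np.ndarray     # same layout, before the log transform

    def mark_slice(self, mark: str) -> slice:
        i = self.marks.index(mark)
        return slice(i * self.n_bins, (i + 1) * self.n_bins)


def build_signal_matrix(
    regions: list[EnhancerRecord],
    tracks: dict[str, CoverageTrack],
    window: int = 6000,
    n_bins: int = 60,
) -> SignalMatrix:
    """Summit-centered, library-scaled, log-transformed signal matrix.

    Regions are never strand-flipped: the profiled marks are summit-symmetric.
    """
    if window % n_bins != 0:
        raise ValueError(f"window {window} not divisible by n_bins {n_bins}")
    bw = window // n_bins
    marks = list(tracks)
    raw = np.zeros((len(regions), len(marks) * n_bins))
    half = window // 2
    for m_i, mark in enumerate(marks):
        track = tracks[mark]
        scale = track.scale_factor()
        by_chrom: dict[str, list[int]] = {}
        for r_i, r in enumerate(regions):
            by_chrom.setdefault(r.interval.chrom, []).append(r_i)
        for chrom, idxs in by_chrom.items():
            summits = np.array([regions[i].summit for i in idxs])
            for b in range(n_bins):
                lo = summits - half + b * bw
                hi = lo + bw
                vals = track.window_means(chrom, lo, hi) * scale
                raw[idxs, m_i * n_bins + b] = vals
    return SignalMatrix(list(regions), marks, window, n_bins, np.log2(1.0 + raw), raw)


def aggregate_profile(
    regions: list[EnhancerRecord],
    track: CoverageTrack,
    window: int = 6000,
    n_bins: int = 60,
) -> np.ndarray:
    """Mean summit-centered profile for one mark (column means of the matrix)."""
    if not regions:
        raise ValueError("empty region list")
    sm = build_signal_matrix(regions, {track.mark: track}, window, n_bins)
    return sm.matrix.mean(axis=0)


def cluster_enhancer_states(
    sm: SignalMatrix,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    k27ac_mark: str = "H3K27ac",
) -> list[str]:
    """K-means on the column-standardized matrix; labels renamed by
    descending mean raw H3K27ac window signal."""
    n = sm.matrix.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} regions")
    x = sm.matrix
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    z = (x - mu) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(z)

    k27 = sm.raw[:, sm.mark_slice(k27ac_mark)].mean(axis=1)
    means = []
    for c in range(k):
        mask = labels == c
        means.append(float(k27[mask].mean()) if mask.any() else -np.inf)
    # descending K27ac; ties broken by original cluster index for determinism
    order = sorted(range(k), key=lambda c: (-means[c], c))
    names = list(STATE_NAMES[:k]) + [f"state_{i}" for i in range(3, k)]
    rename = {c: names[rank] for rank, c in enumerate(order)}
    return [rename[int(c)] for c in labels]


def assign_enhancers_to_genes(
    enhancers: list[EnhancerRecord],
    transcripts: list[TranscriptModel],
    max_distance: int | None = None,
) -> list[EnhancerRecord]:
    """Closest-TSS assignment; drops the gene when beyond ``max_distance``."""
    for e in enhancers:
        hit = nearest_tss(e.summit, e.interval.chrom, transcripts)
        if hit is None:
            e.assigned_gene, e.distance = None, None
            continue
        gene, dist = hit
        if max_distance is not None and abs(dist) > max_distance:
            e.assigned_gene, e.distance = None, None
        else:
            e.assigned_gene, e.distance = gene, dist
    return enhancers


def effector_subset(
    enhancers: list[EnhancerRecord], regulated_genes: set[str]
) -> list[EnhancerRecord]:
    """Enhancers whose assigned gene is treatment-regulated."""
    return [e for e in enhancers if e.assigned_gene in regulated_genes]


# ---------------------------------------------------------------------------
# Known-motif differential enrichment
# ---------------------------------------------------------------------------

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """Position probability matrix with a log-odds score threshold.

    ``threshold`` defaults to 80% of the PWM's maximum log-odds score
    against a uniform background, mirroring common known-motif scanners.
    """

    name: str
    probs: np.ndarray  # positions x 4 (A, C, G, T)
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be positions x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.name}: PWM rows must sum to 1")
        with np.errstate(divide="ignore"):
            self.logodds = np.log2(np.maximum(self.probs, 1e-9) / 0.25)
        if self.threshold is None:
            self.threshold = 0.8 * float(self.logodds.max(axis=1).sum())

    def __len__(self) -> int:
        return self.probs.shape[0]


def read_jaspar(path) -> list[PWM]:
    """Read JASPAR-format count matrices; counts are converted to
    probabilities with a 0.01 pseudocount per base."""
    pwms = []
    name, rows = None, {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    for ln in lines + [">__end__"]:
        if ln.startswith(">"):
            if name is not None and len(rows) == 4:
                counts = np.array([rows[b] for b in "ACGT"]).T + 0.01
                pwms.append(PWM(name, counts / counts.sum(axis=1, keepdims=True)))
            name, rows = ln[1:].split()[0], {}
        else:
            base, rest = ln.split(None, 1)
            nums = rest.strip().lstrip("[").rstrip("]").split()
            rows[base[0].upper()] = [float(x) for x in nums]
    return pwms


def _scores(seq: str, pwm: PWM) -> np.ndarray:
    """Log-odds score at every start position of one strand; positions with
    N (or any non-ACGT base) score -inf."""
    L, w = len(seq), len(pwm)
    if L < w:
        return np.empty(0)
    idx = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_IDX.items():
        code[ord(b)] = i
    bases = code[idx]
    out = np.zeros(L - w + 1)
    valid = np.ones(L - w + 1, dtype=bool)
    for j in range(w):
        b = bases[j : j + L - w + 1]
        ok = b >= 0
        valid &= ok
        out += np.where(ok, pwm.logodds[j, np.where(ok, b, 0)], 0.0)
    out[~valid] = -np.inf
    return out


def scan_contains(seq: str, pwm: PWM) -> bool:
    """True iff any position on either strand scores >= the PWM threshold."""
    for s in (seq, revcomp(seq)):
        sc = _scores(s, pwm)
        if sc.size and float(sc.max()) >= pwm.threshold:
            return True
    return False


def differential_motif_enrichment(
    fg_seqs: list[str],
    bg_seqs: list[str],
    pwms: list[PWM],
    odds_cap: float = 1e6,
) -> pd.DataFrame:
    """Per-PWM 2x2 Fisher exact test of motif containment, fg vs bg.

    Infinite sample odds ratios are reported capped at ``odds_cap``.
    """
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background must be non-empty")
    rows = []
    for pwm in pwms:
        fg_k = sum(scan_contains(s, pwm) for s in fg_seqs)
        bg_k = sum(scan_contains(s, pwm) for s in bg_seqs)
        table = [[fg_k, len(fg_seqs) - fg_k], [bg_k, len(bg_seqs) - bg_k]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        if np.isnan(odds):  # degenerate table (a margin is zero): no signal
            odds = 1.0
        elif np.isinf(odds):
            odds = odds_cap
        rows.append(
            {
                "pwm": pwm.name,
                "fg_frac": fg_k / len(fg_seqs),
                "bg_frac": bg_k / len(bg_seqs),
                "odds_ratio": float(odds),
                "p_fisher": float(p),
            }
        )
    df = pd.DataFrame(rows)
    df["q_bh"] = multipletests(df["p_fisher"], method="fdr_bh")[1]
    return df


def window_sequences(
    genome: dict[str, str],
    summits: list[tuple[str, int]],
    window: int = 500,
) -> list[str]:
    """Fixed windows centered on summits, clipped at chromosome bounds."""
    half = window // 2
    out = []
    for chrom, pos in summits:
        seq = genome[chrom]
        out.append(seq[max(0, pos - half) : min(len(seq), pos + window - half)])
    return out
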