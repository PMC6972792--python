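"""PWM scanning and motif-level filtering.

A :class:`PWM` is a position probability matrix with background base
frequencies and a log-odds threshold (natural log). Scanning reports every
position on both strands scoring at or above the threshold; downstream
filters reproduce the analysis' motif accounting: mappability/blacklist
filtering of 200-bp motif-centered regions, "no-signal" (never-bound) motif
flagging from ChIP coverage, CpG-core (CGGAA) classification for the
methylation analysis, and word-matched random control sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .tracks import SignalTrack

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

PSEUDOCOUNT = 1e-3  # added to probabilities before log-odds


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to codes 0..3 (A,C,G,T); anything else -> 4 (N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    """Position probability matrix with background and log-odds threshold.

    ``core_offset`` marks the 0-based start of the biological core (GGAA for
    an ETS factor) within the motif; it drives the CpG-core classification.
    """

    name: str
    probs: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float = 0.0
    core_offset: int | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be a width x 4 matrix")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM row must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """width x 5 natural-log odds matrix; column 4 (N) is the row minimum,
        so N-containing windows effectively fail thresholds."""
        p = self.probs + PSEUDOCOUNT
        p = p / p.sum(axis=1, keepdims=True)
        b = self.background + PSEUDOCOUNT
        b = b / b.sum()
        lo = np.log(p / b)
        return np.column_stack([lo, lo.min(axis=1)])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            threshold=self.threshold,
            core_offset=None,
        )

    # -- file format -------------------------------------------------------
    # one header line: >name core_offset=K threshold=T
    # then `width` rows of four tab-separated probabilities (A C G T)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            parts = [f">{self.name}"]
            if self.core_offset is not None:
                parts.append(f"core_offset={self.core_offset}")
            parts.append(f"threshold={self.threshold:.6g}")
            fh.write(" ".join(parts) + "\n")
            for row in self.probs:
                fh.write("\t".join(f"{p:.6f}" for p in row) + "\n")

    @classmethod
    def read(cls, path: str) -> "PWM":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith(">"):
                raise ValueError("PWM file must start with a '>' header line")
            fields = header[1:].split()
            name = fields[0]
            kw = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
            rows = [list(map(float, line.split())) for line in fh if line.strip()]
        probs = np.array(rows)
        probs = probs / probs.sum(axis=1, keepdims=True)
        return cls(
            name=name,
            probs=probs,
            threshold=float(kw.get("threshold", 0.0)),
            core_offset=int(kw["core_offset"]) if "core_offset" in kw else None,
        )


def score_sequence(pwm: PWM, seq: str) -> float:
    """Natural-log odds score of ``seq`` (length = motif width) under ``pwm``."""
    if len(seq) != pwm.width:
        raise ValueError(f"sequence length {len(seq)} != motif width {pwm.width}")
    codes = encode(seq)
    return float(pwm.log_odds[np.arange(pwm.width), codes].sum())


def scan_genome(pwm: PWM, genome: dict[str, str],
                threshold: float | None = None) -> IntervalSet:
    """Scan both strands of every chromosome; report matches >= threshold.

    Minus-strand matches are scored on the reverse complement and reported
    in reference coordinates; overlapping opposite-strand matches are both
    kept. Returns an IntervalSet with ``strand``, ``score``, ``name``.
    """
    if threshold is None:
        threshold = pwm.threshold
    w = pwm.width
    lod = {"+": pwm.log_odds, "-": pwm.reverse_complement().log_odds}
    records = []
    for chrom in genome:
        codes = encode(genome[chrom])
        n = len(codes)
        if n < w:
            continue
        for strand in "+-":
            L = lod[strand]
            scores = np.zeros(n - w + 1)
            for j in range(w):
                scores += L[j, codes[j : n - w + 1 + j]]
            for i in np.flatnonzero(scores >= threshold):
                records.append((chrom, int(i), int(i) + w, pwm.name,
                                float(scores[i]), strand))
    out = IntervalSet.from_records(
        records, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return out.sort()


def extract_words(matches: IntervalSet, genome: dict[str, str]) -> pd.Series:
    """Motif-oriented nucleotide sequence ("word") under each match."""
    words = []
    for row in matches.df.itertuples(index=False):
        seq = genome[row.chrom][int(row.start): int(row.end)]
        if getattr(row, "strand", "+") == "-":
            seq = reverse_complement(seq)
        words.append(seq)
    return pd.Series(words, index=matches.df.index, name="word")


def motif_regions(matches: IntervalSet, size: int = 200) -> IntervalSet:
    """Motif-centered fixed-size regions (attributes carried through)."""
    half = size // 2
    df = matches.df.copy()
    centers = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    df["start"] = np.maximum(centers - half, 0)
    df["end"] = centers - half + size
    return IntervalSet(df, validate=False)


def mappability_filter(matches: IntervalSet, mappability: SignalTrack,
                       blacklist: IntervalSet, region_size: int = 200,
                       min_mappability: float = 0.8) -> IntervalSet:
    """Keep matches whose 200-bp centered region avoids the blacklist and has
    mean mappability >= the cutoff. Original match coordinates are returned."""
    if not len(matches):
        return matches
    regions = motif_regions(matches, size=region_size)
    keep = ~regions._overlap_mask(blacklist)
    means = np.zeros(len(matches))
    df = regions.df
    for chrom in df["chrom"].unique():
        sel = (df["chrom"] == chrom).to_numpy()
        arr_len = len(mappability[chrom])
        s = np.clip(df.loc[sel, "start"].to_numpy(), 0, arr_len)
        e = np.clip(df.loc[sel, "end"].to_numpy(), 0, arr_len)
        widths = np.maximum(e - s, 1)
        means[sel] = mappability.interval_sums(chrom, s, e) / widths
    keep &= means >= min_mappability
    return matches.select(keep)


def no_signal_motifs(matches: IntervalSet, chip_tracks: list[SignalTrack],
                     window: int = 200, max_normalized: float = 3.0) -> np.ndarray:
    """Flag motifs with no ChIP evidence in any profiled sample.

    A motif is "no-signal" iff its tags-per-10^7 count in a motif-centered
    ``window`` is <= ``max_normalized`` in every track. Counts strictly above
    the boundary in any one sample remove the motif from the unbound universe.
    """
    flags = np.ones(len(matches), dtype=bool)
    centers = matches.centers()
    chroms = matches.df["chrom"].to_numpy()
    for track in chip_tracks:
        if track.library_size is None:
            raise ValueError("ChIP tracks must carry a library size")
        counts = np.zeros(len(matches))
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            counts[sel] = track.window_sums(chrom, centers[sel], window)
        flags &= counts * track.norm_scale <= max_normalized
    return flags


def classify_cpg_core(matches: IntervalSet, genome: dict[str, str],
                      core_offset: int, core: str = "GGAA",
                      pair_radius: int = 150) -> pd.DataFrame:
    """CpG-core (CGGAA) classification for the methylation analysis.

    ``cpg_core`` is true iff the sense-strand word carries a CG immediately
    5' of the core (pattern C+core at ``core_offset - 1``). ``meth_set``
    marks motifs admissible for the methylation analysis: those without a
    second motif match within ``pair_radius`` bp (where ChIP signal could
    derive from the unmethylated neighbor).
    """
    if core_offset is None or core_offset < 1:
        raise ValueError(
            "core offset must be a PWM annotation >= 1 to locate the CpG position"
        )
    words = extract_words(matches, genome)
    pattern = "C" + core
    cpg = words.str.slice(core_offset - 1, core_offset - 1 + len(pattern)) == pattern
    # neighbor exclusion: any other match within pair_radius (start distance)
    df = matches.df
    paired = np.zeros(len(df), dtype=bool)
    srt = df.sort_values(["chrom", "start"], kind="mergesort")
    idx = srt.index.to_numpy()
    chroms = srt["chrom"].to_numpy()
    starts = srt["start"].to_numpy()
    for i in range(1, len(srt)):
        if chroms[i - 1] == chroms[i] and starts[i] - starts[i - 1] <= pair_radius:
            paired[idx[i]] = paired[idx[i - 1]] = True
    return pd.DataFrame(
        {"cpg_core": cpg.to_numpy(), "meth_set": ~paired}, index=df.index
    )


def matched_control_sample(targets: IntervalSet, pool: IntervalSet,
                           genome: dict[str, str], seed: int):
    """Word-matched random control sampling from the no-signal pool.

    For each distinct word among the targets with multiplicity ``k``, sample
    ``min(k, available)`` pool matches carrying that exact word, uniformly
    without replacement. Returns ``(controls, shortfall)`` where shortfall
    maps word -> number of missing controls.
    """
    rng = np.random.default_rng(seed)
    target_words = extract_words(targets, genome)
    pool_words = extract_words(pool, genome)
    pool_groups = {
        w: g.index.to_numpy() for w, g in pool.df.groupby(pool_words, sort=True)
    }
    chosen: list[int] = []
    shortfall: dict[str, int] = {}
    for word, k in target_words.value_counts().sort_index().items():
        avail = pool_groups.get(word, np.array([], dtype=int))
        take = min(int(k), len(avail))
        if take:
            chosen.extend(rng.choice(avail, size=take, replace=False).tolist())
        if take < k:
            shortfall[word] = int(k) - take
    controls = IntervalSet(pool.df.loc[sorted(chosen)], validate=False)
    return controls, shortfall
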