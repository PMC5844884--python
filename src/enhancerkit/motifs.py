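"""PWM scanning of enhancer-center windows and Fisher enrichment.

Windows of +/- 2 kb around enhancer midpoints are scanned on both
strands with a log-odds position weight matrix; enrichment of a motif in
a target window set against background windows is a one-sided Fisher
exact test on window-level presence/absence (a window is a "hit" iff it
contains at least one match), the unit used by motif-enrichment tools
such as AME.

Two E-box matrices ship with the package (``data/``): the canonical MYC
E-box CACGTG and a non-canonical variant. Both are synthetic consensus-
derived matrices built for the simulation, not measured binding models.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

from .intervals import Interval

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position weight matrix with background and a log-odds threshold."""

    name: str
    probs: np.ndarray  # (L, 4) position x base probabilities
    background: np.ndarray = None
    threshold: float | None = None  # log2-odds; default 80% of max score

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if len(self.probs) < 4:
            raise ValueError("PWM must have length >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if self.threshold is None:
            self.threshold = 0.8 * self.max_score()

    def __len__(self) -> int:
        return len(self.probs)

    def log_odds(self, pseudo: float = 1e-9) -> np.ndarray:
        return np.log2((self.probs + pseudo) / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.name, self.probs[::-1, ::-1].copy(), self.background[::-1].copy(),
            self.threshold,
        )

    @classmethod
    def from_file(cls, path: str | Path, threshold: float | None = None) -> "PWM":
        """Read a tab-separated matrix: header '>name', then one row per
        position with 4 probabilities (or counts, normalized on load)."""
        lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        if not lines or not lines[0].startswith(">"):
            raise ValueError("PWM file must start with a '>name' header")
        name = lines[0][1:].strip()
        rows = [[float(x) for x in ln.split("\t")] for ln in lines[1:]]
        mat = np.asarray(rows, dtype=float)
        mat = mat / mat.sum(axis=1, keepdims=True)
        return cls(name, mat, threshold=threshold)


def bundled_pwm(which: str) -> PWM:
    """Load a PWM shipped with the package ('ebox_canonical' or
    'ebox_noncanonical')."""
    ref = resources.files("enhancerkit").joinpath(f"data/{which}.pwm")
    with resources.as_file(ref) as path:
        return PWM.from_file(path)


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    codes = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    known = np.isin(arr, [ord(c) for c in "ACGTN"])
    if not known.all():
        bad = chr(arr[~known][0])
        raise ValueError(f"invalid base {bad!r} in sequence")
    return codes


def scan(sequence: str, pwm: PWM) -> list[tuple[int, str]]:
    """Log-odds scan on both strands; (position, strand) per hit.

    Positions are 0-based starts of the match on the forward strand; any
    window containing N never matches.
    """
    L = len(pwm)
    if len(sequence) < L:
        return []
    codes = _encode(sequence)
    hits: list[tuple[int, str]] = []
    for strand, matrix in (("+", pwm), ("-", pwm.reverse_complement())):
        lut = np.hstack([matrix.log_odds(), np.full((L, 1), -np.inf)])  # N column
        n_pos = len(codes) - L + 1
        scores = np.zeros(n_pos)
        for j in range(L):
            scores += lut[j, codes[j : j + n_pos]]
        for pos in np.flatnonzero(scores >= pwm.threshold):
            hits.append((int(pos), strand))
    return sorted(hits)


def extract_center_windows(
    regions: list[Interval], chrom_lengths: dict[str, int], flank: int = 2000
) -> list[Interval]:
    """[mid - flank, mid + flank) windows, clipped to chromosome bounds."""
    out = []
    for region in regions:
        if region.chromosome not in chrom_lengths:
            raise KeyError(f"unknown chromosome {region.chromosome!r}")
        length = chrom_lengths[region.chromosome]
        mid = region.midpoint
        if not (0 <= mid < length):
            raise ValueError(f"region midpoint {mid} outside chromosome")
        out.append(
            Interval(region.chromosome, max(0, mid - flank), min(length, mid + flank))
        )
    return out


def window_sequences(
    windows: list[Interval], sequences: dict[str, str]
) -> list[str]:
    return [sequences[w.chromosome][w.start : w.end] for w in windows]


def enrichment(
    target_seqs: list[str], background_seqs: list[str], pwm: PWM
) -> dict:
    """One-sided Fisher exact enrichment of motif-bearing windows.

    fold = target hit fraction / background hit fraction; infinite when
    the background fraction is 0 but targets hit, 1 when both are 0.
    """
    if not target_seqs or not background_seqs:
        raise ValueError("both window sets must be non-empty")
    t_hits = sum(1 for s in target_seqs if scan(s, pwm))
    b_hits = sum(1 for s in background_seqs if scan(s, pwm))
    nt, nb = len(target_seqs), len(background_seqs)
    table = [[t_hits, nt - t_hits], [b_hits, nb - b_hits]]
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    tf, bf = t_hits / nt, b_hits / nb
    if bf == 0:
        fold = 1.0 if tf == 0 else float("inf")
    else:
        fold = tf / bf
    return {
        "motif": pwm.name,
        "target_hits": t_hits,
        "target_n": nt,
        "background_hits": b_hits,
        "background_n": nb,
        "fold": fold,
        "p_value": p,
    }
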