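"""PFM/PWM handling, promoter extraction, and min-max relative-score scanning.

A position frequency matrix (PFM) of base counts is converted to a
log2-odds position weight matrix (PWM) against a uniform background,
with a pseudocount distributed by the background. A window is a "hit"
when its min-max-normalized PWM score reaches the threshold (default
0.8, the "80% maximum accuracy" convention); an alternative
fraction-of-maximum normalization is available behind ``mode``.
Coordinates are 0-based half-open; reverse-strand hits are reported on
forward coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PFM:
    """Position frequency matrix: 4 x L base counts (rows A, C, G, T)."""

    name: str
    counts: np.ndarray
    matrix_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.ndim != 2 or self.counts.shape[1] < 1:
            raise ValueError(f"PFM {self.name!r}: counts must be 4 x L with L >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"PFM {self.name!r}: counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"PFM {self.name!r}: every column needs positive total count")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))

    def pwm(self, pseudocount: float = 0.8, background: float = 0.25) -> np.ndarray:
        """log2 odds against the background, pseudocount split by background."""
        pc = pseudocount * background
        probs = (self.counts + pc) / (self.counts.sum(axis=0) + 4 * pc)
        return np.log2(probs / background)


@dataclass
class MotifHit:
    """One motif occurrence; ``start`` is 0-based on forward coordinates."""

    tf: str
    seq_id: str
    start: int
    strand: str
    score: float
    relative_score: float


@dataclass
class ScanResult:
    """Hit list plus the tally of windows skipped for non-ACGT characters."""

    hits: list[MotifHit] = field(default_factory=list)
    n_skipped_windows: int = 0

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def _encode(seq: str) -> np.ndarray:
    buf = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(seq), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[buf == ord(b)] = i
    return out


def _window_scores(pwm: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all windows; invalid windows (non-ACGT) flagged."""
    L = pwm.shape[1]
    n = len(idx) - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        col = idx[j:j + n]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, pwm[np.clip(col, 0, 3), j], 0.0)
    return scores, valid


def scan(pfm: PFM, sequence: str, seq_id: str = "", threshold: float = 0.8,
         pseudocount: float = 0.8, background: float = 0.25,
         mode: str = "minmax") -> ScanResult:
    """Scan both strands of ``sequence`` for PFM hits.

    A window is a hit when its normalized score reaches ``threshold``;
    ``mode='minmax'`` normalizes (score - min) / (max - min) over the
    per-column extrema, ``mode='maxfrac'`` uses score / max. Windows
    containing non-ACGT characters are skipped and tallied.
    """
    if len(sequence) < pfm.length:
        raise ValueError(
            f"sequence {seq_id!r} shorter than motif {pfm.name!r} ({pfm.length} bp)")
    if mode not in ("minmax", "maxfrac"):
        raise ValueError(f"unknown scan mode {mode!r}")
    pwm = pfm.pwm(pseudocount=pseudocount, background=background)
    max_score = pwm.max(axis=0).sum()
    min_score = pwm.min(axis=0).sum()

    def rel(scores: np.ndarray) -> np.ndarray:
        if mode == "minmax":
            denom = max_score - min_score
            return (scores - min_score) / denom if denom > 0 else np.ones_like(scores)
        return scores / max_score if max_score != 0 else np.ones_like(scores)

    result = ScanResult()
    n_seq = len(sequence)
    L = pfm.length
    for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
        idx = _encode(seq)
        scores, valid = _window_scores(pwm, idx)
        result.n_skipped_windows += int((~valid).sum())
        relative = rel(scores)
        for pos in np.nonzero(valid & (relative >= threshold))[0]:
            start = int(pos) if strand == "+" else n_seq - int(pos) - L
            result.hits.append(MotifHit(
                tf=pfm.name, seq_id=seq_id, start=start, strand=strand,
                score=float(scores[pos]), relative_score=float(relative[pos])))
    result.hits.sort(key=lambda h: (h.start, h.strand))
    return result


def extract_promoter(sequence: str, tss: int, strand: str,
                     upstream: int = 1000, downstream: int = 200) -> str:
    """Strand-aware promoter window around a TSS.

    ``+`` strand: [tss - upstream, tss + downstream); ``-`` strand:
    reverse complement of [tss - downstream, tss + upstream). Windows
    are truncated at sequence ends with a warning.
    """
    n = len(sequence)
    if not 0 <= tss < n:
        raise ValueError(f"TSS {tss} outside sequence of length {n}")
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
    elif strand == "-":
        lo, hi = tss - downstream, tss + upstream
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    clo, chi = max(lo, 0), min(hi, n)
    if (clo, chi) != (lo, hi):
        warnings.warn(
            f"promoter window [{lo}, {hi}) truncated to [{clo}, {chi}) at "
            f"sequence bounds", stacklevel=2)
    window = sequence[clo:chi]
    return reverse_complement(window) if strand == "-" else window


def build_prior(pfms: dict[str, PFM], promoters: dict[str, str | None],
                threshold: float = 0.8, **scan_kwargs) -> pd.DataFrame:
    """TF x gene matrix of promoter hit counts (the regulatory prior)."""
    genes = []
    for g, seq in promoters.items():
        if seq is None:
            logger.warning("gene %s has no promoter sequence; excluded from prior", g)
        else:
            genes.append(g)
    prior = pd.DataFrame(0, index=pd.Index(pfms.keys(), name="tf"),
                         columns=pd.Index(genes, name="gene"), dtype=int)
    pseudocount = scan_kwargs.get("pseudocount", 0.8)
    background = scan_kwargs.get("background", 0.25)
    mode = scan_kwargs.get("mode", "minmax")
    encoded = {g: (_encode(promoters[g]),
                   _encode(reverse_complement(promoters[g]))) for g in genes}
    for t, pfm in pfms.items():
        pwm = pfm.pwm(pseudocount=pseudocount, background=background)
        max_s, min_s = pwm.max(axis=0).sum(), pwm.min(axis=0).sum()
        for g in genes:
            n_hits = 0
            for idx in encoded[g]:
                scores, valid = _window_scores(pwm, idx)
                if mode == "minmax":
                    relative = (scores - min_s) / (max_s - min_s)
                else:
                    relative = scores / max_s
                n_hits += int((valid & (relative >= threshold)).sum())
            prior.loc[t, g] = n_hits
    return prior
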