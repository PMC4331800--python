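"""Composite host-σ70 promoter model: -35/-10 (and optional -15) weight
matrices plus a spacer-length score, normalised so that the consensus
configuration (TTGACA, 17 bp spacer, TATAAT) scores exactly zero and every
other configuration scores below zero.

Score values are provisional by construction (they depend on the training
alignment); the reproducible signal is the *strand bias* of predictions on a
divergently organised phage genome: a reporting threshold is chosen as the
most permissive score at which no promoter is predicted on the "+"
(structural) strand, leaving predictions only upstream of / within the
functional "-" cluster where early transcription by host RNA polymerase is
expected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from ._seq import BASES, encode, revcomp
from .genome_io import GenomeRecord

logger = logging.getLogger(__name__)

ELEMENT_LEN = 6
MINUS15_LEN = 4
OPTIMAL_SPACER = 17


@dataclass(frozen=True)
class TrainingPromoter:
    minus35: str
    spacer_len: int
    minus10: str
    minus15: str | None = None


@dataclass
class PromoterModel:
    """Consensus-zero composite promoter scoring model.

    ``pwm_35``/``pwm_10`` are (6, 4) log-odds matrices with the per-column
    maximum shifted to 0, so the consensus hexamers score 0 and any
    substitution scores < 0.  ``spacer_score`` maps spacer length to
    log(freq(l)/freq(17)); lengths outside the support are excluded
    (effectively -inf).  ``pwm_15`` is an optional (4, 4) matrix for the
    conserved region immediately 5' of the -10 element.
    """

    pwm_35: np.ndarray
    pwm_10: np.ndarray
    spacer_score: dict[int, float]
    pwm_15: np.ndarray | None = None
    warning: str | None = None

    @property
    def consensus_35(self) -> str:
        return "".join(BASES[i] for i in self.pwm_35.argmax(axis=1))

    @property
    def consensus_10(self) -> str:
        return "".join(BASES[i] for i in self.pwm_10.argmax(axis=1))

    @property
    def spacer_support(self) -> list[int]:
        return sorted(self.spacer_score)


@dataclass(frozen=True)
class SigmaPromoterPrediction:
    minus35: str
    spacer_length: int
    minus10: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: Literal["+", "-"]
    score: float


def _logodds(seqs: Sequence[str], width: int, pseudocount: float, background: np.ndarray) -> np.ndarray:
    counts = np.full((width, 4), pseudocount, dtype=float)
    for s in seqs:
        si = encode(s)
        if len(s) != width or (si >= 4).any():
            raise ValueError(f"training element {s!r} must be {width} bp of ACGT")
        counts[np.arange(width), si] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    lo = np.log(freqs / background[None, :])
    return lo - lo.max(axis=1, keepdims=True)  # per-column max -> 0


def build_promoter_model(
    training: Sequence[TrainingPromoter],
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
    spacer_support: tuple[int, int] = (15, 20),
) -> PromoterModel:
    """Fit the composite model from an aligned promoter training set."""
    if len(training) < 10:
        raise ValueError("need >= 10 training promoters")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    lo, hi = spacer_support
    for t in training:
        if not lo <= t.spacer_len <= hi:
            raise ValueError(
                f"spacer length {t.spacer_len} outside support {lo}..{hi}"
            )
    pwm_35 = _logodds([t.minus35 for t in training], ELEMENT_LEN, pseudocount, bg)
    pwm_10 = _logodds([t.minus10 for t in training], ELEMENT_LEN, pseudocount, bg)
    pwm_15 = None
    if all(t.minus15 for t in training):
        pwm_15 = _logodds([t.minus15 for t in training], MINUS15_LEN, pseudocount, bg)  # type: ignore[misc]
    counts: dict[int, int] = {}
    for t in training:
        counts[t.spacer_len] = counts.get(t.spacer_len, 0) + 1
    warning = None
    if OPTIMAL_SPACER in counts:
        ref = counts[OPTIMAL_SPACER]
    else:
        ref = max(counts.values())
        warning = (
            "no 17 bp spacer in training; spacer score normalised at the "
            "modal length instead of the canonical optimum"
        )
        logger.warning(warning)
    spacer_score = {l: float(np.log(c / ref)) for l, c in counts.items()}
    return PromoterModel(pwm_35, pwm_10, spacer_score, pwm_15, warning)


def score_window(window: str, spacer: int, model: PromoterModel) -> float | None:
    """Score a 6 + spacer + 6 window; None for non-ACGT content."""
    if spacer not in model.spacer_score:
        raise ValueError(f"spacer {spacer} outside model support {model.spacer_support}")
    if len(window) != 2 * ELEMENT_LEN + spacer:
        raise ValueError("window length must be 12 + spacer")
    si = encode(window)
    if (si >= 4).any():
        return None
    idx = np.arange(ELEMENT_LEN)
    total = float(model.pwm_35[idx, si[:ELEMENT_LEN]].sum())
    total += float(model.pwm_10[idx, si[ELEMENT_LEN + spacer :]].sum())
    total += model.spacer_score[spacer]
    if model.pwm_15 is not None:
        m15 = si[ELEMENT_LEN + spacer - MINUS15_LEN : ELEMENT_LEN + spacer]
        total += float(model.pwm_15[np.arange(MINUS15_LEN), m15].sum())
    return total


def _element_scores(si: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Vectorised sliding-window PWM sums; positions with ambiguity -> -inf."""
    w = pwm.shape[0]
    n = len(si) - w + 1
    if n <= 0:
        return np.empty(0)
    out = np.zeros(n)
    ok = np.ones(n, dtype=bool)
    for k in range(w):
        col = si[k : k + n]
        bad = col >= 4
        ok &= ~bad
        out += np.where(bad, 0.0, pwm[k][np.minimum(col, 3)])
    out[~ok] = -np.inf
    return out


def _scan_strand(seq: str, model: PromoterModel) -> list[tuple[int, int, float]]:
    """All (start0, spacer, score) decompositions on one strand, best spacer
    kept per start."""
    si = encode(seq)
    s35 = _element_scores(si, model.pwm_35)
    s10 = _element_scores(si, model.pwm_10)
    s15 = _element_scores(si, model.pwm_15) if model.pwm_15 is not None else None
    best: dict[int, tuple[float, int]] = {}
    for spacer, sp_score in model.spacer_score.items():
        width = 2 * ELEMENT_LEN + spacer
        n = len(seq) - width + 1
        if n <= 0:
            continue
        tot = s35[:n] + s10[ELEMENT_LEN + spacer : ELEMENT_LEN + spacer + n] + sp_score
        if s15 is not None:
            off = ELEMENT_LEN + spacer - MINUS15_LEN
            tot = tot + s15[off : off + n]
        for i in np.nonzero(np.isfinite(tot))[0]:
            sc = float(tot[i])
            if i not in best or sc > best[i][0] or (
                sc == best[i][0] and spacer < best[i][1]
            ):
                best[int(i)] = (sc, spacer)
    return [(i, sp, sc) for i, (sc, sp) in sorted(best.items())]


def scan_genome(
    genome: GenomeRecord | str,
    model: PromoterModel,
    threshold: float,
    strands: str = "both",
    offset: int = 0,
) -> list[SigmaPromoterPrediction]:
    """Scan a genome (or sequence slice) for promoter windows scoring >=
    ``threshold`` (which must be finite and <= 0).

    Every window is reported with its best spacer decomposition; overlapping
    same-strand predictions (by > 50% of the shorter interval) are merged to
    the best-scoring one.  ``offset`` shifts reported coordinates when
    scanning a slice of a larger genome (0-based offset of the slice).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if threshold > 0:
        raise ValueError("threshold must be <= 0 (scores never exceed 0)")
    seq = genome.sequence if isinstance(genome, GenomeRecord) else str(genome).upper()
    n = len(seq)
    preds: list[SigmaPromoterPrediction] = []
    strand_list = ["+", "-"] if strands == "both" else [strands]
    for strand in strand_list:
        s = seq if strand == "+" else revcomp(seq)
        for i, spacer, sc in _scan_strand(s, model):
            if sc < threshold:
                continue
            width = 2 * ELEMENT_LEN + spacer
            if strand == "+":
                start = offset + i + 1
            else:
                start = offset + (n - (i + width)) + 1
            end = start + width - 1
            m35 = s[i : i + ELEMENT_LEN]
            m10 = s[i + ELEMENT_LEN + spacer : i + width]
            preds.append(
                SigmaPromoterPrediction(m35, spacer, m10, start, end, strand, sc)  # type: ignore[arg-type]
            )
    return merge_overlapping(preds)


def merge_overlapping(
    preds: Sequence[SigmaPromoterPrediction], frac: float = 0.5
) -> list[SigmaPromoterPrediction]:
    """Keep the best-scoring of same-strand predictions overlapping by more
    than ``frac`` of the shorter interval."""
    kept: list[SigmaPromoterPrediction] = []
    for p in sorted(preds, key=lambda q: (-q.score, q.start, q.strand)):
        clash = False
        for q in kept:
            if q.strand != p.strand:
                continue
            ov = min(p.end, q.end) - max(p.start, q.start) + 1
            shorter = min(p.end - p.start, q.end - q.start) + 1
            if ov > frac * shorter:
                clash = True
                break
        if not clash:
            kept.append(p)
    kept.sort(key=lambda q: (q.start, q.strand))
    return kept


def predictions_to_tsv(preds: Sequence[SigmaPromoterPrediction], path: str) -> None:
    """Write predictions as a table (−35, spacer, −10, interval, strand,
    score), mirroring the usual promoter-table layout."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "minus35": p.minus35,
                "spacer_length": p.spacer_length,
                "minus10": p.minus10,
                "start": p.start,
                "end": p.end,
                "strand": p.strand,
                "score": p.score,
            }
            for p in preds
        ]
    ).to_csv(path, sep="\t", index=False)


def load_training_tsv(path: str) -> list[TrainingPromoter]:
    """Read a training alignment: minus35 <TAB> spacer_len <TAB> minus10
    [<TAB> minus15], comments with '#'."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    out = []
    for row in df.itertuples(index=False):
        m15 = str(row[3]).upper() if len(row) > 3 and isinstance(row[3], str) else None
        out.append(TrainingPromoter(str(row[0]).upper(), int(row[1]), str(row[2]).upper(), m15))
    return out


def threshold_by_strand_bias(
    preds: Sequence[SigmaPromoterPrediction],
    required_minus: int | None = None,
    max_plus: int = 0,
) -> tuple[float, int, int, str | None]:
    """Choose the reporting threshold from the strand bias of the scores.

    With ``required_minus=None`` the most permissive threshold keeping at
    most ``max_plus`` "+"-strand predictions is returned (anchored at an
    observed "-"-strand score so it is attainable).  When a target
    "-"-strand count is given, the threshold is placed at the
    ``required_minus``-th best "-"-strand score instead - the "there is a
    threshold so that k promoters are predicted on '-' and none on '+'"
    reading - provided that still keeps "+"-strand calls within ``max_plus``;
    otherwise the best achievable threshold is returned with a warning.

    Returns ``(threshold, n_minus, n_plus, warning)``.
    """
    if not preds:
        raise ValueError("no scored predictions")
    plus = sorted((p.score for p in preds if p.strand == "+"), reverse=True)
    minus = sorted((p.score for p in preds if p.strand == "-"), reverse=True)
    # score that must be excluded: the (max_plus+1)-th best plus score
    cut = plus[max_plus] if len(plus) > max_plus else -np.inf
    eligible = [s for s in minus if s > cut]
    warning = None
    if eligible:
        if required_minus is not None and len(eligible) >= required_minus:
            threshold = eligible[required_minus - 1]
        else:
            threshold = eligible[-1]
            if required_minus is not None:
                warning = (
                    f"only {len(eligible)} '-'-strand predictions achievable "
                    f"with <= {max_plus} '+'-strand predictions "
                    f"(required {required_minus})"
                )
    else:
        threshold = float(np.nextafter(cut, 0.0)) if np.isfinite(cut) else 0.0
        warning = "no '-'-strand prediction above the '+'-strand cut"
    n_minus = sum(1 for s in minus if s >= threshold)
    n_plus = sum(1 for s in plus if s >= threshold)
    return float(threshold), n_minus, n_plus, warning
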