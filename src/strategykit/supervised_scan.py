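"""Supervised core-motif scanning and promoter classification.

Once pairwise alignment has revealed the conserved promoter repeat, its core
hexamer (consensus ``TGATGT``) is used to sweep all intergenic regions for
additional copies that the initial alignment missed because their conserved
stretch is shorter.  Candidate 12-bp windows (2 bp left flank + core + 4 bp
right flank) are scored against a profile built from the initially discovered
long motifs, with an exact score-distribution p-value, and partitioned into
two promoter classes:

* ``late_long``  - windows opening with (near-)``TG`` and closing with the
  extra ``TATA`` element; these sit upstream of the structural gene cluster
  and are taken to drive late transcription.
* ``middle_short`` - core-only windows lacking ``TATA``, driving the middle
  temporal class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from ._seq import BASES, encode, is_acgt
from .intergenic import IntergenicRegion

logger = logging.getLogger(__name__)

CORE = "TGATGT"
WINDOW_LEN = 12
LEFT_FLANK = 2
RIGHT_FLANK = 4


@dataclass
class LogoMatrix:
    """Per-position nucleotide frequencies (rows sum to 1) over A,C,G,T."""

    freqs: np.ndarray  # shape (L, 4)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError("freqs must be (L, 4)")
        if not np.allclose(self.freqs.sum(axis=1), 1.0):
            raise ValueError("frequencies must sum to 1 per position")

    def __len__(self) -> int:
        return self.freqs.shape[0]

    @property
    def information(self) -> np.ndarray:
        """Information content per position: IC = 2 - H (bits), no
        small-sample correction."""
        f = self.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + terms.sum(axis=1)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))


@dataclass(frozen=True)
class CandidateWindow:
    """A 12-bp window whose core positions match the scanned core."""

    region: IntergenicRegion
    window: str
    local_offset: int  # 0-based offset of the window start in the region
    genomic_coordinate: int  # forward-strand coordinate of the window start


@dataclass(frozen=True)
class PromoterMotif:
    """A classified phage promoter candidate.

    ``genomic_coordinate`` follows the reporting convention of the discovery
    tables: the 5' end of the ``TG`` segment (window start) for long motifs
    and the 5' end of the core for short motifs.
    """

    downstream_gene: int
    sequence: str
    genomic_coordinate: int
    promoter_class: Literal["late_long", "middle_short"]
    strand: Literal["+", "-"]
    pvalue: float | None = None


def core_scan(
    regions: Sequence[IntergenicRegion],
    core: str = CORE,
    max_core_mismatch: int = 0,
) -> list[CandidateWindow]:
    """Find every direct-strand window whose positions 3-8 match the core.

    Windows truncated by a region edge, or containing non-ACGT bases, are
    skipped (and counted in the log).
    """
    if len(core) < 4:
        raise ValueError("core must be >= 4 bp")
    core_i = encode(core)
    skipped = 0
    out: list[CandidateWindow] = []
    for region in regions:
        seq = region.sequence
        si = encode(seq)
        n = len(seq)
        for pos in range(n - len(core) + 1):
            seg = si[pos : pos + len(core)]
            if (seg >= 4).any():
                continue
            if int((seg != core_i).sum()) > max_core_mismatch:
                continue
            w0 = pos - LEFT_FLANK
            w1 = pos + len(core) + RIGHT_FLANK
            if w0 < 0 or w1 > n:
                skipped += 1
                continue
            window = seq[w0:w1]
            if not is_acgt(window):
                skipped += 1
                continue
            out.append(
                CandidateWindow(
                    region=region,
                    window=window,
                    local_offset=w0,
                    genomic_coordinate=region.to_genomic(w0),
                )
            )
    if skipped:
        logger.info("core_scan skipped %d truncated/ambiguous windows", skipped)
    return out


def information_content(sequences: Sequence[str]) -> LogoMatrix:
    """Raw-frequency logo matrix from equal-length aligned sequences."""
    if not sequences:
        raise ValueError("need at least one sequence")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must have equal length")
    counts = np.zeros((L, 4))
    for s in sequences:
        si = encode(s)
        if (si >= 4).any():
            raise ValueError(f"non-ACGT base in {s!r}")
        counts[np.arange(L), si] += 1
    return LogoMatrix(counts / counts.sum(axis=1, keepdims=True))


def build_profile(sequences: Sequence[str], pseudocount: float = 0.5) -> LogoMatrix:
    """Pseudocounted frequency profile for scoring (default +0.5/nucleotide)."""
    raw = information_content(sequences)
    counts = raw.freqs * len(sequences) + pseudocount
    return LogoMatrix(counts / counts.sum(axis=1, keepdims=True))


def _llr_scores(profile: LogoMatrix, background: np.ndarray) -> np.ndarray:
    if (profile.freqs == 0).any():
        raise ValueError("degenerate profile: zero frequencies (use a pseudocount)")
    return np.log(profile.freqs / background[None, :])


def window_score(window: str, profile: LogoMatrix, background=None) -> float:
    bg = _background_array(background)
    si = encode(window)
    if len(window) != len(profile) or (si >= 4).any():
        raise ValueError("window must be ACGT and match the profile length")
    llr = _llr_scores(profile, bg)
    return float(llr[np.arange(len(profile)), si].sum())


def _background_array(background) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    return bg / bg.sum()


def window_pvalue(window: str, profile: LogoMatrix, background=None) -> float:
    """Exact p-value of a window's log-likelihood-ratio score.

    The null draws each of the L positions i.i.d. from the background; the
    full score distribution is computed by dynamic programming over positions
    on a discretised score grid, and p = P[score >= observed].
    """
    bg = _background_array(background)
    llr = _llr_scores(profile, bg)
    window_score(window, profile, bg)  # validates the window
    scale = 1000.0  # 1e-3 score resolution
    illr = np.round(llr * scale).astype(np.int64)
    lo = int(illr.min(axis=1).sum())
    hi = int(illr.max(axis=1).sum())
    dist = np.zeros(hi - lo + 1)
    offset = -lo
    dist[offset] = 1.0  # score 0 before any position
    pos_min = illr.min(axis=1).cumsum()
    pos_max = illr.max(axis=1).cumsum()
    cur_lo = cur_hi = 0
    for p in range(len(profile)):
        new = np.zeros_like(dist)
        for b in range(4):
            shift = int(illr[p, b])
            src = dist[offset + cur_lo : offset + cur_hi + 1]
            new[offset + cur_lo + shift : offset + cur_hi + shift + 1] += bg[b] * src
        dist = new
        cur_lo, cur_hi = int(pos_min[p]), int(pos_max[p])
    # compute the observed score on the same discretised grid as the DP so
    # that the observed window's own probability mass is included in the tail
    si = encode(window)
    iobs = int(illr[np.arange(len(profile)), si].sum())
    return float(dist[offset + iobs :].sum())


def classify_long_short(
    windows: Sequence[CandidateWindow | PromoterMotif],
    pvalues: Sequence[float] | None = None,
) -> list[PromoterMotif]:
    """Partition 12-bp windows into late (long) and middle (short) promoters.

    A window is ``late_long`` iff its first two bases match ``TG`` with at
    most one mismatch AND its last four bases are exactly ``TATA``; otherwise
    it is ``middle_short``.  The anchor coordinate is the window start for
    long motifs and the core (position 3) start for short motifs.
    """
    out: list[PromoterMotif] = []
    for i, w in enumerate(windows):
        if isinstance(w, CandidateWindow):
            seq = w.window
            gene = w.region.downstream_gene
            strand = w.region.strand
            start_coord = w.genomic_coordinate
            core_coord = w.region.to_genomic(w.local_offset + LEFT_FLANK)
        else:
            seq = w.sequence
            gene = w.downstream_gene
            strand = w.strand
            start_coord = w.genomic_coordinate
            core_coord = w.genomic_coordinate  # caller supplied anchor
        if len(seq) != WINDOW_LEN:
            raise ValueError(f"window {seq!r} is not {WINDOW_LEN} bp")
        s = seq.upper()
        tg_mismatch = (s[0] != "T") + (s[1] != "G")
        is_long = tg_mismatch <= 1 and s[8:12] == "TATA"
        out.append(
            PromoterMotif(
                downstream_gene=gene,
                sequence=s,
                genomic_coordinate=start_coord if is_long else core_coord,
                promoter_class="late_long" if is_long else "middle_short",
                strand=strand,
                pvalue=pvalues[i] if pvalues is not None else getattr(w, "pvalue", None),
            )
        )
    return out


def logo_to_tsv(logo: LogoMatrix, path: str) -> None:
    """Write a logo matrix as position x A/C/G/T frequency + bits."""
    import pandas as pd

    df = pd.DataFrame(logo.freqs, columns=list(BASES))
    df.insert(0, "position", np.arange(1, len(logo) + 1))
    df["bits"] = logo.information
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LogoAlignment:
    offset: int  # of logo_b's first column relative to logo_a's
    gap_in: Literal["a", "b", None]
    gap_position: int | None  # column index before which the gap is inserted
    score: float
    aligned_columns: int


def _dot_score(fa: np.ndarray, fb: np.ndarray, offset: int) -> tuple[float, int]:
    la, lb = fa.shape[0], fb.shape[0]
    total = 0.0
    cols = 0
    for j in range(lb):
        i = j + offset
        if 0 <= i < la:
            if fb[j].sum() == 0 or fa[i].sum() == 0:  # gap column
                continue
            total += float(fa[i] @ fb[j])
            cols += 1
    return total, cols


def compare_specificities(
    logo_a: LogoMatrix, logo_b: LogoMatrix, max_gap: int = 1
) -> LogoAlignment:
    """Best ungapped-or-single-gap offset alignment of two logos.

    The score is the summed per-position dot product of frequency vectors
    over aligned columns; a single gap column (scoring 0) may be inserted in
    either logo.  Ties prefer no gap, then the smaller |offset|.
    """
    if len(logo_a) == 0 or len(logo_b) == 0:
        raise ValueError("empty logo")
    fa, fb = logo_a.freqs, logo_b.freqs
    variants: list[tuple[np.ndarray, np.ndarray, str | None, int | None]] = [
        (fa, fb, None, None)
    ]
    if max_gap >= 1:
        gap = np.zeros((1, 4))
        for g in range(1, fb.shape[0]):
            variants.append((fa, np.vstack([fb[:g], gap, fb[g:]]), "b", g))
        for g in range(1, fa.shape[0]):
            variants.append((np.vstack([fa[:g], gap, fa[g:]]), fb, "a", g))
    best: LogoAlignment | None = None
    for va, vb, gap_in, gap_pos in variants:
        la, lb = va.shape[0], vb.shape[0]
        for offset in range(-(lb - 1), la):
            score, cols = _dot_score(va, vb, offset)
            if cols == 0:
                continue
            key = (
                -score,
                0 if gap_in is None else 1,
                abs(offset),
                offset,
                gap_pos if gap_pos is not None else -1,
            )
            if best is None or key < best._key:  # type: ignore[attr-defined]
                best = LogoAlignment(offset, gap_in, gap_pos, score, cols)  # type: ignore[arg-type]
                object.__setattr__(best, "_key", key)
    assert best is not None
    return best
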