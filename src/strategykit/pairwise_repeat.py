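"""Low-copy conserved repeat discovery by pairwise local alignment.

Phage-encoded σ-factor promoters are typically well conserved but present in
only a handful of copies, which defeats multiple-local-alignment motif
finders.  Instead, the anchor intergenic region (the long origin-spanning
region upstream of the structural gene cluster) is locally aligned against
itself and against every other intergenic region; repeated high-identity hits
are consolidated into candidate motif sets whose significance is scored by a
word-occurrence Poisson E-value.

The aligner is an affine-gap Smith-Waterman (Gotoh recurrences, vectorised
per row with a lazy-F correction sweep) that reports all locally optimal,
mutually non-overlapping hits above a minimum length, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.stats import poisson

from ._seq import encode
from .intergenic import IntergenicRegion


@dataclass(frozen=True)
class AlignScoring:
    """Local alignment scoring; defaults suit short nucleotide repeats."""

    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_hit_len: int = 7

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.min_hit_len < 4:
            raise ValueError("min_hit_len must be >= 4")


@dataclass(frozen=True)
class LocalAlignmentHit:
    """One ungapped-or-gapped local alignment between two sequences.

    Offsets are 0-based into the oriented region sequences.  ``region_a`` /
    ``region_b`` are attached by :func:`repeat_search`; plain
    :func:`local_align` leaves them ``None``.
    """

    a_start: int
    a_len: int
    b_start: int
    b_len: int
    length: int  # aligned columns
    identities: int
    score: int
    region_a: IntergenicRegion | None = None
    region_b: IntergenicRegion | None = None
    evalue: float | None = None


@dataclass
class CandidateMotifSet:
    """A consolidated repeat: one consensus with k genomic instances."""

    consensus: str
    instances: list[tuple[IntergenicRegion | None, int, int, str]]
    # (region, local_offset, genomic_coordinate or -1, sequence)
    copy_number: int
    search_space: int
    evalue: float


def _align_matrices(
    ai: np.ndarray, bi: np.ndarray, scoring: AlignScoring, self_comparison: bool
):
    """Fill H, E, F Gotoh matrices (int32).  Gap of length g scores
    gap_open + (g-1)*gap_extend, matching Bio.Align.PairwiseAligner."""
    n, m = len(ai), len(bi)
    go, ge = scoring.gap_open, scoring.gap_extend
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), np.iinfo(np.int32).min // 4, dtype=np.int32)
    F = np.full((n + 1, m + 1), np.iinfo(np.int32).min // 4, dtype=np.int32)
    j_idx = np.arange(1, m + 1)
    for i in range(1, n + 1):
        s = np.where((bi == ai[i - 1]) & (bi < 4), scoring.match, scoring.mismatch)
        diag = H[i - 1, :-1] + s
        e = np.maximum(H[i - 1, 1:] + go, E[i - 1, 1:] + ge)
        h = np.maximum(np.maximum(diag, e), 0)
        # lazy-F: F[j] = max_{k<j}(H[i,k] + go + (j-1-k)*ge); iterate to fixpoint
        f = np.full(m, np.iinfo(np.int32).min // 4, dtype=np.int32)
        for _ in range(m):
            # prefix max of H[i,k] - k*ge over k in 0..j-1 (k=0 is column 0 = 0)
            a_run = np.empty(m + 1, dtype=np.int64)
            a_run[0] = 0  # H[i,0] - 0*ge
            a_run[1:] = h.astype(np.int64) - j_idx * ge
            pref = np.maximum.accumulate(a_run)[:-1]
            f_new = (pref + go + (j_idx - 1) * ge).astype(np.int32)
            h_new = np.maximum(h, f_new)
            f = f_new
            if (h_new == h).all():
                break
            h = h_new
        if self_comparison and i <= m:
            h[i - 1] = 0
            e[i - 1] = np.iinfo(np.int32).min // 4
            f[i - 1] = np.iinfo(np.int32).min // 4
        H[i, 1:] = h
        E[i, 1:] = e
        F[i, 1:] = f
    return H, E, F


def _traceback(H, E, F, ai, bi, scoring, i, j):
    """Trace one local alignment ending at (i, j) back to its start."""
    go, ge = scoring.gap_open, scoring.gap_extend
    length = identities = 0
    state = "H"
    end_i, end_j = i, j
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            s = scoring.match if (ai[i - 1] == bi[j - 1] and ai[i - 1] < 4) else scoring.mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                length += 1
                if ai[i - 1] == bi[j - 1] and ai[i - 1] < 4:
                    identities += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - defensive
                break
        elif state == "E":
            length += 1
            if E[i, j] == E[i - 1, j] + ge and E[i - 1, j] > np.iinfo(np.int32).min // 8:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:  # F
            length += 1
            if F[i, j] == F[i, j - 1] + ge and F[i, j - 1] > np.iinfo(np.int32).min // 8:
                j -= 1
            else:
                j -= 1
                state = "H"
    return i, j, end_i, end_j, length, identities


def local_align(
    a: str,
    b: str,
    scoring: AlignScoring = AlignScoring(),
    self_comparison: bool = False,
    min_score: int | None = None,
    max_hits: int = 200,
) -> list[LocalAlignmentHit]:
    """All locally optimal non-overlapping local alignments of ``a`` vs ``b``.

    Only the direct strands are compared (promoter motifs are
    orientation-specific).  In ``self_comparison`` mode the identity diagonal
    is excluded and mirror-image hits are reported once (a_start < b_start).
    Ties are broken by smallest start in ``a``, then in ``b``.
    """
    if not a or not b:
        return []
    ai, bi = encode(a), encode(b)
    if min_score is None:
        min_score = scoring.min_hit_len * scoring.match
    H, E, F = _align_matrices(ai, bi, scoring, self_comparison)
    cand_i, cand_j = np.nonzero(H >= min_score)
    if cand_i.size == 0:
        return []
    scores = H[cand_i, cand_j]
    order = np.lexsort((cand_j, cand_i, -scores))
    hits: list[LocalAlignmentHit] = []
    accepted: list[tuple[int, int, int, int]] = []  # (a0, a1, b0, b1) half-open
    for idx in order[: max(4 * max_hits, 2000)]:
        i, j = int(cand_i[idx]), int(cand_j[idx])
        s0, t0, s1, t1, length, identities = _traceback(H, E, F, ai, bi, scoring, i, j)
        if length < scoring.min_hit_len:
            continue
        a0, a1, b0, b1 = s0, s1, t0, t1
        if self_comparison and a0 >= b0:
            continue
        dup = False
        for pa0, pa1, pb0, pb1 in accepted:
            if a0 < pa1 and pa0 < a1 and b0 < pb1 and pb0 < b1:
                dup = True
                break
        if dup:
            continue
        hits.append(
            LocalAlignmentHit(
                a_start=a0,
                a_len=a1 - a0,
                b_start=b0,
                b_len=b1 - b0,
                length=length,
                identities=identities,
                score=int(H[i, j]),
            )
        )
        accepted.append((a0, a1, b0, b1))
        if len(hits) >= max_hits:
            break
    hits.sort(key=lambda h: (-h.score, h.a_start, h.b_start))
    return hits


def repeat_search(
    regions: Sequence[IntergenicRegion],
    mode: Literal["anchor", "all_pairs"] = "anchor",
    scoring: AlignScoring = AlignScoring(),
    anchor: IntergenicRegion | None = None,
) -> list[LocalAlignmentHit]:
    """Run pairwise comparisons among intergenic regions.

    Anchor mode aligns the anchor region (by default the first region given,
    expected to be the origin-spanning region of the "+" cluster) with itself
    and with every other region.  ``all_pairs`` runs every self- and
    cross-comparison.
    """
    if not regions:
        raise ValueError("no regions to search")
    pairs: list[tuple[IntergenicRegion, IntergenicRegion]] = []
    if mode == "anchor":
        a = anchor if anchor is not None else regions[0]
        pairs.append((a, a))
        pairs.extend((a, r) for r in regions if r is not a)
    elif mode == "all_pairs":
        for i, r in enumerate(regions):
            pairs.append((r, r))
            pairs.extend((r, s) for s in regions[i + 1 :])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out: list[LocalAlignmentHit] = []
    for ra, rb in pairs:
        for h in local_align(ra.sequence, rb.sequence, scoring, self_comparison=ra is rb):
            out.append(replace(h, region_a=ra, region_b=rb))
    return out


def repeat_evalue(k: int, L: int, n: int) -> float:
    """Expected number of L-bp words occurring >= k times in n bp.

    Under a uniform i.i.d. background each word's occurrence count is
    approximately Poisson with mean n/4^L, so
    E(k, L, n) = 4^L * P[Poisson(n * 4^-L) >= k].
    """
    if k < 1 or L < 1 or n < L:
        raise ValueError("require k >= 1, L >= 1, n >= L")
    lam = n * 4.0 ** (-L)
    return 4.0**L * float(poisson.sf(k - 1, lam))


def repeat_evalue_composition(k: int, L: int, n: int, freqs: Sequence[float]) -> float:
    """Composition-matched variant: expected count of >=k-fold words when the
    background draws letters with the given frequencies (mean word probability
    taken as the expectation over random words)."""
    f = np.asarray(freqs, dtype=float)
    f = f / f.sum()
    # E over words of p_word = (sum f_i^2)^L for an L-word drawn from f
    p_word = float((f**2).sum()) ** L
    lam = n * p_word
    return 4.0**L * float(poisson.sf(k - 1, lam))


def _best_offset(seq: str, ref: str, max_shift: int) -> int:
    """Ungapped offset of ``seq`` relative to ``ref`` maximising matches."""
    best_shift, best_matches = 0, -1
    for shift in range(-max_shift, max_shift + 1):
        matches = 0
        for i, c in enumerate(seq):
            j = i + shift
            if 0 <= j < len(ref) and ref[j] == c:
                matches += 1
        if matches > best_matches:
            best_matches, best_shift = matches, shift
    return best_shift


def _frame_and_consensus(
    raw: list[tuple["IntergenicRegion", int, int]],
) -> tuple[str, list[tuple["IntergenicRegion", int, int, str]]]:
    """Put instance intervals in a common ungapped frame and call a consensus.

    The longest instance is the frame reference; every instance is offset
    against it by maximal ungapped matches, a per-column majority consensus is
    called over columns covered by at least half the instances, and each
    instance is re-sliced from its region to the consensus extent so all
    reported instances share the frame and length.
    """
    seqs = [r.sequence[s:e] for r, s, e in raw]
    ref_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    ref = seqs[ref_idx]
    shifts = [_best_offset(q, ref, max_shift=max(len(ref), 4)) for q in seqs]
    lo = min(shifts)
    hi = max(sh + len(q) for sh, q in zip(shifts, seqs))
    width = hi - lo
    k = len(seqs)
    cols: list[dict[str, int]] = [dict() for _ in range(width)]
    for sh, q in zip(shifts, seqs):
        for i, c in enumerate(q):
            col = cols[sh + i - lo]
            col[c] = col.get(c, 0) + 1
    covered = [i for i, col in enumerate(cols) if sum(col.values()) * 2 >= k]
    if not covered:
        return "", []
    c0, c1 = covered[0], covered[-1] + 1
    consensus = "".join(
        max(sorted(cols[i]), key=cols[i].get) if cols[i] else "N"
        for i in range(c0, c1)
    )
    instances: list[tuple["IntergenicRegion", int, int, str]] = []
    for (region, s, e), sh in zip(raw, shifts):
        # region-local start of the consensus window for this instance
        new_s = s + (c0 + lo - sh)
        new_e = new_s + (c1 - c0)
        new_s_c = max(0, new_s)
        new_e_c = min(len(region.sequence), new_e)
        if new_e_c - new_s_c < (c1 - c0) // 2:
            continue
        seq = region.sequence[new_s_c:new_e_c]
        instances.append((region, new_s_c, region.to_genomic(new_s_c), seq))
    instances.sort(key=lambda t: (t[2], t[1]))
    # drop exact duplicates (same region and start)
    dedup: list[tuple["IntergenicRegion", int, int, str]] = []
    seen: set[tuple[int, int]] = set()
    for inst in instances:
        key = (id(inst[0]), inst[1])
        if key not in seen:
            seen.add(key)
            dedup.append(inst)
    return consensus, dedup


def hits_to_tsv(hits: Sequence[LocalAlignmentHit], path: str) -> None:
    """Write a hit table (regions, offsets, length, identities, score)."""
    import pandas as pd

    rows = []
    for h in hits:
        rows.append(
            {
                "gene_a": h.region_a.downstream_gene if h.region_a else "",
                "gene_b": h.region_b.downstream_gene if h.region_b else "",
                "a_start": h.a_start,
                "a_len": h.a_len,
                "b_start": h.b_start,
                "b_len": h.b_len,
                "length": h.length,
                "identities": h.identities,
                "score": h.score,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def motif_sets_to_tsv(sets: Sequence[CandidateMotifSet], path: str) -> None:
    """Write motif instances (gene, sequence, genomic coordinate) per set."""
    import pandas as pd

    rows = []
    for i, s in enumerate(sets, start=1):
        for region, _off, coord, seq in s.instances:
            rows.append(
                {
                    "set": i,
                    "consensus": s.consensus,
                    "copy_number": s.copy_number,
                    "evalue": s.evalue,
                    "gene": region.downstream_gene if region else "",
                    "sequence": seq,
                    "coordinate": coord,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.p = list(range(n))

    def find(self, x: int) -> int:
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[rb] = ra


def consolidate_motifs(
    hits: Sequence[LocalAlignmentHit],
    search_space: int,
    min_identity: float = 0.75,
    max_hit_evalue: float = 10.0,
    min_overlap_frac: float = 0.5,
    match_score: int = 1,
) -> list[CandidateMotifSet]:
    """Merge overlapping / transitively linked hits into candidate motif sets.

    Hits below ``min_identity``, or whose pairwise E-value exceeds
    ``max_hit_evalue``, are dropped first - short chance matches are abundant
    in kilobases of sequence and would otherwise daisy-chain unrelated
    intervals.  A hit's E-value treats its alignment score (in match-reward
    units) as the length of an equivalent exact word - with the default
    +1/-3 scoring the word-Poisson rate per word length (ln 4 = 1.386) is
    nearly the Karlin-Altschul lambda of the scheme (1.374) - and applies
    ``repeat_evalue(2, score/match, search_space)``.  Each surviving hit contributes its two aligned intervals as
    instances; instances overlapping by at least ``min_overlap_frac`` of the
    shorter interval within the same region are merged (union-find), and the
    two sides of every hit are linked.  The consensus is the per-position
    majority over the instances, and the set E-value uses the word-Poisson
    estimator with the consensus length, the copy number, and the total
    searched space.
    """
    n_eff = max(search_space, 2)
    kept = [
        h
        for h in hits
        if h.length
        and h.identities / h.length >= min_identity
        and repeat_evalue(
            2,
            max(int(round(h.score / match_score)), 1),
            max(n_eff, h.identities),
        )
        <= max_hit_evalue
    ]
    nodes: list[tuple[int, int, int, LocalAlignmentHit, str]] = []
    # node: (region_id, start, end, hit, side)
    for h in kept:
        nodes.append((id(h.region_a), h.a_start, h.a_start + h.a_len, h, "a"))
        nodes.append((id(h.region_b), h.b_start, h.b_start + h.b_len, h, "b"))
    uf = _UnionFind(len(nodes))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            ri, si, ei = nodes[i][:3]
            rj, sj, ej = nodes[j][:3]
            if ri != rj:
                continue
            overlap = min(ei, ej) - max(si, sj)
            shorter = min(ei - si, ej - sj)
            if overlap > 0 and overlap >= min_overlap_frac * shorter:
                uf.union(i, j)
    for i in range(0, len(nodes), 2):  # link the two sides of each hit
        uf.union(i, i + 1)
    groups: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        groups.setdefault(uf.find(i), []).append(i)
    sets: list[CandidateMotifSet] = []
    for members in groups.values():
        # merge same-region overlapping intervals into distinct instances
        by_region: dict[int, list[tuple[int, int]]] = {}
        region_of: dict[int, IntergenicRegion | None] = {}
        for m in members:
            rid, s, e, h, side = nodes[m]
            region_of[rid] = h.region_a if side == "a" else h.region_b
            by_region.setdefault(rid, []).append((s, e))
        raw: list[tuple[IntergenicRegion, int, int]] = []
        for rid, ivals in by_region.items():
            ivals.sort()
            merged = [list(ivals[0])]
            for s, e in ivals[1:]:
                if s < merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            region = region_of[rid]
            if region is None:
                continue
            for s, e in merged:
                raw.append((region, s, e))
        if not raw:
            continue
        consensus, instances = _frame_and_consensus(raw)
        if not consensus:
            continue
        k = len(instances)
        ev = repeat_evalue(k, len(consensus), max(search_space, len(consensus)))
        sets.append(
            CandidateMotifSet(
                consensus=consensus,
                instances=instances,
                copy_number=k,
                search_space=search_space,
                evalue=ev,
            )
        )
    sets.sort(key=lambda s: (s.evalue, s.consensus))
    return sets
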