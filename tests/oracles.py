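"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written against the *definitions* (exhaustive
enumeration, per-position recounts), never by calling the code paths it
checks.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from retroinvade.io_utils import encode, revcomp


def brute_homopolymer(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Position-by-position scan for maximal single-base runs."""
    runs = []
    n = len(seq)
    for i in range(n):
        if i > 0 and seq[i] == seq[i - 1]:
            continue  # not a run start
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
    return runs


def exhaustive_align(read_id, seq, library, min_identity=0.75, min_aligned=30):
    """All-offsets semi-global alignment over every reference and strand;
    same scoring (match +1 / mismatch -1 over the aligned span, overhangs
    free) and the same tie semantics as the seed-and-extend aligner."""
    entries = []
    for strand, s in (("+", seq.upper()), ("-", revcomp(seq.upper()))):
        q = encode(s)
        L = len(q)
        if L < min_aligned:
            continue
        for rid in library.reference_ids:
            ref = encode(library.sequence_of(rid))
            R = len(ref)
            # interior diagonals in one vectorized sweep
            if R >= L:
                windows = sliding_window_view(ref, L)
                mms = (windows != q).sum(axis=1)
                for d in range(R - L + 1):
                    mm = int(mms[d])
                    if (L - mm) / L >= min_identity:
                        entries.append((L - 2 * mm, rid, strand, d, L, mm))
            # overhanging diagonals
            edge = list(range(-(L - min_aligned), 0)) + list(
                range(max(0, R - L + 1), R - min_aligned + 1)
            )
            for d in edge:
                a, b = max(0, d), min(R, d + L)
                alen = b - a
                if alen < min_aligned or alen == L:
                    continue
                mm = int(np.count_nonzero(ref[a:b] != q[a - d : b - d]))
                if (alen - mm) / alen >= min_identity:
                    entries.append((alen - 2 * mm, rid, strand, a, alen, mm))
    if not entries:
        return []
    best = max(e[0] for e in entries)
    winners = [e for e in entries if e[0] == best]
    per_ref = {}
    for e in winners:
        rank = (e[2] != "+", e[3])
        if e[1] not in per_ref or rank < (per_ref[e[1]][2] != "+", per_ref[e[1]][3]):
            per_ref[e[1]] = e
    n_tied = len(per_ref)
    return [
        {
            "read_id": read_id,
            "family_id": rid,
            "start": e[3],
            "strand": e[2],
            "mismatches": e[5],
            "aligned_len": e[4],
            "is_ambiguous": n_tied > 1,
        }
        for rid, e in sorted(per_ref.items())
    ]


def recount_pileup(alignments, library):
    """Per-position recount of coverage and base counts from the alignment
    list, using plain dict arithmetic."""
    covU = {r: {} for r in library.reference_ids}
    covA = {r: {} for r in library.reference_ids}
    bases = {r: {} for r in library.reference_ids}
    for aln in alignments:
        if aln.is_ambiguous:
            for p in range(aln.start, aln.start + aln.aligned_len):
                covA[aln.family_id][p] = covA[aln.family_id].get(p, 0.0) + 1.0 / aln.n_tied
        else:
            seg = aln.seq[aln.q_start : aln.q_start + aln.aligned_len]
            for off, base in enumerate(seg):
                if base not in "ACGT":
                    continue
                p = aln.start + off
                covU[aln.family_id][p] = covU[aln.family_id].get(p, 0) + 1
                bases[aln.family_id].setdefault(p, {}).setdefault(base, 0)
                bases[aln.family_id][p][base] += 1
    return covU, covA, bases


def merge_with_gap(intervals, max_gap):
    """Interval union allowing gaps <= max_gap (intervals as (start, end))."""
    out = []
    for start, end in sorted(intervals):
        if out and start - out[-1][1] <= max_gap:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def pca_variance_by_eig(X):
    """Variance-explained fractions from a covariance eigendecomposition of
    the centered matrix."""
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False)
    vals = np.linalg.eigvalsh(cov)[::-1]
    vals = np.clip(vals, 0, None)
    return vals / vals.sum()
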