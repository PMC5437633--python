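"""Exhaustive oracle for the imperfect-microsatellite search.

A deliberately plain reimplementation of the pinned search semantics used
only by the test suite: every position of the sequence is tried as a seed
for every motif length, extension is simulated step by step with simple
string operations, and candidate resolution is re-derived from scratch.
The production scanner must agree exactly on (interval, mismatch count).
"""

from __future__ import annotations


def _primitive(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def _best_phase(seq: str, j: int, motif: str, cont: int) -> int:
    """Rotation offset with the longest exact run at j; ties prefer the
    continuation phase, then the smallest offset."""
    k = len(motif)
    runs = []
    for p in range(k):
        r = 0
        while j + r < len(seq) and seq[j + r] == motif[(p + r) % k]:
            r += 1
        runs.append(r)
    best = max(runs)
    if runs[cont] == best:
        return cont
    for p in range(k):
        if runs[p] == best:
            return p
    raise AssertionError  # pragma: no cover


def _walk(seq: str, start: int, motif: str, max_consec: int, penalty: int,
          match: int):
    """One-directional extension; returns (trimmed_len, score, n_mismatch)."""
    k = len(motif)
    phase = 0
    pos = start
    score = 0
    top = 0
    top_len = 0
    length = 0
    streak = 0
    mism_at = []
    while pos < len(seq):
        if seq[pos] == motif[phase] and seq[pos] in "ACGT":
            score += match
            length += 1
            streak = 0
            phase = (phase + 1) % k
            if score >= top:
                top = score
                top_len = length
        else:
            if streak == max_consec:
                break
            if top - (score - penalty) > penalty:
                break
            score -= penalty
            length += 1
            streak += 1
            mism_at.append(length - 1)
            phase = _best_phase(seq, pos + 1, motif, (phase + 1) % k)
        pos += 1
    mm = sum(1 for m in mism_at if m < top_len)
    return top_len, top, mm


def oracle_scan(seq: str, cfg) -> list[tuple[int, int, int, int]]:
    """All reported loci as (start, end, mismatch_count, score) tuples."""
    seq = seq.upper()
    n = len(seq)
    rev = seq[::-1]
    found = {}
    for k in sorted(cfg.motif_lengths):
        seedlen = max(3 * k, 8)
        for s in range(0, n - seedlen + 1):
            motif = seq[s:s + k]
            if any(c not in "ACGT" for c in motif) or not _primitive(motif):
                continue
            if seq[s:s + seedlen] != (motif * seedlen)[:seedlen]:
                continue
            rlen, rscore, rmm = _walk(seq, s, motif,
                                      cfg.max_successive_mismatch,
                                      cfg.mismatch_penalty, cfg.match_score)
            llen, lscore, lmm = _walk(rev, n - s, motif[::-1],
                                      cfg.max_successive_mismatch,
                                      cfg.mismatch_penalty, cfg.match_score)
            start, end = s - llen, s + rlen
            score = rscore + lscore
            mm = rmm + lmm
            if end - start < cfg.min_repeat_length or score < cfg.min_score:
                continue
            key = (start, end, k, mm, score)
            if key not in found:
                found[key] = motif  # first (leftmost) seed names the motif
    cands = sorted(
        [(st, en, sc, mm, mo) for (st, en, k, mm, sc), mo in found.items()],
        key=lambda c: (-c[2], len(c[4]), c[0], c[4]))
    picked = []
    for st, en, sc, mm, mo in cands:
        if all(en <= p[0] or st >= p[1] for p in picked):
            picked.append((st, en, mm, sc))
    return sorted(picked)
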