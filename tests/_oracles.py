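"""Independent brute-force oracles used to cross-check the detectors.

These deliberately use different algorithms from the package: set-based
reachability for quadruplex candidates, cubic enumeration for palindromes,
per-offset Python rescoring for matrix scans, quadratic loops for interval
overlaps, and the textbook step-up definition for BH-FDR.  They are written
for clarity, not speed.
"""

from __future__ import annotations

import numpy as np

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def revcomp(seq: str) -> str:
    return "".join(COMP.get(c, "N") for c in reversed(seq))


# ---------------------------------------------------------------------------
# quadruplexes


def _candidate_ends(seq, s, ch, min_run, loop_min, loop_max):
    """All e such that seq[s:e] splits into 4 runs of >= min_run `ch`
    separated by 3 loops of ACGT with bounded length (forward reachability)."""
    n = len(seq)

    def run_extents(pos):
        k = 0
        while pos + k < n and seq[pos + k] == ch:
            k += 1
        return k

    # states after each of the 6 leading parts (run, loop, ...), as position sets
    states = {s}
    for part in range(6):
        nxt = set()
        if part % 2 == 0:  # run
            for p in states:
                m = run_extents(p)
                for k in range(min_run, m + 1):
                    nxt.add(p + k)
        else:  # loop
            for p in states:
                for k in range(loop_min, loop_max + 1):
                    if p + k > n:
                        break
                    if all(c in "ACGT" for c in seq[p : p + k]):
                        nxt.add(p + k)
        states = nxt
        if not states:
            return set()
    ends = set()
    for p in states:  # final run
        m = run_extents(p)
        for k in range(min_run, m + 1):
            ends.add(p + k)
    return ends


def g4_oracle(seq, min_run=3, loop_min=1, loop_max=7, both_strands=True):
    """Greedy-selected quadruplex intervals per strand: list of (start, end, strand)."""
    seq = seq.upper()
    n = len(seq)
    out = []
    strands = [("G", "+")] + ([("C", "-")] if both_strands else [])
    for ch, strand in strands:
        candidates = []
        for s in range(n):
            if seq[s] != ch:
                continue
            for e in sorted(_candidate_ends(seq, s, ch, min_run, loop_min, loop_max)):
                candidates.append((s, e))
        candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
        cursor = 0
        for s, e in candidates:
            if s >= cursor:
                out.append((s, e, strand))
                cursor = e
    return sorted(out)


# ---------------------------------------------------------------------------
# palindromes


def palindrome_oracle(seq, min_arm=6, max_loop=10):
    """All maximal-arm palindromes by cubic enumeration: (arm_start, arm, loop)."""
    seq = seq.upper()
    n = len(seq)
    out = []
    for s in range(n):
        for arm in range(min_arm, (n - s) // 2 + 1):
            for loop in range(0, max_loop + 1):
                e = s + 2 * arm + loop
                if e > n:
                    break
                left = seq[s : s + arm]
                right = seq[s + arm + loop : e]
                if left != revcomp(right):
                    continue
                # maximality: outward extension by one base must fail
                if (
                    s - 1 >= 0
                    and e < n
                    and COMP.get(seq[s - 1]) == seq[e]
                ):
                    continue
                out.append((s, arm, loop))
    return sorted(out)


# ---------------------------------------------------------------------------
# matrix scans


def pwm_scan_oracle(seq, matrix, min_score, max_score, min_rel, both_strands=True):
    """Hits as (start, strand, score) by per-offset Python rescoring."""
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = matrix.shape[1]
    hits = []

    def scan(s, strand):
        for o in range(len(s) - L + 1):
            kmer = s[o : o + L]
            if any(c not in base_idx for c in kmer):
                continue
            score = sum(matrix[base_idx[c], j] for j, c in enumerate(kmer))
            span = max_score - min_score
            rel = 1.0 if span == 0 else (score - min_score) / span
            if rel >= min_rel:
                start = o if strand == "+" else len(s) - o - L
                hits.append((start, strand, score))

    scan(seq.upper(), "+")
    if both_strands:
        scan(revcomp(seq.upper()), "-")
    return sorted(hits)


def splice_scan_oracle(seq, freq, min_score, both_strands=True):
    """Splice-site hits as (start, strand, pct_score) by per-offset rescoring."""
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = freq.shape[1]
    t_min = freq.min(axis=0).sum()
    t_max = freq.max(axis=0).sum()
    hits = []

    def scan(s, strand):
        for o in range(len(s) - L + 1):
            kmer = s[o : o + L]
            if any(c not in base_idx for c in kmer):
                continue
            t = sum(freq[base_idx[c], j] for j, c in enumerate(kmer))
            pct = 100.0 * (t - t_min) / (t_max - t_min)
            if pct >= min_score:
                start = o if strand == "+" else len(s) - o - L
                hits.append((start, strand, round(pct, 9)))

    scan(seq.upper(), "+")
    if both_strands:
        scan(revcomp(seq.upper()), "-")
    return sorted(hits)


# ---------------------------------------------------------------------------
# intervals and statistics


def overlap_count_oracle(win_start, win_end, intervals):
    """Quadratic interval-overlap count: intervals as (start, end) pairs."""
    return sum(1 for s, e in intervals if s < win_end and e > win_start)


def bh_oracle(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = n - rank_from_end  # 1-based rank of p[i] among sorted values
        running_min = min(running_min, p[i] * n / rank)
        adj[i] = running_min
    return np.minimum(adj, 1.0)
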