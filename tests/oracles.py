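"""Independent brute-force reference implementations used only by tests.

Everything here is written from the stated rules directly, without
importing the implementation's scanning/annotation/adjustment code, so
agreement is a genuine two-route check.
"""
from __future__ import annotations

import numpy as np

WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE = {("G", "U"), ("U", "G")}  # (miRNA base, target base)
ALLOWANCES = {6: (0, 0), 7: (1, 0), 8: (1, 1)}  # (max wobble, max mismatch)


def to_rna(s: str) -> str:
    return s.upper().replace("T", "U")


def window_counts(seed: str, window: str) -> tuple[int, int]:
    """(n_wobble, n_mismatch) pairing seed 5'->3' against window antiparallel."""
    w = to_rna(window)
    L = len(seed)
    wob = mm = 0
    for i in range(L):
        pair = (seed[i], w[L - 1 - i])
        if pair in WC:
            continue
        if pair in WOBBLE:
            wob += 1
        else:
            mm += 1
    return wob, mm


def brute_force_scan(
    mirna_seq: str, utr_seq: str, lengths: tuple[int, ...] = (8, 7, 6)
) -> list[tuple[int, int, int, int]]:
    """All seed sites as (start, seed_len, n_wobble, n_mismatch).

    Enumerates every window of every seed length; at one start only the
    longest admissible length is kept.  N-containing windows never match.
    """
    m = to_rna(mirna_seq)
    sites = []
    for s in range(len(utr_seq)):
        for L in lengths:
            if s + L > len(utr_seq):
                continue
            window = utr_seq[s : s + L]
            if "N" in window.upper():
                continue
            seed = m[1 : 1 + L]
            wob, mm = window_counts(seed, window)
            max_wob, max_mm = ALLOWANCES[L]
            if wob <= max_wob and mm <= max_mm:
                sites.append((s, L, wob, mm))
                break
    return sites


def brute_force_bh(pvals) -> np.ndarray:
    """BH adjusted values by the definition q_i = min_{j>=i} m*p_(j)/j."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


def brute_force_best_alignment(read: str, ref: str, max_mm=2, max_shift=2):
    """Best ungapped end-shifted alignment score (n_mismatch, total_shift) or None."""
    best = None
    nr, nf = len(read), len(ref)
    for a in range(-max_shift, max_shift + 1):
        b = nr - nf - a
        if abs(b) > max_shift:
            continue
        lo, hi = max(0, a), min(nr, nf + a)
        if hi <= lo:
            continue
        mm = sum(read[i] != ref[i - a] for i in range(lo, hi))
        if mm <= max_mm:
            key = (mm, abs(a) + abs(b))
            if best is None or key < best:
                best = key
    return best


def seed_duplex_energy_sum(mirna_seq: str, utr_seq: str, start: int, seed_len: int,
                           table: dict[str, float]) -> float:
    """Independent tally of the anchored-duplex energy: walk mature
    positions 2.. pairing the window then leftward UTR bases, sum stacks
    over adjacent paired positions."""
    m = to_rna(mirna_seq)
    u = to_rna(utr_seq)
    paired = []
    for i in range(seed_len):
        j = 2 + i
        t = start + seed_len - 1 - i
        pair = (m[j - 1], u[t])
        paired.append((j, t) if (pair in WC or pair in WOBBLE) else None)
    j, t = 2 + seed_len, start - 1
    while j <= len(m) and t >= 0 and (m[j - 1], u[t]) in (WC | WOBBLE):
        paired.append((j, t))
        j, t = j + 1, t - 1
    total = table["INIT"]
    for a, b in zip(paired, paired[1:]):
        if a and b:
            total += table[f"{m[a[0]-1]}{m[b[0]-1]}/{u[a[1]]}{u[b[1]]}"]
    return total
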