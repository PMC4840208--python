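"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's code paths: the motif matcher tests
every window of every strand directly, the BH oracle applies the step-up
formula literally, and the window oracles recount per window.
"""
from __future__ import annotations

import numpy as np

CLASSES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def rc_pattern(pattern: str) -> str:
    return "".join(COMP[c] for c in reversed(pattern))


def window_matches(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        b in CLASSES[p] for b, p in zip(window, pattern)
    )


def brute_force_sites(
    seq: str, pattern: str, offset: int, circular: bool
) -> set[tuple[int, str]]:
    """Every (methylated-base position, strand) pair, by direct window test."""
    L, m = len(seq), len(pattern)
    ext = seq + (seq[: m - 1] if circular else "")
    rc = rc_pattern(pattern)
    out: set[tuple[int, str]] = set()
    n_starts = L if circular else L - m + 1
    for s0 in range(max(n_starts, 0)):
        win = ext[s0 : s0 + m]
        if len(win) < m:
            break
        if window_matches(win, pattern):
            out.add(((s0 + offset - 1) % L + 1, "+"))
        if window_matches(win, rc):
            out.add(((s0 + m - offset) % L + 1, "-"))
    return out


def brute_force_sites_np(
    seq: str, pattern: str, offset: int, circular: bool
) -> set[tuple[int, str]]:
    """Vectorised variant of the window test for long sequences."""
    L, m = len(seq), len(pattern)
    ext = seq + (seq[: m - 1] if circular else "")
    a = np.frombuffer(ext.encode("ascii"), dtype=np.uint8)
    n_starts = L if circular else L - m + 1

    def mask_for(pat: str) -> np.ndarray:
        ok = np.ones(n_starts, dtype=bool)
        for i, p in enumerate(pat):
            col = a[i : i + n_starts]
            allowed = np.zeros(n_starts, dtype=bool)
            for b in CLASSES[p]:
                allowed |= col == ord(b)
            ok &= allowed
        return ok

    out: set[tuple[int, str]] = set()
    for s0 in np.nonzero(mask_for(pattern))[0]:
        out.add((int(s0 + offset - 1) % L + 1, "+"))
    for s0 in np.nonzero(mask_for(rc_pattern(pattern)))[0]:
        out.add((int(s0 + m - offset) % L + 1, "-"))
    return out


def bh_stepup(p: list[float]) -> list[float]:
    """Literal BH step-up: sort ascending, adj_(i) = min_{j>=i} p_(j)*m/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, p[i] * m / rank))
        adj[i] = running
    return adj


def recount_window(
    positions: list[int],
    methylated: list[bool],
    start: int,
    window: int,
    genome_length: int,
    circular: bool,
) -> tuple[int, int]:
    """(methylated sites, total sites) inside one window, wrap-aware."""
    end = start + window - 1
    n = k = 0
    for pos, meth in zip(positions, methylated):
        inside = start <= pos <= end or (
            circular and end > genome_length and pos <= end - genome_length
        )
        if inside:
            n += 1
            k += bool(meth)
    return k, n


def gc_of_window(seq: str, start: int, window: int, circular: bool) -> float:
    ext = seq + (seq[: window - 1] if circular else "")
    win = ext[start - 1 : start - 1 + window]
    return (win.count("G") + win.count("C")) / window
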