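"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive formulations (explicit budget-state reachability,
quadratic scans, direct pair tables) and share no code with the package's own
algorithms.
"""

from __future__ import annotations

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}


def oracle_best_per_start(
    subject: str, pattern: str, bmm: int, bins: int, bdel: int
) -> dict[int, tuple[int, int, int]]:
    """For every start, the best alignment of the whole pattern within the
    budgets: (total cost, indels, end), by exhaustive state reachability."""
    n, plen = len(subject), len(pattern)
    classes = [_IUPAC[c] for c in pattern]
    best: dict[int, tuple[int, int, int]] = {}
    for s in range(n):
        seen = {(0, s, 0, 0, 0)}
        stack = [(0, s, 0, 0, 0)]
        finals: list[tuple[int, int, int]] = []
        while stack:
            i, j, mm, ins, dl = stack.pop()
            if i == plen:
                if j > s:
                    finals.append((mm + ins + dl, ins + dl, j))
                continue
            moves = []
            if dl < bdel:
                moves.append((i + 1, j, mm, ins, dl + 1))
            if j < n:
                cost = 0 if subject[j] in classes[i] else 1
                if mm + cost <= bmm:
                    moves.append((i + 1, j + 1, mm + cost, ins, dl))
                if ins < bins:
                    moves.append((i, j + 1, mm, ins + 1, dl))
            for m in moves:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        if finals:
            best[s] = min(finals)
    return best


def oracle_helices(a: str, b: str, min_len: int) -> set[tuple[int, int, int, int]]:
    """All maximal antiparallel pairing runs as (a_start, a_end, b_start, b_end),
    by quadratic scan over all (i, j) run anchors."""
    out = set()
    for i in range(len(a)):
        for j in range(len(b)):
            if (a[i], b[j]) not in _PAIRS:
                continue
            if i - 1 >= 0 and j + 1 < len(b) and (a[i - 1], b[j + 1]) in _PAIRS:
                continue  # not the start of a maximal run
            k = 0
            while i + k < len(a) and j - k >= 0 and (a[i + k], b[j - k]) in _PAIRS:
                k += 1
            if k >= min_len:
                out.add((i, i + k, j - k + 1, j + 1))
    return out


def oracle_hairpin(seq: str, min_stem: int, min_loop: int) -> int:
    """Longest hairpin stem by cubic enumeration of arm starts and lengths."""
    n = len(seq)
    best = 0
    for a in range(n):
        for b in range(a + 1, n):
            k = 0
            while (
                a + k < n
                and b - k > a + k
                and (b - k) - (a + k) - 1 >= min_loop
                and (seq[a + k], seq[b - k]) in _PAIRS
            ):
                k += 1
            best = max(best, k)
    return best


def oracle_duplex_windows(
    guide: str, target: str, min_pairs: int, max_mm: int, max_gu: int
) -> list[tuple[int, int, int, int]]:
    """Accepted duplex windows as (target_start, wc, gu, mm), by direct
    pair-class counting (guide 3' end pairs the window start)."""
    L = len(guide)
    out = []
    for s in range(len(target) - L + 1):
        wc = gu = mm = 0
        plus5_wc = False
        for t in range(L):
            g, tb = guide[L - 1 - t], target[s + t]
            if (g, tb) in _WC:
                wc += 1
                if t == 4:
                    plus5_wc = True
            elif (g, tb) in _PAIRS:
                gu += 1
            else:
                mm += 1
        if plus5_wc and wc + gu >= min_pairs and mm <= max_mm and gu <= max_gu:
            out.append((s, wc, gu, mm))
    return out


def random_rna(rng, n: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, n))
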