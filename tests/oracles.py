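"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: recursive/enumerative
formulations checked on small instances.
"""

from functools import lru_cache

NEG = float("-inf")

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def nw_score(a: str, b: str, match: float, mismatch: float,
             gap_open: float, gap_extend: float) -> float:
    """Optimal affine-gap global alignment score by memoized recursion.

    State: (i, j, g) where g is 0 (last column was a substitution),
    1 (gap in b), 2 (gap in a); gap of length L costs open + (L-1)*extend.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, g: int) -> float:
        if i == 0 and j == 0:
            return 0.0 if g == 0 else NEG
        best = NEG
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            v = max(rec(i - 1, j - 1, 0), rec(i - 1, j - 1, 1),
                    rec(i - 1, j - 1, 2)) + s
            best = max(best, v) if g == 0 else best
        if g == 1 and i > 0:
            best = max(best,
                       rec(i - 1, j, 0) + gap_open,
                       rec(i - 1, j, 1) + gap_extend,
                       rec(i - 1, j, 2) + gap_open)
        if g == 2 and j > 0:
            best = max(best,
                       rec(i, j - 1, 0) + gap_open,
                       rec(i, j - 1, 2) + gap_extend,
                       rec(i, j - 1, 1) + gap_open)
        return best

    out = max(rec(len(a), len(b), 0), rec(len(a), len(b), 1),
              rec(len(a), len(b), 2))
    rec.cache_clear()
    return out


def alignment_score(row_a: str, row_b: str, match: float, mismatch: float,
                    gap_open: float, gap_extend: float) -> float:
    """Rescore an aligned pair column by column under the affine model."""
    s = 0.0
    in_a = in_b = False
    for x, y in zip(row_a, row_b):
        if x == "-":
            s += gap_extend if in_a else gap_open
            in_a, in_b = True, False
        elif y == "-":
            s += gap_extend if in_b else gap_open
            in_b, in_a = True, False
        else:
            s += match if x == y else mismatch
            in_a = in_b = False
    return s


def p_distance(row_a: str, row_b: str):
    comp = diff = 0
    for x, y in zip(row_a, row_b):
        if x in "ACGT" and y in "ACGT":
            comp += 1
            if x != y:
                diff += 1
    return diff / comp if comp else float("nan")


def diagnostic_columns(rows: list[str], target_idx: set[int],
                       max_share: float) -> list[tuple[int, str, float]]:
    """Brute column scan: (1-based column, state, off-target share)."""
    out = []
    ncols = len(rows[0])
    others = [rows[i] for i in range(len(rows)) if i not in target_idx]
    targets = [rows[i] for i in sorted(target_idx)]
    for c in range(ncols):
        states = {t[c] for t in targets}
        if len(states) != 1:
            continue
        s = next(iter(states))
        if s not in "ACGT":
            continue
        share = (sum(o[c] == s for o in others) / len(others)) if others else 0.0
        if share <= max_share:
            out.append((c + 1, s, share))
    return out


def max_stem(a: str, b: str) -> int:
    """Longest contiguous antiparallel WC duplex over all pairings (i, j)
    of a position in a against a position in b."""
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            run = 0
            x, y = i, j
            while x < len(a) and y >= 0 and COMP[a[x]] == b[y]:
                run += 1
                x += 1
                y -= 1
            best = max(best, run)
    return best


def binding_sites(primer: str, template: str, max_mm: int,
                  max_3p: int) -> list[tuple[str, int, int, int, int]]:
    """All footprints as (strand, start, end, mismatches, 3' mismatches)."""
    out = []
    L = len(primer)
    for strand in ("+", "-"):
        probe = primer if strand == "+" else revcomp(primer)
        for start in range(len(template) - L + 1):
            window = template[start:start + L]
            mism = [not (set(IUPAC_SETS[p]) & IUPAC_SETS[w])
                    for p, w in zip(probe, window)]
            three = mism[-3:] if strand == "+" else mism[:3]
            if sum(mism) <= max_mm and sum(three) <= max_3p:
                out.append((strand, start + 1, start + L, sum(mism), sum(three)))
    return sorted(out, key=lambda s: (s[1], s[0]))


def false_priming(primer: str, template: str) -> float:
    """Exhaustive 3'-weighted identity scan, both strands, no exclusion."""
    L = len(primer)
    w = [1.0] * (L - 5) + [2.0] * 5
    best = 0.0
    for t in (template, revcomp(template)):
        for start in range(len(t) - L + 1):
            sc = sum(wi for wi, p, c in zip(w, primer, t[start:start + L])
                     if p == c)
            best = max(best, 100.0 * sc / sum(w))
    return best


def welch(a: list[float], b: list[float]) -> tuple[float, float]:
    """(t, df) from the textbook formulas."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / se2 ** 0.5
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
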