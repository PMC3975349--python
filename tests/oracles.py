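"""Independent brute-force oracles for the descriptor formulas.

Everything here is deliberately written with plain Python loops and
dictionaries — no numpy, no imports from the package's compute paths —
so tests compare two genuinely independent evaluations of each formula.
"""

import math

AA = "ACDEFGHIKLMNPQRSTVWY"


def standardize(prop: dict) -> dict:
    """z-score 20 per-residue values with divisor-20 SD, as a dict."""
    vals = [prop[a] for a in AA]
    mean = sum(vals) / 20.0
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20.0)
    return {a: (prop[a] - mean) / sd for a in AA}


def frequencies(seq: str) -> dict:
    return {a: seq.count(a) / len(seq) for a in AA}


def type1(seq: str, lam: int, w: float, raw_props: list[dict]) -> list[float]:
    """Type I pseudo-composition: 20 frequencies + lambda correlation tiers."""
    props = [standardize(p) for p in raw_props]
    L = len(seq)

    def theta(a: str, b: str) -> float:
        return sum((p[b] - p[a]) ** 2 for p in props) / len(props)

    taus = []
    for j in range(1, lam + 1):
        taus.append(
            sum(theta(seq[i], seq[i + j]) for i in range(L - j)) / (L - j)
        )
    f = frequencies(seq)
    denom = sum(f.values()) + w * sum(taus)
    return [f[a] / denom for a in AA] + [w * t / denom for t in taus]


def type2(seq: str, lam: int, w: float, h1: dict, h2: dict) -> list[float]:
    """Type II: interleaved per-property product factors tau_1..tau_2lam."""
    p1, p2 = standardize(h1), standardize(h2)
    L = len(seq)
    taus = []
    for j in range(1, lam + 1):
        taus.append(sum(p1[seq[i]] * p1[seq[i + j]] for i in range(L - j)) / (L - j))
        taus.append(sum(p2[seq[i]] * p2[seq[i + j]] for i in range(L - j)) / (L - j))
    f = frequencies(seq)
    denom = 1.0 + w * sum(taus)
    return [f[a] / denom for a in AA] + [w * t / denom for t in taus]


def profile(seq: str, raw_prop: dict) -> list[float]:
    std = standardize(raw_prop)
    return [std[c] for c in seq]


def moreau_broto(p: list[float], d: int) -> float:
    L = len(p)
    return sum(p[i] * p[i + d] for i in range(L - d)) / (L - d)


def moran(p: list[float], d: int) -> float:
    L = len(p)
    pbar = sum(p) / L
    denom = sum((x - pbar) ** 2 for x in p) / L
    if denom == 0:
        return 0.0
    num = sum((p[i] - pbar) * (p[i + d] - pbar) for i in range(L - d)) / (L - d)
    return num / denom


def geary(p: list[float], d: int) -> float:
    L = len(p)
    pbar = sum(p) / L
    denom = sum((x - pbar) ** 2 for x in p) / (L - 1)
    if denom == 0:
        return 0.0
    num = sum((p[i] - p[i + d]) ** 2 for i in range(L - d)) / (2.0 * (L - d))
    return num / denom


def ctd_transition(seq: str, groups: tuple[str, str, str]) -> list[float]:
    cls = {a: k for k, g in enumerate(groups) for a in g}
    out = []
    for k, l in ((0, 1), (0, 2), (1, 2)):
        n = sum(
            1
            for i in range(len(seq) - 1)
            if {cls[seq[i]], cls[seq[i + 1]]} == {k, l}
        )
        out.append(100.0 * n / (len(seq) - 1))
    return out


def ctd_distribution(seq: str, groups: tuple[str, str, str]) -> list[float]:
    cls = {a: k for k, g in enumerate(groups) for a in g}
    L = len(seq)
    out = []
    for k in range(3):
        positions = [i + 1 for i, c in enumerate(seq) if cls[c] == k]
        if not positions:
            out.extend([0.0] * 5)
            continue
        n = len(positions)
        for q in (0.0, 0.25, 0.5, 0.75, 1.0):
            occ = 1 if q == 0.0 else math.ceil(q * n)
            out.append(100.0 * positions[occ - 1] / L)
    return out


def coupling(seq: str, dist: dict, d: int) -> float:
    """tau_d with dist[(a, b)] the amino-acid distance."""
    return sum(dist[(seq[i], seq[i + d])] ** 2 for i in range(len(seq) - d))


def qso(seq: str, dist: dict, max_lag: int, w: float) -> list[float]:
    taus = [coupling(seq, dist, d) for d in range(1, max_lag + 1)]
    f = frequencies(seq)
    denom = sum(f.values()) + w * sum(taus)
    return [f[a] / denom for a in AA] + [w * t / denom for t in taus]


def psepssm(rows: list[list[float]], xi: int) -> list[float]:
    """20 column means + lag-major squared-difference blocks, from
    row-standardized scores (divisor-20 SD; constant rows -> zeros)."""
    std_rows = []
    for row in rows:
        mean = sum(row) / 20.0
        sd = math.sqrt(sum((v - mean) ** 2 for v in row) / 20.0)
        std_rows.append([0.0] * 20 if sd == 0 else [(v - mean) / sd for v in row])
    L = len(std_rows)
    out = [sum(r[j] for r in std_rows) / L for j in range(20)]
    for g in range(1, xi + 1):
        for j in range(20):
            out.append(
                sum(
                    (std_rows[i][j] - std_rows[i + g][j]) ** 2
                    for i in range(L - g)
                )
                / (L - g)
            )
    return out
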