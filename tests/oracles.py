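"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by exhaustive enumeration or
direct formula manipulation, sharing no code paths with the package.
"""

from __future__ import annotations

import math

import numpy as np

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def oracle_best_duplex_score(bulged: str, partner: str, max_bulge: int) -> int:
    """Exhaustive best score over all non-crossing one-bulge alignments.

    Enumerates every placement of one or two consecutive pairing blocks
    (the second block displaced by a bulge of 1..max_bulge nt on the
    bulged strand), counting Watson-Crick pairs plus the tandem-G:A
    core bonus for the two positions directly 3' of the bulge.
    """
    m, n = len(bulged), len(partner)
    q = partner[::-1]  # q[t] pairs bulged position aligned with t

    # prefix sums of matches along each diagonal d = i - t
    def block_score(s1: int, s2: int, L: int) -> int:
        return sum(1 for k in range(L) if (bulged[s1 + k], q[s2 + k]) in WC)

    match = [[(bulged[i], q[t]) in WC for t in range(n)] for i in range(m)]
    diag = {}
    for d in range(-n + 1, m):
        i0, t0 = (d, 0) if d >= 0 else (0, -d)
        acc = [0]
        i, t = i0, t0
        while i < m and t < n:
            acc.append(acc[-1] + match[i][t])
            i += 1
            t += 1
        diag[d] = (i0, t0, acc)

    def fast_block(s1: int, s2: int, L: int) -> int:
        i0, t0, acc = diag[s1 - s2]
        k = s1 - i0
        return acc[k + L] - acc[k]

    best = 0
    for s1 in range(m):
        for s2 in range(n):
            max_l1 = min(m - s1, n - s2)
            for L1 in range(1, max_l1 + 1):
                sc1 = fast_block(s1, s2, L1)
                best = max(best, sc1)
                for g in range(1, max_bulge + 1):
                    i2, t2 = s1 + L1 + g, s2 + L1
                    max_l2 = min(m - i2, n - t2)
                    for L2 in range(1, max_l2 + 1):
                        sc = sc1 + fast_block(i2, t2, L2)
                        if L2 >= 2 and bulged[i2] == "G" and q[t2] == "A" \
                                and bulged[i2 + 1] == "A" and q[t2 + 1] == "G":
                            sc += 2
                        best = max(best, sc)
    return best


def oracle_hbonds(atoms, table, max_distance=3.5, min_angle=120.0):
    """All-pairs H-bond enumeration with the same geometric criteria.

    ``atoms`` is a list of (chain, resnum, resname, name, xyz); returns
    a set of (donor_key, acceptor_key, round(distance, 9)).
    """
    index = {(a[0], a[1], a[3]): a for a in atoms}
    out = set()
    for d in atoms:
        entry = table.get(d[2])
        if entry is None:
            continue
        ante_name = dict(entry["donors"]).get(d[3])
        if d[3] not in dict(entry["donors"]):
            continue
        for a in atoms:
            ea = table.get(a[2])
            if ea is None or a[3] not in ea["acceptors"]:
                continue
            if (a[0], a[1]) == (d[0], d[1]):
                continue
            dv = np.array(d[4]) - np.array(a[4])
            dist = float(np.linalg.norm(dv))
            if dist > max_distance or dist == 0:
                continue
            ante = index.get((d[0], d[1], ante_name))
            if ante is not None:
                u = np.array(ante[4]) - np.array(d[4])
                v = np.array(a[4]) - np.array(d[4])
                cosv = float(np.dot(u, v) /
                             (np.linalg.norm(u) * np.linalg.norm(v)))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosv))))
                if ang < min_angle:
                    continue
            out.add(((d[0], d[1], d[3]), (a[0], a[1], a[3]), round(dist, 9)))
    return out


def oracle_efret_quadratic(PT, E0, dE, KA, RT):
    """Isotherm via numerically solving the mass-balance quadratic.

    KA*C^2 - (1 + KA*PT + KA*RT)*C + KA*RT*PT = 0 for the complex
    concentration C; the physical root satisfies 0 <= C <= min(RT, PT).
    """
    roots = np.roots([KA, -(1.0 + KA * PT + KA * RT), KA * RT * PT])
    roots = roots[np.isreal(roots)].real
    ok = roots[(roots >= -1e-12) & (roots <= min(RT, PT) * (1 + 1e-9) + 1e-30)]
    c = float(ok.min()) if len(ok) else 0.0
    return E0 + dE * max(0.0, min(1.0, c / RT))


def oracle_grid_fit(pt, e, rt, e0_range, de_range, logka_range, n=25):
    """Coarse grid-search least squares over (E0, dE, log10 KA)."""
    best = (math.inf, None)
    for e0 in np.linspace(*e0_range, n):
        for de in np.linspace(*de_range, n):
            for lka in np.linspace(*logka_range, n):
                pred = np.array([oracle_efret_quadratic(p, e0, de, 10 ** lka, rt)
                                 for p in pt])
                rss = float(np.sum((pred - e) ** 2))
                if rss < best[0]:
                    best = (rss, (e0, de, 10 ** lka))
    return best
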