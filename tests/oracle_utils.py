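"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: scores are
computed by explicit per-pixel loops and Fisher p-values by exact
hypergeometric enumeration with rational arithmetic.
"""

from fractions import Fraction
from math import comb

import numpy as np


def brute_force_scores(dorsal, ventral_flipped, classes=(1, 2, 3, 4, 5),
                       denominator="union"):
    """Per-class and combined symmetry scores by pixel-pair enumeration."""
    dorsal = np.asarray(dorsal)
    ventral = np.asarray(ventral_flipped)
    matching, total, scores = {}, {}, {}
    for c in classes:
        m = t = 0
        for i in range(dorsal.shape[0]):
            for j in range(dorsal.shape[1]):
                in_d = dorsal[i, j] == c
                in_v = ventral[i, j] == c
                if in_d and in_v:
                    m += 1
                if denominator == "union":
                    if in_d or in_v:
                        t += 1
                else:
                    t += int(in_d) + int(in_v)
        matching[c], total[c] = m, t
        scores[c] = m / t if t > 0 else None
    grand = sum(t for t in total.values() if t > 0)
    combined = (
        sum(matching[c] for c in classes if total[c] > 0) / grand if grand else None
    )
    return scores, combined


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    p = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= p_obs:
            p += pk
    return float(p)


def welch_statistic_closed_form(a, b) -> tuple[float, float]:
    """Textbook Welch statistic and Welch-Satterthwaite df via the hand formula."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / se2**0.5
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
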