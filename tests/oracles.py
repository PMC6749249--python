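"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's vectorised code paths: plain Python
loops applying the rule definitions and the Gi* formula literally, so they
can serve as oracles for the production implementations.
"""

from __future__ import annotations

import math


def brute_force_detect(g, T, weights, cs=75.0, g_amp=None, refractory=10.0):
    """Literal per-second scan of the five rules and the weighted score.

    ``g`` drives run structure (R1/R3), ``g_amp`` (default ``g``) supplies
    the R4 amplitude, ``T`` the skin-temperature decrease test. Returns a
    list of (onset_index, total_score).
    """
    n = len(g)
    ga = g if g_amp is None else g_amp
    accepted: list[int] = []
    out: list[tuple[int, float]] = []

    def neg_run(s: int) -> bool:
        if s < 0 or s + 3 > n - 1:
            return False
        return all(T[k + 1] - T[k] < 0 for k in range(s, s + 3))

    for i in range(n - 1):
        if not g[i + 1] > g[i]:
            continue
        if i > 0 and g[i] > g[i - 1]:
            continue  # interior of a run, not its local-minimum start
        j = i
        while j + 1 < n and g[j + 1] > g[j]:
            j += 1
        run = j - i
        sc1 = 1.0 if 2 <= run <= 5 else (0.5 if 5 < run <= 8 else 0.0)
        sc2 = 1.0 if neg_run(i + 3) else (0.5 if any(neg_run(s) for s in range(i + 2, i + 7)) else 0.0)
        sc3 = 1.0 if 1 <= run <= 5 else (0.5 if 5 < run <= 15 else 0.0)
        slope = math.degrees(math.atan((ga[j] - ga[i]) / run))
        sc4 = 1.0 if slope >= 10.0 else (0.5 if slope >= 8.0 else 0.0)
        sc5 = 1.0 if (not accepted or i - accepted[-1] > refractory) else 0.0
        ts = sum(sc * w for sc, w in zip((sc1, sc2, sc3, sc4, sc5), weights))
        if sc5 == 1.0 and ts >= cs:
            accepted.append(i)
            out.append((i, ts))
    return out


def brute_force_gi_star(x, w):
    """Direct evaluation of the self-inclusive Gi* z-score for every cell.

    ``x`` is the attribute vector, ``w`` a full (n, n) weight matrix given
    as nested lists. Returns a list of z-scores.
    """
    n = len(x)
    xbar = sum(x) / n
    s = math.sqrt(sum(v * v for v in x) / n - xbar * xbar)
    z = []
    for i in range(n):
        wi = sum(w[i])
        s1 = sum(wij * wij for wij in w[i])
        num = sum(w[i][j] * x[j] for j in range(n)) - wi * xbar
        den = s * math.sqrt((n * s1 - wi * wi) / (n - 1))
        z.append(num / den)
    return z
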