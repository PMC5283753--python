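"""Brute-force reference implementations used to cross-check estimators.

Everything here enumerates empirical state distributions with dictionaries
and computes entropies as sample averages of log-probabilities — a path
deliberately independent of the vectorized histogram code under test.
"""

from collections import Counter
from math import log


def entropy_of(samples) -> float:
    """−Σ p ln p by direct enumeration of hashable samples."""
    counts = Counter(samples)
    n = len(samples)
    return -sum((c / n) * log(c / n) for c in counts.values())


def mutual_information_of(pairs) -> float:
    """I(X;Y) = S(X) + S(Y) − S(X,Y) on a list of (x, y) samples."""
    pairs = list(pairs)
    return (
        entropy_of([p[0] for p in pairs])
        + entropy_of([p[1] for p in pairs])
        - entropy_of(pairs)
    )


def conditional_entropy_of(x, y, lag: int) -> float:
    """S(y(t+lag) | x(t)) via the lagged pair distribution."""
    pairs = list(zip(x[: len(x) - lag] if lag else x, y[lag:]))
    return entropy_of(pairs) - entropy_of([p[0] for p in pairs])


def transfer_entropy_of(x, y, lag: int) -> float:
    """TE(x→y) summed term-by-term as averages of log empirical
    probabilities over the lagged triples (x(t), y(t), y(t+lag))."""
    n = len(x)
    stop = n - lag if lag else n
    triples = list(zip(x[:stop], y[:stop], y[lag:]))
    m = len(triples)
    p3 = Counter(triples)
    p_yyt = Counter((b, c) for _, b, c in triples)
    p_xy = Counter((a, b) for a, b, _ in triples)
    p_y = Counter(b for _, b, _ in triples)
    total = 0.0
    for t in triples:
        a, b, c = t
        total += (
            -log(p_yyt[(b, c)] / m)
            + log(p3[t] / m)
            + log(p_y[b] / m)
            - log(p_xy[(a, b)] / m)
        )
    return total / m


def delayed_correlation_of(x, y, lag: int) -> float:
    """Normalized lagged correlation by an explicit double loop-free sum,
    matching the estimator definition term by term."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    xc = [v - mx for v in x]
    yc = [v - my for v in y]
    num = sum(xc[k] * yc[k + lag] for k in range(n - lag)) / (n - lag)
    vx = sum(v * v for v in xc) / n
    vy = sum(v * v for v in yc) / n
    return num / (vx * vy) ** 0.5
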