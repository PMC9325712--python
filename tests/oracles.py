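"""Independent brute-force oracles shared across test modules.

These deliberately share no code with the implementation: step-up rules are
evaluated by explicit scans over order statistics.
"""


def bky_oracle(p, q):
    """Brute-force two-stage adaptive linear step-up rejection set."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q1 = q / (1 + q)

    def bh_count(level):
        r = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * level / m:
                r = rank
        return r

    r1 = bh_count(q1)
    if r1 == 0:
        return [False] * m
    if r1 == m:
        return [True] * m
    r2 = bh_count(q1 * m / (m - r1))
    rejected = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= r2:
            rejected[idx] = True
    return rejected
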