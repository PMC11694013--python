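"""Independent scalar life-table oracle for cross-checking the engine.

Deliberately coded as plain Python loops over one schedule at a time, in
spreadsheet style, sharing no code with the package implementation.
"""


def oracle_life_table(m, boundaries=None):
    """All abridged life-table columns for one m schedule.

    ``boundaries`` are the closed-group lower bounds plus the terminal
    start, defaulting to [0, 1, 5, 10, ..., 85]; the last group is open.
    Returns a dict of per-age lists: m, a, q, l, d, L, T, e.
    """
    if boundaries is None:
        boundaries = [0, 1] + list(range(5, 90, 5))
    k = len(m)
    assert len(boundaries) == k

    widths = [boundaries[i + 1] - boundaries[i] for i in range(k - 1)]
    a = []
    for i in range(k - 1):
        if boundaries[i] == 0 and widths[i] == 1:
            a.append(0.07 + 1.7 * m[0])
        else:
            a.append(widths[i] / 2.0)

    q = []
    for i in range(k - 1):
        qi = widths[i] * m[i] / (1.0 + (widths[i] - a[i]) * m[i])
        q.append(min(qi, 1.0))
    q.append(1.0)

    radix = 100_000.0
    l = [radix]
    for i in range(k - 1):
        l.append(l[i] * (1.0 - q[i]))
    d = [l[i] - l[i + 1] for i in range(k - 1)] + [l[k - 1]]

    e_terminal = 1.0 / m[k - 1] if m[k - 1] > 0 else 0.0
    a.append(e_terminal)

    L = [widths[i] * l[i + 1] + a[i] * d[i] for i in range(k - 1)]
    L.append(l[k - 1] * e_terminal)

    T = [0.0] * k
    running = 0.0
    for i in range(k - 1, -1, -1):
        running += L[i]
        T[i] = running
    e = [T[i] / l[i] if l[i] > 0 else 0.0 for i in range(k)]

    return {"m": list(m), "a": a, "q": q, "l": l, "d": d, "L": L, "T": T, "e": e}


def oracle_partial_le(table, boundaries, x1, x2):
    """(T(x1) − T(x2)) / l(x1) computed directly from oracle columns."""
    i1 = boundaries.index(x1)
    i2 = boundaries.index(x2)
    return (table["T"][i1] - table["T"][i2]) / table["l"][i1]
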