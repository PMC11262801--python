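"""Independent brute-force oracles used by several test modules."""


def brute_force_window_count(t, window_seconds=2.0, max_gap_fraction=0.5):
    """Plain-Python enumeration of valid window centres: a timestep keeps its
    window unless some gap between consecutive raw samples overlaps the
    window span and exceeds the allowed fraction of the window length."""
    t = list(t)
    if len(t) < 2 or t[-1] - t[0] < window_seconds:
        return 0
    half = window_seconds / 2
    count = 0
    for tc in t:
        ok = True
        for a, b in zip(t, t[1:]):
            if b > tc - half and a < tc + half and b - a > max_gap_fraction * window_seconds:
                ok = False
                break
        if ok:
            count += 1
    return count
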