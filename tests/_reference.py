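"""Independent brute-force re-implementation of the detection rules.

Used as an oracle: a plain-loop, whole-array implementation of the same
documented contracts (zero-crossing conventions, sustained swing threshold,
first-local-minimum IC, unique-window-minimum FO, waiting time, preemption
order), written without reusing any package internals. Kept deliberately
naive — exhaustive per-sample evaluation of every condition.
"""

from __future__ import annotations


def reference_detect(
    g,
    fs: float,
    swing_threshold: float = 60.0,
    swing_min_samples: int = 5,
    fo_threshold: float = -60.0,
    fo_window: int = 26,
    fo_lookahead: int = 15,
    wait_time_ms: float = 200.0,
    preempt: bool = True,
) -> list[tuple[str, int]]:
    g = [float(x) for x in g]
    n_total = len(g)
    behind = fo_window - 1 - fo_lookahead
    wait = int(round(wait_time_ms * fs / 1000.0))
    out: list[tuple[str, int]] = []

    def fo_ok(k: int) -> bool:
        if g[k] > fo_threshold:
            return False
        lo = max(0, k - behind)
        hi = min(n_total - 1, k + fo_lookahead)
        for j in range(lo, hi + 1):
            if j != k and g[j] <= g[k]:
                return False
        return True

    pos = 0
    while True:
        # --- qualified swing wave: AZ then sustained threshold then DZ ---
        az = dz = None
        n = pos
        while n < n_total:
            prev = g[n - 1] if n > 0 else 0.0
            if prev <= 0.0 < g[n]:
                run = best = 0
                m = n
                while m < n_total and g[m] > 0.0:
                    run = run + 1 if g[m] >= swing_threshold else 0
                    best = max(best, run)
                    m += 1
                if m < n_total and best >= swing_min_samples:
                    az, dz = n, m
                    break
                n = m  # wave discarded (or signal ended); resume after it
            else:
                n += 1
        if dz is None:
            break

        # --- IC: first negative local minimum after DZ ---
        ic = None
        for k in range(dz + 1, n_total - 1):
            if g[k] < 0.0 and g[k] < g[k - 1] and g[k] <= g[k + 1]:
                ic = k
                break
        if ic is None:
            break
        out.append(("IC", ic))

        # --- FO search with optional preemption by a new swing ---
        start_fo = ic + wait
        fo = None
        resume = None
        if start_fo <= ic and fo_ok(ic):
            fo = ic
        else:
            in_wave = False
            run = 0
            qualified = False
            wave_az = None
            k = ic + 1
            while k < n_total:
                if in_wave:
                    if g[k] <= 0.0:
                        in_wave = False
                        qualified = False
                        run = 0
                    else:
                        run = run + 1 if g[k] >= swing_threshold else 0
                        qualified = qualified or run >= swing_min_samples
                elif g[k - 1] <= 0.0 < g[k]:
                    in_wave = True
                    wave_az = k
                    run = 1 if g[k] >= swing_threshold else 0
                    qualified = run >= swing_min_samples
                if preempt and k >= start_fo and in_wave and qualified:
                    resume = wave_az
                    break
                if k >= start_fo and fo_ok(k):
                    fo = k
                    break
                k += 1
        if fo is not None:
            out.append(("FO", fo))
            pos = fo + 1
        elif resume is not None:
            pos = resume
        else:
            break
    return out
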