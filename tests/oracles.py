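"""Independent brute-force oracles shared across tests.

These implement the operation definitions directly (exhaustive enumeration),
independently of the package's scanning algorithms.
"""


def brute_force_inversions(order_a, order_b, flank_k=2):
    """Test every contiguous A-block for reversal+flip with syntenic flanks."""
    pos_b = {g: i for i, (g, _) in enumerate(order_b)}
    sign_b = {g: s for g, s in order_b}
    n = len(order_a)
    found = []
    for i in range(n):
        for j in range(i, n):
            block = order_a[i : j + 1]
            bpos = [pos_b[g] for g, _ in block]
            if bpos != list(range(max(bpos), min(bpos) - 1, -1)):
                continue
            if any(sign_b[g] != -s for g, s in block):
                continue

            def extends(ai, side):
                if ai < 0 or ai >= n:
                    return False
                g, s = order_a[ai]
                if sign_b[g] != -s:
                    return False
                return (
                    pos_b[g] == max(bpos) + 1 if side == "left"
                    else pos_b[g] == min(bpos) - 1
                )

            if extends(i - 1, "left") or extends(j + 1, "right"):
                continue
            ok = True
            for f in range(1, flank_k + 1):
                li, ri = i - f, j + f
                if li < 0 or ri >= n:
                    ok = False
                    break
                for ai, expect in ((li, min(bpos) - f), (ri, max(bpos) + f)):
                    g, s = order_a[ai]
                    if sign_b[g] != s or pos_b[g] != expect:
                        ok = False
                if not ok:
                    break
            if ok:
                found.append(frozenset(g for g, _ in block))
    return sorted(found, key=sorted)
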