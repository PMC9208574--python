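"""Independent reference implementations used only by the tests."""

from __future__ import annotations


def merge_oracle(intervals, gap_s):
    """Exhaustive session-merging oracle over one sorted event stream.

    ``intervals`` is a list of (start_s, end_s) pairs sorted by (start, end).
    Enumerates all 2^(n-1) contiguous partitions and keeps the one where
    every within-block successive gap (next start minus the running max end)
    is strictly below ``gap_s`` and every between-block gap is >= ``gap_s``.
    Exactly one partition satisfies this; it is returned as a list of blocks
    of indices.
    """
    n = len(intervals)
    if n == 0:
        return []
    valid = []
    for mask in range(2 ** (n - 1)):
        ok = True
        run_end = intervals[0][1]
        for i in range(n - 1):
            gap = intervals[i + 1][0] - run_end
            boundary = (mask >> i) & 1
            if boundary != (gap >= gap_s):
                ok = False
                break
            if boundary:
                run_end = intervals[i + 1][1]
            else:
                run_end = max(run_end, intervals[i + 1][1])
        if ok:
            valid.append(mask)
    assert len(valid) == 1, f"expected exactly one valid partition, got {len(valid)}"
    mask = valid[0]
    blocks, block = [], [0]
    for i in range(n - 1):
        if (mask >> i) & 1:
            blocks.append(block)
            block = [i + 1]
        else:
            block.append(i + 1)
    blocks.append(block)
    return blocks


def bh_step_up(p_values, q):
    """Textbook Benjamini-Hochberg linear step-up, written from the
    definition: reject H_(1..k*) where k* = max{k : p_(k) <= k q / m}."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if p_values[i] <= rank * q / m:
            k_star = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            reject[i] = True
    return reject
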