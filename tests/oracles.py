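"""Independent brute-force oracles used to validate the pipeline.

These deliberately take a different route from the implementation:
recombination events are counted as (number of zygosity runs - 1) via
run-length encoding, and the singleton rule is applied by dropping
interior runs of length one from the RLE decomposition.
"""

from __future__ import annotations


def rle(calls: list[str]) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for c in calls:
        if runs and runs[-1][0] == c:
            runs[-1] = (c, runs[-1][1] + 1)
        else:
            runs.append((c, 1))
    return runs


def oracle_count(calls: list[str]) -> int:
    """Events = number of zygosity runs minus one."""
    if not calls:
        return 0
    return len(rle(calls)) - 1


def oracle_singleton(calls: list[str]) -> list[str]:
    """Drop interior runs of length one (terminal runs are kept).

    For a binary HOM/HET alphabet, adjacent runs always differ, so an
    interior run of length one is exactly a call contradicted by both
    informative neighbours.
    """
    runs = rle(calls)
    out: list[str] = []
    for i, (call, length) in enumerate(runs):
        if length == 1 and 0 < i < len(runs) - 1:
            continue
        out.extend([call] * length)
    return out


def oracle_true_events(het: list[bool]) -> int:
    """Events implied by a true zygosity vector, after the singleton rule."""
    calls = ["HET" if h else "HOM" for h in het]
    return oracle_count(oracle_singleton(calls))
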