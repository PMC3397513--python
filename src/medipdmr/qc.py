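"""Small sequencing-run summary statistics."""

from __future__ import annotations

__all__ = ["alignment_yield"]


def alignment_yield(aligned_gb: float, total_gb: float) -> float:
    """Percentage of sequenced bases that aligned, to two decimals.

    E.g. 32.91 Gb aligned of 42.80 Gb sequenced → 76.89.
    """
    if total_gb <= 0:
        raise ValueError("total must be positive")
    if aligned_gb < 0 or aligned_gb > total_gb:
        raise ValueError("aligned bases must lie in [0, total]")
    return round(100.0 * aligned_gb / total_gb, 2)
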