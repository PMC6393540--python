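"""Formal side-chain net charge of a protein sequence."""

from __future__ import annotations

__all__ = ["sequence_net_charge"]

_VALID = set("ACDEFGHIKLMNPQRSTVWY")
_POSITIVE = {"K", "R"}
_NEGATIVE = {"D", "E"}


def sequence_net_charge(sequence: str) -> int:
    """Formal net side-chain charge: +1 per K/R, -1 per D/E.

    Histidine is counted neutral and termini are ignored (a plain
    side-chain count).  Case-insensitive; invalid one-letter codes raise.
    """
    total = 0
    for pos, raw in enumerate(sequence):
        aa = raw.upper()
        if aa not in _VALID:
            raise ValueError(
                f"invalid one-letter amino acid code {raw!r} at position {pos}"
            )
        if aa in _POSITIVE:
            total += 1
        elif aa in _NEGATIVE:
            total -= 1
    return total
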