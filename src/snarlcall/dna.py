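"""Small DNA sequence helpers shared across modules."""

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet, case preserved)."""
    return seq.translate(_COMP)[::-1]


def check_dna(seq: str, context: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{context}: empty DNA sequence")
    bad = set(seq.upper()) - VALID_ALPHABET
    if bad:
        raise ValueError(f"{context}: invalid characters {sorted(bad)}")
    return seq
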