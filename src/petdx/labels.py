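"""Canonical diagnostic classes and their fixed ordering.

The order is used everywhere a deterministic tie-break over classes is
needed (majority-vote ties, confusion-matrix layout, coding matrices).
"""

CLASS_ORDER: tuple[str, ...] = ("AD", "DLB", "FTD", "NC")

OTHER_LABEL = "other"


def class_rank(label: str) -> int:
    """Position of ``label`` in the canonical order (unknown labels last)."""
    try:
        return CLASS_ORDER.index(label)
    except ValueError:
        return len(CLASS_ORDER)
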