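"""Virtual restriction digest: CATG-anchored tag sites on transcripts."""

from __future__ import annotations

ANCHOR = "CATG"
TAG_LENGTH = 21  # anchor (4 nt) + 17 nt downstream
VARIABLE_LENGTH = TAG_LENGTH - len(ANCHOR)


def tag_sites(seq: str) -> list[tuple[int, int, str]]:
    """Enumerate tag sites of a sense-strand transcript sequence.

    A valid site is an occurrence of the CATG anchor with at least 17 nt
    downstream, yielding a 21-nt tag (anchor + 17 nt). Sites are returned
    as ``(rank, start, tag)`` tuples ordered by rank, where rank 0 is the
    3'-most valid site.
    """
    seq = seq.upper()
    positions = []
    i = seq.find(ANCHOR)
    while i != -1:
        if len(seq) - i >= TAG_LENGTH:
            positions.append(i)
        i = seq.find(ANCHOR, i + 1)
    return [
        (rank, pos, seq[pos : pos + TAG_LENGTH])
        for rank, pos in enumerate(reversed(positions))
    ]
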