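"""Trinucleotide contexts and the 96-channel substitution convention.

Single-base substitutions are reported pyrimidine-centered: a mutation at
a purine reference base is reverse-complemented onto the opposite strand,
collapsing the 64 trinucleotides onto 32 pyrimidine-centered contexts and
the 12 substitution types onto 6. Channels follow the standard catalog
layout ``5'[REF>ALT]3'`` ordered by substitution class then flanks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
PYRIMIDINES = "CT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: the six pyrimidine-centered substitution classes, catalog order
SUBSTITUTION_CLASSES = [
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
]

#: 32 pyrimidine-centered trinucleotide contexts (5' flank, C/T, 3' flank)
CONTEXTS_32 = [f"{f}{c}{t}" for c in PYRIMIDINES for f in BASES for t in BASES]

#: 96 substitution channels, e.g. ``A[C>T]G``
CHANNELS_96 = [
    f"{f}[{r}>{a}]{t}"
    for (r, a) in SUBSTITUTION_CLASSES
    for f in BASES
    for t in BASES
]

_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_32)}
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def collapse_context(trinucleotide: str) -> str:
    """Map a trinucleotide onto its pyrimidine-centered representative."""
    if len(trinucleotide) != 3:
        raise ValueError(f"expected a trinucleotide, got {trinucleotide!r}")
    if trinucleotide[1] in PYRIMIDINES:
        return trinucleotide
    return revcomp(trinucleotide)


def channel_of(context: str, ref_base: str, alt_base: str) -> str:
    """96-channel label for a substitution in its trinucleotide context.

    Purine-centered inputs are reverse-complemented first, so e.g.
    ``channel_of("TGA", "G", "A") == "T[C>T]A"``.
    """
    if len(context) != 3:
        raise ValueError(f"context must have length 3, got {context!r}")
    context = context.upper()
    ref_base = ref_base.upper()
    alt_base = alt_base.upper()
    for b in context + ref_base + alt_base:
        if b not in BASES:
            raise ValueError(f"non-ACGT base {b!r} in substitution")
    if context[1] != ref_base:
        raise ValueError(
            f"central base of context {context} does not match ref {ref_base}"
        )
    if ref_base == alt_base:
        raise ValueError(f"ref and alt are both {ref_base}")
    if ref_base not in PYRIMIDINES:
        context = revcomp(context)
        ref_base = revcomp(ref_base)
        alt_base = revcomp(alt_base)
    return f"{context[0]}[{ref_base}>{alt_base}]{context[2]}"


def parse_channel(channel: str) -> tuple[str, str, str, str]:
    """Split ``"A[C>T]G"`` into (5' flank, ref, alt, 3' flank)."""
    if (
        len(channel) != 7
        or channel[1] != "["
        or channel[3] != ">"
        or channel[5] != "]"
    ):
        raise ValueError(f"malformed channel label {channel!r}")
    return channel[0], channel[2], channel[4], channel[6]


def context_of_channel(channel: str) -> str:
    """Trinucleotide context of a channel label."""
    f, r, _, t = parse_channel(channel)
    return f"{f}{r}{t}"


#: context label per channel, aligned with :data:`CHANNELS_96`
CHANNEL_CONTEXTS = [context_of_channel(c) for c in CHANNELS_96]

#: channels describing C>T at CpG sites (N[C>T]G)
CPG_CT_CHANNELS = [c for c in CHANNELS_96 if c[2:5] == "C>T" and c[6] == "G"]
#: channels describing C>T at CpA sites (N[C>T]A)
CPA_CT_CHANNELS = [c for c in CHANNELS_96 if c[2:5] == "C>T" and c[6] == "A"]


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0..T=3, -1 for non-ACGT)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


# 64 -> 32 collapse table: trinucleotide code 16*a+4*b+c maps to the row of
# its pyrimidine-centered representative in CONTEXTS_32.
def _build_collapse_table() -> np.ndarray:
    table = np.empty(64, dtype=np.int64)
    for a in range(4):
        for b in range(4):
            for c in range(4):
                tri = BASES[a] + BASES[b] + BASES[c]
                table[16 * a + 4 * b + c] = _CONTEXT_INDEX[collapse_context(tri)]
    return table


_COLLAPSE_64_TO_32 = _build_collapse_table()


def context_code_array(codes: np.ndarray) -> np.ndarray:
    """Collapsed 32-context index per interior position of an encoded sequence.

    Position ``i`` of the output corresponds to the context centered at
    sequence position ``i + 1`` (0-based).  Positions touching a non-ACGT
    base get -1.
    """
    if codes.size < 3:
        return np.empty(0, dtype=np.int64)
    a, b, c = codes[:-2], codes[1:-1], codes[2:]
    valid = (a >= 0) & (b >= 0) & (c >= 0)
    tri = (
        16 * a.astype(np.int64) + 4 * b.astype(np.int64) + c.astype(np.int64)
    )
    out = np.where(valid, _COLLAPSE_64_TO_32[np.clip(tri, 0, 63)], -1)
    return out


def build_context_model(reference_sequence: str) -> pd.Series:
    """Frequencies of the 32 pyrimidine-centered contexts in a sequence.

    Every interior position contributes its centered trinucleotide, with
    purine-centered occurrences collapsed by reverse complement.  Interior
    positions touching non-ACGT characters are skipped (a count of skipped
    positions is logged); if every position is skipped the sequence is
    unusable and an error is raised.
    """
    if len(reference_sequence) < 3:
        raise ValueError("sequence must be at least 3 bases long")
    ctx = context_code_array(encode_sequence(reference_sequence))
    skipped = int((ctx < 0).sum())
    if skipped:
        logger.info("skipped %d interior positions with non-ACGT bases", skipped)
    counts = np.bincount(ctx[ctx >= 0], minlength=32)
    total = counts.sum()
    if total == 0:
        raise ValueError("no usable ACGT trinucleotides in sequence")
    return pd.Series(counts / total, index=CONTEXTS_32, name="frequency")
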