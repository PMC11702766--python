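"""Assign barcode pairs to guide pairs from long construct reads.

Long reads of the plasmid library interleave five fixed anchor sequences
with the two protospacers and the two barcodes:

    [a0][protospacer1][a1][protospacer2][a2][barcode22][a3][barcode23][a4]

Parsing matches each anchor within a substitution budget (fast path at the
fixed layout offsets, with a scanning fallback), extracts the intervening
segments, and resolves each protospacer to a unique library guide by Hamming
distance.  The barcode map then demands concordance: a barcode pair whose
reads support more than one distinct guide pair is dropped as ambiguous
(never majority-voted), and pairs below the support threshold are dropped as
low-support.  Assignment errors propagate multiplicatively into phenotypes,
so the map favours precision over recall.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .library import (
    BARCODE_LEN_PCL5,
    BARCODE_LEN_UBC6,
    PROTOSPACER_LEN,
    AmbiguousMatch,
    GuideLibrary,
)
from .simulate import LONG_ANCHORS

STATUS_OK = "ok"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_LOW_SUPPORT = "low_support"

MAP_COLUMNS = [
    "barcode_ubc6",
    "barcode_pcl5",
    "guide_first",
    "guide_second",
    "support",
    "status",
]


@dataclass(frozen=True)
class ConstructCall:
    """A successfully parsed long read."""

    guide_first: str
    guide_second: str
    barcode_ubc6: str
    barcode_pcl5: str


@dataclass(frozen=True)
class ParseFailure:
    """A long read that could not be parsed; ``reason`` says which segment."""

    reason: str


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _anchor_matches(seq: str, anchor: str, offset: int, max_mismatch: int) -> bool:
    window = seq[offset : offset + len(anchor)]
    if len(window) != len(anchor):
        return False
    return hamming(window, anchor) <= max_mismatch


def _find_anchor(seq: str, anchor: str, max_mismatch: int) -> int | None:
    """Best unique anchor position by Hamming scan; None if not found."""
    best_pos, best_d, ties = None, max_mismatch + 1, 0
    for pos in range(len(seq) - len(anchor) + 1):
        d = hamming(seq[pos : pos + len(anchor)], anchor)
        if d < best_d:
            best_pos, best_d, ties = pos, d, 1
        elif d == best_d:
            ties += 1
    if best_pos is None or best_d > max_mismatch or ties > 1:
        return None
    return best_pos


def _expected_offsets(anchors=LONG_ANCHORS) -> list[int]:
    lens = [len(a) for a in anchors]
    segs = [PROTOSPACER_LEN, PROTOSPACER_LEN, BARCODE_LEN_UBC6, BARCODE_LEN_PCL5]
    offsets = [0]
    for a_len, s_len in zip(lens[:-1], segs):
        offsets.append(offsets[-1] + a_len + s_len)
    return offsets


def parse_construct_read(
    read: str,
    library: GuideLibrary,
    anchors=LONG_ANCHORS,
    max_mismatch: int = 1,
) -> ConstructCall | ParseFailure:
    """Extract (guide1, guide2, barcode_ubc6, barcode_pcl5) from a long read.

    Returns a :class:`ConstructCall`, or a :class:`ParseFailure` whose reason
    is one of ``no_anchor``, ``bad_protospacer_length``,
    ``bad_barcode_length``, ``unknown_guide`` or ``ambiguous_guide``.
    """
    offsets = _expected_offsets(anchors)
    expected_len = offsets[-1] + len(anchors[-1])

    if len(read) == expected_len and all(
        _anchor_matches(read, a, o, max_mismatch) for a, o in zip(anchors, offsets)
    ):
        positions = offsets
    else:
        positions = []
        for a in anchors:
            pos = _find_anchor(read, a, max_mismatch)
            if pos is None:
                return ParseFailure("no_anchor")
            positions.append(pos)
        if positions != sorted(positions):
            return ParseFailure("no_anchor")

    segments = [
        read[positions[i] + len(anchors[i]) : positions[i + 1]] for i in range(len(anchors) - 1)
    ]
    proto1, proto2, bc_u, bc_p = segments
    if len(proto1) != PROTOSPACER_LEN or len(proto2) != PROTOSPACER_LEN:
        return ParseFailure("bad_protospacer_length")
    if len(bc_u) != BARCODE_LEN_UBC6 or len(bc_p) != BARCODE_LEN_PCL5:
        return ParseFailure("bad_barcode_length")

    guides = []
    for proto in (proto1, proto2):
        try:
            hit = library.match_protospacer(proto, max_mismatch=max_mismatch)
        except AmbiguousMatch:
            return ParseFailure("ambiguous_guide")
        if hit is None:
            return ParseFailure("unknown_guide")
        guides.append(hit)
    return ConstructCall(guides[0], guides[1], bc_u, bc_p)


def build_barcode_map(calls, min_support: int = 3) -> pd.DataFrame:
    """Aggregate parsed reads into a barcode-pair -> guide-pair map.

    Each barcode pair appears exactly once in the output.  Entries whose
    reads support a single guide pair with at least ``min_support`` reads are
    ``ok``; conflicting guide pairs yield ``ambiguous`` (reporting the modal
    pair); insufficient support yields ``low_support``.
    """
    import warnings

    tallies: dict[tuple[str, str], Counter] = {}
    for call in calls:
        if isinstance(call, ParseFailure):
            continue
        key = (call.barcode_ubc6, call.barcode_pcl5)
        tallies.setdefault(key, Counter())[(call.guide_first, call.guide_second)] += 1
    if not tallies:
        warnings.warn("no parsed construct reads: barcode map is empty")

    rows = []
    for (bu, bp), counter in tallies.items():
        support = sum(counter.values())
        (g1, g2), _top = counter.most_common(1)[0]
        if len(counter) > 1:
            status = STATUS_AMBIGUOUS
        elif support < min_support:
            status = STATUS_LOW_SUPPORT
        else:
            status = STATUS_OK
        rows.append(
            {
                "barcode_ubc6": bu,
                "barcode_pcl5": bp,
                "guide_first": g1,
                "guide_second": g2,
                "support": support,
                "status": status,
            }
        )
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


def assign_from_fastq(
    fastq_path,
    library: GuideLibrary,
    anchors=LONG_ANCHORS,
    max_mismatch: int = 1,
    min_support: int = 3,
) -> tuple[pd.DataFrame, Counter]:
    """Full long-read pipeline: FASTQ -> barcode map plus failure tally."""
    from .io import iter_fastq_sequences

    failures: Counter = Counter()
    calls = []
    for seq in iter_fastq_sequences(fastq_path):
        res = parse_construct_read(seq, library, anchors=anchors, max_mismatch=max_mismatch)
        if isinstance(res, ParseFailure):
            failures[res.reason] += 1
        else:
            calls.append(res)
    return build_barcode_map(calls, min_support=min_support), failures


def compare_to_manifest(barcode_map: pd.DataFrame, manifest: pd.DataFrame) -> dict:
    """Precision/recall of ok map entries against the simulator manifest.

    An ok entry is correct when its barcode pair exists in the manifest with
    the same (order-sensitive) guide pair.
    """
    truth = {
        (r.barcode_ubc6, r.barcode_pcl5): (r.guide_first, r.guide_second)
        for r in manifest.itertuples()
    }
    ok = barcode_map[barcode_map["status"] == STATUS_OK]
    correct = sum(
        truth.get((r.barcode_ubc6, r.barcode_pcl5)) == (r.guide_first, r.guide_second)
        for r in ok.itertuples()
    )
    n_ok = len(ok)
    return {
        "n_ok": n_ok,
        "n_correct": correct,
        "precision": correct / n_ok if n_ok else float("nan"),
        "recall": correct / len(truth) if len(truth) else float("nan"),
    }
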