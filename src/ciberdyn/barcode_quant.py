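"""Short-read barcode extraction, UMI deduplication and counting.

Reporter amplicon reads have the layout

    [8-nt UMI][1 fixed base][20-nt reporter anchor][barcode (22 or 23 nt)]

The anchor identifies the reporter (UBC6/normalizer side carries 22-nt
barcodes, PCL5/ISR side 23-nt), the UMI collapses PCR duplicates, and the
barcode is looked up in the construct map.  UMI collapse is exact-match: a
sample's count for a barcode is the number of distinct (barcode, UMI) pairs
observed, which makes counting idempotent under re-reading the same file.
Barcodes absent from the map are rescued when they are within the mismatch
budget of exactly one known barcode; ties stay unassigned.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import BARCODE_LEN_PCL5, BARCODE_LEN_UBC6
from .simulate import REPORTER_PCL5, REPORTER_UBC6, SHORT_ANCHORS, UMI_LENGTH

BARCODE_OFFSET = UMI_LENGTH + 1 + 20  # UMI + fixed base + anchor
MIN_READ_LEN = BARCODE_OFFSET + BARCODE_LEN_PCL5

_BARCODE_LEN = {REPORTER_UBC6: BARCODE_LEN_UBC6, REPORTER_PCL5: BARCODE_LEN_PCL5}


@dataclass(frozen=True)
class BarcodeHit:
    """One successfully extracted read."""

    umi: str
    reporter: str
    barcode: str


@dataclass(frozen=True)
class ExtractFailure:
    reason: str


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_barcode_hit(
    read: str, anchors: dict = SHORT_ANCHORS, max_mismatch: int = 1
) -> BarcodeHit | ExtractFailure:
    """Extract (UMI, reporter, barcode) from a short read.

    Failure reasons: ``too_short`` (read cannot hold UMI + anchor + the
    longer barcode), ``no_anchor`` (neither reporter anchor matches within
    ``max_mismatch``), ``truncated_barcode``.
    """
    anchor_len = len(next(iter(anchors.values())))
    if len(read) < UMI_LENGTH + 1 + anchor_len + max(_BARCODE_LEN.values()):
        return ExtractFailure("too_short")
    window = read[UMI_LENGTH + 1 : UMI_LENGTH + 1 + anchor_len]
    best_rep, best_d = None, max_mismatch + 1
    for reporter, anchor in anchors.items():
        d = _hamming(window, anchor)
        if d < best_d:
            best_rep, best_d = reporter, d
    if best_rep is None:
        return ExtractFailure("no_anchor")
    bc_len = _BARCODE_LEN[best_rep]
    start = UMI_LENGTH + 1 + anchor_len
    barcode = read[start : start + bc_len]
    if len(barcode) != bc_len:
        return ExtractFailure("truncated_barcode")
    return BarcodeHit(umi=read[:UMI_LENGTH], reporter=best_rep, barcode=barcode)


class _BarcodeIndex:
    """Exact and 1-ish-mismatch lookup of known barcodes for one side."""

    def __init__(self, barcodes: pd.Series, max_mismatch: int):
        # barcodes: index construct_id, values barcode strings
        self.exact = {b: c for c, b in barcodes.items()}
        self.max_mismatch = max_mismatch
        self._strings = list(barcodes.values)
        self._ids = list(barcodes.index)
        self._matrix = None
        self._cache: dict[str, str | None] = {}

    def lookup(self, barcode: str) -> str | None:
        hit = self.exact.get(barcode)
        if hit is not None:
            return hit
        if self.max_mismatch == 0 or not self._strings:
            return None
        cached = self._cache.get(barcode, "_miss_")
        if cached != "_miss_":
            return cached
        if self._matrix is None:
            self._matrix = np.frombuffer(
                "".join(self._strings).encode("ascii"), dtype=np.uint8
            ).reshape(len(self._strings), len(self._strings[0]))
        q = np.frombuffer(barcode.encode("ascii"), dtype=np.uint8)
        if len(q) != self._matrix.shape[1]:
            self._cache[barcode] = None
            return None
        d = (self._matrix != q).sum(axis=1)
        best = d.min()
        result = None
        if best <= self.max_mismatch and (d == best).sum() == 1:
            result = self._ids[int(d.argmin())]
        self._cache[barcode] = result
        return result


def count_barcodes(
    hits_by_sample: dict,
    construct_map: pd.DataFrame,
    collapse_umi: bool = True,
    max_mismatch: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally hits into a construct x reporter x sample count table.

    ``hits_by_sample`` maps sample_id to an iterable of :class:`BarcodeHit`.
    ``construct_map`` needs columns construct_id, barcode_ubc6, barcode_pcl5
    (an ok-status barcode map joined to construct ids, or the simulator
    manifest).  Returns ``(counts, unassigned)`` where counts has one row per
    (construct_id, reporter) and one column per sample, and unassigned
    tallies extracted hits whose barcode matched no known barcode uniquely.
    """
    cm = construct_map.drop_duplicates("construct_id").set_index("construct_id")
    indexes = {
        REPORTER_UBC6: _BarcodeIndex(cm["barcode_ubc6"], max_mismatch),
        REPORTER_PCL5: _BarcodeIndex(cm["barcode_pcl5"], max_mismatch),
    }
    sample_ids = list(hits_by_sample)
    assigned: dict[str, Counter] = {s: Counter() for s in sample_ids}
    unassigned: dict[str, int] = {s: 0 for s in sample_ids}
    for sample_id in sample_ids:
        seen: set = set()
        tally = assigned[sample_id]
        for hit in hits_by_sample[sample_id]:
            if isinstance(hit, ExtractFailure):
                continue
            construct = indexes[hit.reporter].lookup(hit.barcode)
            if construct is None:
                if collapse_umi:
                    key = ("_un_", hit.reporter, hit.barcode, hit.umi)
                    if key in seen:
                        continue
                    seen.add(key)
                unassigned[sample_id] += 1
                continue
            if collapse_umi:
                key = (construct, hit.reporter, hit.umi)
                if key in seen:
                    continue
                seen.add(key)
            tally[(construct, hit.reporter)] += 1

    keys = sorted({k for t in assigned.values() for k in t})
    out = pd.DataFrame(
        {
            "construct_id": [k[0] for k in keys],
            "reporter": [k[1] for k in keys],
            **{s: [assigned[s].get(k, 0) for k in keys] for s in sample_ids},
        }
    )
    un = pd.DataFrame({"sample_id": sample_ids, "unassigned": [unassigned[s] for s in sample_ids]})
    return out, un


def count_fastq_files(
    fastq_by_sample: dict,
    construct_map: pd.DataFrame,
    anchors: dict = SHORT_ANCHORS,
    collapse_umi: bool = True,
    max_mismatch: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, Counter]:
    """FASTQ -> count table pipeline; also returns extraction-failure tally."""
    from .io import iter_fastq_sequences

    failures: Counter = Counter()

    def hits(path):
        for seq in iter_fastq_sequences(path):
            res = extract_barcode_hit(seq, anchors=anchors, max_mismatch=max_mismatch)
            if isinstance(res, ExtractFailure):
                failures[res.reason] += 1
            else:
                yield res

    hits_by_sample = {s: hits(p) for s, p in fastq_by_sample.items()}
    counts, unassigned = count_barcodes(
        hits_by_sample, construct_map, collapse_umi=collapse_umi, max_mismatch=max_mismatch
    )
    return counts, unassigned, failures
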