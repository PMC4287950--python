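"""Interval-keyed piecewise-constant containers.

Position-associated genomic data (read coverage, annotation, scores) is
usually piecewise constant, so instead of one value per base pair the
:class:`GenomicArray` stores maximal runs of constant value ("steps") per
chromosome lane, keyed by sorted breakpoints. Point lookup is a binary
search over the breakpoints, i.e. logarithmic in the number of steps.

For genuinely dense data (e.g. per-base conservation scores) a numpy-backed
storage mode is available; both backends answer queries identically.

:class:`GenomicArrayOfSets` layers set-valued steps on top, so that
overlapping features (genes, exons) can share positions: inserting a
feature splits the steps it touches and adds the feature to each covered
step's set. The union of the step sets under a query interval is exactly
the set of features it overlaps.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from typing import Any, Iterable, Iterator

import numpy as np

from .core import GenomicInterval, GenomicPosition

_TYPECODE_DEFAULTS = {"d": 0.0, "i": 0, "O": None}
_NUMERIC_TYPECODES = {"d", "i"}


class _StepLane:
    """One (chromosome, strand) lane stored as sorted breakpoints + values.

    ``starts[i]`` begins step *i*, which extends to ``starts[i+1]`` (or to
    ``length``, possibly ``inf``, for the last step). Invariants: starts are
    strictly increasing beginning at 0, and adjacent values never compare
    equal (steps are maximal).
    """

    __slots__ = ("starts", "values", "length")

    def __init__(self, length: float, default: Any):
        self.starts: list[int] = [0]
        self.values: list[Any] = [default]
        self.length = length

    def _check_range(self, start: int, end: int) -> None:
        if start < 0:
            raise IndexError(f"negative coordinate {start}")
        if end > self.length:
            raise IndexError(
                f"query [{start},{end}) extends past lane end {self.length}"
            )

    def value_at(self, pos: int) -> Any:
        self._check_range(pos, pos + 1)
        return self.values[bisect_right(self.starts, pos) - 1]

    def iter_steps(self, start: int, end: int) -> Iterator[tuple[int, int, Any]]:
        """Yield (sub_start, sub_end, value) partitioning [start, end)."""
        self._check_range(start, end)
        if start >= end:
            return
        i = bisect_right(self.starts, start) - 1
        n = len(self.starts)
        while i < n and self.starts[i] < end:
            sub_start = max(start, self.starts[i])
            sub_end = min(end, self.starts[i + 1]) if i + 1 < n else end
            yield sub_start, sub_end, self.values[i]
            i += 1

    def set_value(self, start: int, end: int, value: Any) -> None:
        if start >= end:
            return
        self._check_range(start, end)
        starts, values = self.starts, self.values
        i = bisect_right(starts, start) - 1
        j = bisect_right(starts, end) - 1
        tail_val = values[j]
        if starts[i] == start:
            head_s, head_v = starts[:i], values[:i]
        else:
            head_s, head_v = starts[: i + 1], values[: i + 1]
        if head_v and head_v[-1] == value:
            mid_s: list[int] = []
            mid_v: list[Any] = []
        else:
            mid_s, mid_v = [start], [value]
        if end == self.length:
            suf_s: list[int] = []
            suf_v: list[Any] = []
        elif starts[j] == end:
            suf_s, suf_v = starts[j:], values[j:]
        else:
            suf_s, suf_v = [end] + starts[j + 1 :], [tail_val] + values[j + 1 :]
        left_v = mid_v if mid_v else head_v
        if suf_v and left_v and suf_v[0] == left_v[-1]:
            suf_s, suf_v = suf_s[1:], suf_v[1:]
        self.starts = head_s + mid_s + suf_s
        self.values = head_v + mid_v + suf_v

    def add_value(self, start: int, end: int, delta: Any) -> None:
        for s, e, v in list(self.iter_steps(start, end)):
            self.set_value(s, e, v + delta)


class _DenseLane:
    """One lane stored as a numpy buffer; numeric values only."""

    __slots__ = ("buf", "length")

    def __init__(self, length: float, default: Any, typecode: str):
        if not (isinstance(length, int) and length > 0):
            raise ValueError(
                "dense storage requires chromosomes declared with finite "
                "integer lengths"
            )
        dtype = np.float64 if typecode == "d" else np.int64
        self.length = length
        self.buf = np.full(length, default, dtype=dtype)

    def _check_range(self, start: int, end: int) -> None:
        if start < 0:
            raise IndexError(f"negative coordinate {start}")
        if end > self.length:
            raise IndexError(
                f"query [{start},{end}) extends past lane end {self.length}"
            )

    def value_at(self, pos: int) -> Any:
        self._check_range(pos, pos + 1)
        return self.buf[pos].item()

    def iter_steps(self, start: int, end: int) -> Iterator[tuple[int, int, Any]]:
        self._check_range(start, end)
        if start >= end:
            return
        seg = self.buf[start:end]
        # breakpoints where the value changes, relative to `start`
        cuts = np.flatnonzero(np.diff(seg)) + 1
        prev = 0
        for c in cuts.tolist() + [end - start]:
            yield start + prev, start + c, seg[prev].item()
            prev = c

    def set_value(self, start: int, end: int, value: Any) -> None:
        if start >= end:
            return
        self._check_range(start, end)
        self.buf[start:end] = value

    def add_value(self, start: int, end: int, delta: Any) -> None:
        self._check_range(start, end)
        self.buf[start:end] += delta


class GenomicArray:
    """A genome-wide container mapping every position to a value.

    Parameters
    ----------
    chroms
        ``"auto"`` to create conceptually infinite lanes on first write, a
        list of names (infinite lanes, declared up front), or a dict
        ``{name: length}``. The dense backend requires the dict form.
    stranded
        When true, every lane exists once per strand and every access must
        name "+" or "-". When false, strand "." is implied.
    typecode
        ``"d"`` float, ``"i"`` int, ``"O"`` arbitrary objects (step
        storage only).
    storage
        ``"step"`` (default) or ``"dense"``.
    """

    def __init__(
        self,
        chroms: str | list[str] | dict[str, int] = "auto",
        stranded: bool = False,
        typecode: str = "d",
        storage: str = "step",
        default: Any = "typecode",
    ):
        if typecode not in _TYPECODE_DEFAULTS:
            raise ValueError(f"unknown typecode {typecode!r}")
        if storage not in ("step", "dense"):
            raise ValueError(f"unknown storage mode {storage!r}")
        if storage == "dense" and typecode not in _NUMERIC_TYPECODES:
            raise ValueError("dense storage supports numeric values only")
        self.stranded = stranded
        self.typecode = typecode
        self.storage = storage
        self.default = (
            _TYPECODE_DEFAULTS[typecode] if default == "typecode" else default
        )
        self._auto = chroms == "auto"
        self._lanes: dict[tuple[str, str], Any] = {}
        self._chrom_lengths: dict[str, float] = {}
        if not self._auto:
            if isinstance(chroms, dict):
                items = chroms.items()
            else:
                items = ((c, math.inf) for c in chroms)
            for chrom, length in items:
                self.add_chrom(chrom, length)
        elif storage == "dense":
            raise ValueError(
                "dense storage requires chromosomes declared with lengths"
            )

    # -- lane management -------------------------------------------------

    def add_chrom(self, chrom: str, length: float = math.inf) -> None:
        if chrom in self._chrom_lengths:
            raise ValueError(f"chromosome {chrom!r} already declared")
        self._chrom_lengths[chrom] = length
        for strand in ("+", "-") if self.stranded else (".",):
            self._lanes[(chrom, strand)] = self._new_lane(length)

    def _new_lane(self, length: float):
        if self.storage == "dense":
            return _DenseLane(length, self.default, self.typecode)
        return _StepLane(length, self.default)

    @property
    def chroms(self) -> dict[str, float]:
        return dict(self._chrom_lengths)

    def _resolve_strand(self, strand: str) -> str:
        if self.stranded:
            if strand not in ("+", "-"):
                raise ValueError(
                    "strand required: this array is stranded but the access "
                    f"named strand {strand!r}"
                )
            return strand
        return "."

    def _lane(self, chrom: str, strand: str, create: bool):
        strand = self._resolve_strand(strand)
        key = (chrom, strand)
        lane = self._lanes.get(key)
        if lane is None:
            if create and self._auto and chrom not in self._chrom_lengths:
                self.add_chrom(chrom)
                lane = self._lanes[key]
            else:
                raise KeyError(f"unknown chromosome {chrom!r}")
        return lane

    # -- mutation ---------------------------------------------------------

    def set_value(self, iv: GenomicInterval, value: Any) -> None:
        """Assign ``value`` to every position of ``iv``."""
        self._lane(iv.chrom, iv.strand, create=True).set_value(
            iv.start, iv.end, value
        )

    def add_value(self, iv: GenomicInterval, delta) -> None:
        """Increment every position of ``iv`` by ``delta`` (numeric arrays)."""
        if self.typecode not in _NUMERIC_TYPECODES:
            raise TypeError("add_value requires a numeric array")
        self._lane(iv.chrom, iv.strand, create=True).add_value(
            iv.start, iv.end, delta
        )

    def __setitem__(self, iv: GenomicInterval, value: Any) -> None:
        self.set_value(iv, value)

    # -- queries ----------------------------------------------------------

    def value_at(self, pos: GenomicPosition) -> Any:
        return self._lane(pos.chrom, pos.strand, create=False).value_at(pos.pos)

    def __getitem__(self, key):
        if isinstance(key, GenomicPosition):
            return self.value_at(key)
        if isinstance(key, GenomicInterval):
            return self.steps(key)
        raise TypeError("index with a GenomicPosition or GenomicInterval")

    def steps(
        self, iv: GenomicInterval | None = None
    ) -> list[tuple[GenomicInterval, Any]]:
        """Steps over ``iv`` (or the whole array), partitioning it in order.

        The returned intervals carry the queried strand; the first starts at
        ``iv.start`` and the last ends at ``iv.end``.
        """
        if iv is None:
            out = []
            for (chrom, strand), lane in sorted(self._lanes.items()):
                end = lane.length
                if math.isinf(end):
                    end = lane.starts[-1] if isinstance(lane, _StepLane) else 0
                    # include one trailing default step marker only if content
                    out.extend(
                        (GenomicInterval(chrom, s, e, strand), v)
                        for s, e, v in lane.iter_steps(0, end)
                    )
                else:
                    out.extend(
                        (GenomicInterval(chrom, s, e, strand), v)
                        for s, e, v in lane.iter_steps(0, int(end))
                    )
            return out
        lane = self._lane(iv.chrom, iv.strand, create=False)
        return [
            (GenomicInterval(iv.chrom, s, e, iv.strand), v)
            for s, e, v in lane.iter_steps(iv.start, iv.end)
        ]


class GenomicArrayOfSets(GenomicArray):
    """A :class:`GenomicArray` whose step values are sets of features.

    The canonical annotation index: insert each exon under its gene
    reference, then query a read's footprint and take the union of the step
    sets to learn which genes it touches. Stored sets are immutable
    (``frozenset``), so splitting a step can never alias another step's set.
    """

    def __init__(
        self,
        chroms: str | list[str] | dict[str, int] = "auto",
        stranded: bool = False,
    ):
        super().__init__(
            chroms,
            stranded=stranded,
            typecode="O",
            storage="step",
            default=frozenset(),
        )

    def add_feature(self, iv: GenomicInterval, item: Any) -> None:
        """Add ``item`` to the set at every position of ``iv``."""
        lane = self._lane(iv.chrom, iv.strand, create=True)
        for s, e, current in list(lane.iter_steps(iv.start, iv.end)):
            lane.set_value(s, e, current | {item})

    def union(self, iv: GenomicInterval) -> frozenset:
        """The union of all step sets intersecting ``iv``."""
        lane = self._lane(iv.chrom, iv.strand, create=False)
        out: frozenset = frozenset()
        for _, _, val in lane.iter_steps(iv.start, iv.end):
            out = out | val
        return out


def aggregate_profile(
    cov: GenomicArray,
    anchors: Iterable[GenomicPosition],
    halfwidth: int,
) -> np.ndarray:
    """Average coverage in windows centred on anchor positions.

    The classic TSS-profile computation: element ``j`` of the returned
    vector (length ``2 * halfwidth``) is the mean coverage at offset
    ``j - halfwidth`` from the anchors, in reading direction — windows of
    minus-strand anchors are reversed so index 0 is always 5'-most.
    Window positions falling outside a lane contribute nothing; each offset
    is divided by the number of anchors that actually cover it (offsets no
    anchor covers are reported as 0).
    """
    if halfwidth <= 0:
        raise ValueError(f"halfwidth must be positive, got {halfwidth}")
    anchors = list(anchors)
    if not anchors:
        raise ValueError("at least one anchor position is required")
    if cov.typecode not in _NUMERIC_TYPECODES:
        raise TypeError("aggregate_profile requires a numeric coverage array")
    width = 2 * halfwidth
    total = np.zeros(width, dtype=np.float64)
    denom = np.zeros(width, dtype=np.float64)
    for anchor in anchors:
        strand = anchor.strand if cov.stranded else "."
        lane = cov._lane(anchor.chrom, strand if cov.stranded else ".", False)
        lane_len = lane.length
        if anchor.strand == "-":
            # window covers genomic [p - halfwidth + 1, p + halfwidth + 1);
            # profile index j maps to genomic position p + halfwidth - j
            lo = anchor.pos - halfwidth + 1
            hi = anchor.pos + halfwidth + 1
        else:
            lo = anchor.pos - halfwidth
            hi = anchor.pos + halfwidth
        clip_lo = max(lo, 0)
        clip_hi = min(hi, lane_len) if not math.isinf(lane_len) else hi
        clip_hi = int(clip_hi)
        if clip_lo >= clip_hi:
            continue
        window = np.empty(clip_hi - clip_lo, dtype=np.float64)
        for s, e, v in lane.iter_steps(clip_lo, clip_hi):
            window[s - clip_lo : e - clip_lo] = v
        if anchor.strand == "-":
            j_from = hi - clip_hi  # genomic hi-1 maps to profile index lo_j
            vals = window[::-1]
        else:
            j_from = clip_lo - lo
            vals = window
        total[j_from : j_from + len(vals)] += vals
        denom[j_from : j_from + len(vals)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(denom > 0, total / np.maximum(denom, 1.0), 0.0)
    return profile
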